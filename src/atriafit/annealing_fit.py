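"""Simulated-annealing estimation of ionic-model parameters.

The fit minimizes a combined percent-error between simulated and target
curves: AP morphology on the normalized grid, APD restitution, CV
restitution, and optionally the upstroke interval.  Candidate parameter
sets are perturbed under an artificial temperature that shrinks by a
constant factor per iteration (default 10%); uphill moves are accepted
with Metropolis probability exp(-dE/T), so the search does not reject
every move that worsens the fit and can escape local minima.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .cable_sim import CableConfig, ConfigError, InstabilityError
from .clinical_curves import ClinicalDataset
from .ionic_model import BlowUpError
from .params import (
    DEFAULT_FROZEN,
    MULTIPLICATIVE_PARAMS,
    PARAM_ORDER,
    InvalidParametersError,
    ModelParameters,
)
from .restitution import (
    MorphologyShape,
    ProtocolError,
    S1S2Result,
    UnresolvedAPDError,
    s1s2_restitution,
)

_SIM_FAILURES = (
    InstabilityError,
    BlowUpError,
    ProtocolError,
    UnresolvedAPDError,
    ConfigError,
    InvalidParametersError,
)


@dataclass
class ErrorBreakdown:
    """Per-component percent errors of a candidate fit."""

    e_morph: float
    e_apd: float
    e_cv: float
    e_upstroke: float
    total: float
    residuals: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "e_morph": self.e_morph, "e_apd": self.e_apd, "e_cv": self.e_cv,
            "e_upstroke": self.e_upstroke, "total": self.total,
        }


@dataclass(frozen=True)
class FitConfig:
    """Annealing schedule, proposal scales and error weighting."""

    n_iterations: int = 50
    cooling_factor: float = 0.9
    moves_per_iteration: int = 20
    initial_temperature: float | None = None  # None -> auto-calibrated
    sigma: float = 0.3                        # proposal scale at T = T0
    min_move_ratio: float = 0.1               # floor on the T/T0 move shrinkage
    weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 0.0)
    frozen: tuple[str, ...] = DEFAULT_FROZEN
    bounds: dict | None = None                # name -> (lo, hi); None -> defaults
    s1_cl: float = 500.0
    n_s1: int = 8
    s2_list: tuple[float, ...] | None = None  # None -> derived from target
    tail: float = 600.0                       # ms recorded after the S2 beat
    max_fit_points: int = 8
    uncovered_penalty: float = 100.0          # percent, per uncovered target point
    morph_largest_only: bool = False
    uphill_acceptance: float | None = None    # None -> Metropolis; 0 -> greedy
    pilot_moves: int = 20
    pilot_accept_prob: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.cooling_factor < 1.0):
            raise ValueError("cooling_factor must be in (0, 1)")
        if any(w < 0 for w in self.weights) or not any(w > 0 for w in self.weights):
            raise ValueError("weights must be >= 0 and not all zero")

    def to_dict(self) -> dict:
        d = {
            "n_iterations": self.n_iterations,
            "cooling_factor": self.cooling_factor,
            "moves_per_iteration": self.moves_per_iteration,
            "initial_temperature": self.initial_temperature,
            "sigma": self.sigma,
            "min_move_ratio": self.min_move_ratio,
            "weights": list(self.weights),
            "frozen": list(self.frozen),
            "s1_cl": self.s1_cl,
            "n_s1": self.n_s1,
            "s2_list": None if self.s2_list is None else list(self.s2_list),
            "tail": self.tail,
            "max_fit_points": self.max_fit_points,
            "uncovered_penalty": self.uncovered_penalty,
            "morph_largest_only": self.morph_largest_only,
            "uphill_acceptance": self.uphill_acceptance,
            "seed": self.seed,
        }
        if self.bounds is not None:
            d["bounds"] = {k: list(v) for k, v in self.bounds.items()}
        return d


@dataclass
class FitResult:
    """Best parameters found, error breakdown, and the annealing trace."""

    best_params: ModelParameters
    best_errors: ErrorBreakdown
    trace: list[dict]
    accepted_moves: int
    n_evaluations: int
    n_failures: int
    seed: int
    config: FitConfig

    def to_json(self, path: str | Path) -> None:
        payload = {
            "best_params": self.best_params.to_dict(),
            "best_errors": self.best_errors.to_dict(),
            "trace": self.trace,
            "accepted_moves": self.accepted_moves,
            "n_evaluations": self.n_evaluations,
            "n_failures": self.n_failures,
            "seed": self.seed,
            "config": self.config.to_dict(),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


# ---------------------------------------------------------------------------
# error functional
# ---------------------------------------------------------------------------

#: Edge tolerance (ms) when deciding whether a target DI is covered by the
#: simulated curve; absorbs sub-ms jitter of the realized DIs without
#: excusing genuinely missing coverage (capture failure removes tens of ms).
COVERAGE_TOL = 2.0


def _curve_percent_error(sim_xy: np.ndarray, tgt_xy: np.ndarray, penalty: float):
    """Mean percent error of a simulated curve against target points,
    interpolating the simulated curve in x; target points outside the
    simulated coverage (beyond a small edge tolerance) are charged
    ``penalty`` percent each."""
    tgt_xy = np.asarray(tgt_xy, dtype=float)
    if sim_xy.shape[0] < 2:
        return penalty, np.full(tgt_xy.shape[0], penalty)
    order = np.argsort(sim_xy[:, 0])
    sx, sy = sim_xy[order, 0], sim_xy[order, 1]
    errors = np.empty(tgt_xy.shape[0])
    for i, (x, y) in enumerate(tgt_xy):
        if x < sx[0] - COVERAGE_TOL or x > sx[-1] + COVERAGE_TOL:
            errors[i] = penalty
        else:
            y_sim = np.interp(x, sx, sy)  # clamps at the curve ends
            errors[i] = 100.0 * abs(y_sim - y) / abs(y)
    return float(errors.mean()), errors


def error_components(
    sim: S1S2Result,
    target: ClinicalDataset,
    weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 0.0),
    uncovered_penalty: float = 100.0,
    morph_largest_only: bool = False,
) -> ErrorBreakdown:
    """Percent-error breakdown of a simulated protocol against a target.

    ``e_apd``/``e_cv``: mean over target points of 100 |sim - tgt| / tgt,
    the simulated curve linearly interpolated in DI; target points outside
    the simulated DI range are charged ``uncovered_penalty``.  ``e_morph``:
    mean absolute difference (x100; voltages already in [0, 1]) on the
    unmasked part of the common grid, averaged over compared S2 shapes.
    ``total``: weighted mean of the components.
    """
    w_morph, w_apd, w_cv, w_up = weights
    pts = sim.captured_points()
    if not pts and not sim.points:
        raise ValueError("empty simulation result")

    sim_apd = np.array([[p.DI, p.APD] for p in pts if p.APD is not None])
    e_apd, res_apd = _curve_percent_error(
        sim_apd, target.apd_points, uncovered_penalty
    ) if sim_apd.size else (uncovered_penalty, None)

    sim_cv = np.array([[p.DI, p.CV] for p in pts if p.CV is not None])
    e_cv, res_cv = _curve_percent_error(
        sim_cv, target.cv_di_points, uncovered_penalty
    ) if sim_cv.size else (uncovered_penalty, None)

    grid = MorphologyShape.common_grid()
    mask = target.morphology.mask_on(grid)
    if not np.any(mask):
        raise ValueError("target morphology is fully masked")
    v_tgt = target.morphology.resample(grid)
    shapes = sim.morphologies
    if morph_largest_only and shapes:
        keys = [max(shapes)]
    else:
        keys = sorted(shapes)
    if keys:
        per_shape = [
            float(np.mean(100.0 * np.abs(shapes[k].resample(grid)[mask] - v_tgt[mask])))
            for k in keys
        ]
        e_morph = float(np.mean(per_shape))
    else:
        e_morph, per_shape = uncovered_penalty, []

    e_up = 0.0
    if w_up > 0:
        if target.upstroke_dt is None:
            raise ValueError("upstroke weight > 0 but target has no upstroke interval")
        if sim.upstroke_dt:
            dt_sim = sim.upstroke_dt[max(sim.upstroke_dt)]
            e_up = 100.0 * abs(dt_sim - target.upstroke_dt) / target.upstroke_dt
        else:
            e_up = uncovered_penalty

    num = w_morph * e_morph + w_apd * e_apd + w_cv * e_cv + w_up * e_up
    den = w_morph + w_apd + w_cv + w_up
    return ErrorBreakdown(
        e_morph=e_morph, e_apd=e_apd, e_cv=e_cv, e_upstroke=e_up,
        total=num / den,
        residuals={
            "apd": None if res_apd is None else res_apd.tolist(),
            "cv": None if res_cv is None else res_cv.tolist(),
            "morph_per_shape": per_shape,
        },
    )


# ---------------------------------------------------------------------------
# proposals
# ---------------------------------------------------------------------------

def default_bounds(init: ModelParameters) -> dict:
    """Per-parameter proposal bounds around the initial set.

    Scale parameters (time constants, steepnesses) may move by an order of
    magnitude in either direction; level parameters (thresholds, midpoints)
    move additively within half the unit interval, clipped to stay valid.
    """
    bounds: dict[str, tuple[float, float]] = {}
    for name in PARAM_ORDER:
        x0 = getattr(init, name)
        if name in MULTIPLICATIVE_PARAMS:
            bounds[name] = (0.1 * x0, 10.0 * x0)
        elif name == "u_u":
            bounds[name] = (max(init.theta_v + 0.01, x0 - 0.5), min(2.0, x0 + 0.5))
        else:
            bounds[name] = (max(0.0, x0 - 0.5), min(0.999, x0 + 0.5))
    return bounds


def propose(
    params: ModelParameters,
    T: float,
    T0: float,
    bounds: dict,
    rng: np.random.Generator,
    sigma: float = 0.3,
    frozen: tuple[str, ...] = DEFAULT_FROZEN,
    min_scale_ratio: float = 0.0,
) -> ModelParameters:
    """One annealing move: perturb every unfrozen parameter.

    Scale parameters move multiplicatively by exp(sigma (T/T0) N(0,1));
    level parameters move additively by sigma (T/T0) range N(0,1).  The
    temperature ratio shrinks the move size as the schedule cools;
    ``min_scale_ratio`` floors the shrinkage so that late iterations retain
    a finite refinement step (at low temperature uphill moves are rejected
    anyway, so the floor turns the late phase into a local descent instead
    of freezing the search).  Results are clipped to ``bounds``; frozen
    parameters are untouched.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    scale = sigma * max(T / T0, min_scale_ratio)
    frozen_set = set(frozen)
    for _ in range(50):
        d = params.to_dict()
        for name in PARAM_ORDER:
            if name in frozen_set:
                continue
            lo, hi = bounds[name]
            x = d[name]
            if name in MULTIPLICATIVE_PARAMS:
                x = x * math.exp(scale * rng.standard_normal())
            else:
                x = x + scale * (hi - lo) * rng.standard_normal()
            d[name] = min(max(x, lo), hi)
        try:
            return ModelParameters.from_dict(d)
        except InvalidParametersError:
            continue  # rare: bounds clipped into an invalid ordering; redraw
    return params


# ---------------------------------------------------------------------------
# annealing core
# ---------------------------------------------------------------------------

def anneal_core(
    energy,
    x0,
    step,
    rng: np.random.Generator,
    n_iterations: int = 50,
    cooling_factor: float = 0.9,
    moves_per_iteration: int = 20,
    T0: float | None = None,
    pilot_moves: int = 20,
    pilot_accept_prob: float = 0.8,
    uphill_acceptance: float | None = None,
    restart_on_cooling: bool = True,
):
    """Generic simulated-annealing loop over an arbitrary state space.

    ``energy(x)`` returns a scalar (may be inf for failed candidates);
    ``step(x, T, T0, rng)`` proposes a neighbor.  If ``T0`` is None it is
    auto-calibrated from a pilot so the median uphill move is accepted with
    probability ``pilot_accept_prob``.  With ``restart_on_cooling`` (the
    default, an elitist annealing variant) the working point is re-anchored
    at the best-so-far whenever the temperature is reduced, so the shrinking
    late-stage moves refine the best basin instead of diffusing on high
    plateaus.  Returns (best_x, best_E, trace, stats) with a per-iteration
    trace of (T, E_best, E_current, acceptance rate).
    """
    E0 = energy(x0)
    n_evals = 1
    n_failures = 0 if np.isfinite(E0) else 1

    if T0 is None:
        uphill = []
        for _ in range(pilot_moves):
            cand = step(x0, 1.0, 1.0, rng)
            E = energy(cand)
            n_evals += 1
            if not np.isfinite(E):
                n_failures += 1
                continue
            if E > E0:
                uphill.append(E - E0)
        if uphill:
            T0 = float(np.median(uphill) / math.log(1.0 / pilot_accept_prob))
        else:
            T0 = max(1.0, 0.1 * abs(E0)) if np.isfinite(E0) else 1.0

    current, E_cur = x0, E0
    best, E_best = x0, E0
    T = T0
    accepted = 0
    trace = []
    for _ in range(n_iterations):
        acc_iter = 0
        for _ in range(moves_per_iteration):
            cand = step(current, T, T0, rng)
            E = energy(cand)
            n_evals += 1
            if not np.isfinite(E):
                n_failures += 1
                continue
            dE = E - E_cur if np.isfinite(E_cur) else -1.0
            if dE <= 0:
                accept = True
            elif uphill_acceptance is not None:
                accept = rng.random() < uphill_acceptance
            else:
                accept = rng.random() < math.exp(-dE / T)
            if accept:
                current, E_cur = cand, E
                accepted += 1
                acc_iter += 1
                if E < E_best:
                    best, E_best = cand, E
        trace.append(
            {
                "T": T, "E_best": E_best, "E_current": E_cur,
                "acceptance_rate": acc_iter / moves_per_iteration,
            }
        )
        T *= cooling_factor
        if restart_on_cooling and E_cur > E_best:
            current, E_cur = best, E_best
    stats = {"accepted": accepted, "n_evaluations": n_evals, "n_failures": n_failures}
    return best, E_best, trace, stats


# ---------------------------------------------------------------------------
# full model fit
# ---------------------------------------------------------------------------

def derive_s2_list(target: ClinicalDataset, s1_cl: float, max_points: int = 8):
    """S2 coupling intervals aimed at the target's measured DIs.

    For each target (DI, APD) point the premature interval that would
    realize it is approximately S2 = DI + APD; the list is subsampled to
    ``max_points`` and clipped to the S1 cycle length.
    """
    pts = np.asarray(target.apd_points, dtype=float)
    s2 = np.unique(np.round(np.minimum(pts[:, 0] + pts[:, 1], s1_cl), 1))
    if s2.size > max_points:
        idx = np.linspace(0, s2.size - 1, max_points).round().astype(int)
        s2 = s2[np.unique(idx)]
    return tuple(float(x) for x in s2)


def simulate_for_target(
    params: ModelParameters,
    target: ClinicalDataset,
    cable: CableConfig,
    cfg: FitConfig,
) -> S1S2Result:
    """Run the S1-S2 protocol with the fit's probing S2 list."""
    s2_list = cfg.s2_list or derive_s2_list(target, cfg.s1_cl, cfg.max_fit_points)
    return s1s2_restitution(
        params, cable, s1_cl=cfg.s1_cl, n_s1=cfg.n_s1, s2_list=s2_list,
        tail=cfg.tail,
    )


def anneal(
    target: ClinicalDataset,
    init: ModelParameters,
    cfg: FitConfig,
    cable: CableConfig | None = None,
    log=None,
) -> FitResult:
    """Fit model parameters to a patient dataset by simulated annealing.

    Each candidate runs the full S1-S2 cable protocol and is scored by
    :func:`error_components`.  Candidates whose simulation blows up or
    fails the protocol receive infinite error (counted, never silently
    dropped).  Fully reproducible given ``cfg.seed``.
    """
    cable = cable or CableConfig()
    if cable.stim_amplitude is None:
        from .cable_sim import calibrate_stim_amplitude

        cable = replace(cable, stim_amplitude=calibrate_stim_amplitude(init, cable))
    rng = np.random.default_rng(cfg.seed)
    bounds = cfg.bounds or default_bounds(init)

    def energy(p: ModelParameters) -> float:
        try:
            sim = simulate_for_target(p, target, cable, cfg)
            return error_components(
                sim, target, cfg.weights, cfg.uncovered_penalty, cfg.morph_largest_only
            ).total
        except _SIM_FAILURES:
            return float("inf")

    def step(p: ModelParameters, T: float, T0: float, rng_) -> ModelParameters:
        return propose(p, T, T0, bounds, rng_, sigma=cfg.sigma, frozen=cfg.frozen,
                       min_scale_ratio=cfg.min_move_ratio)

    best, E_best, trace, stats = anneal_core(
        energy, init, step, rng,
        n_iterations=cfg.n_iterations,
        cooling_factor=cfg.cooling_factor,
        moves_per_iteration=cfg.moves_per_iteration,
        T0=cfg.initial_temperature,
        pilot_moves=cfg.pilot_moves,
        pilot_accept_prob=cfg.pilot_accept_prob,
        uphill_acceptance=cfg.uphill_acceptance,
    )
    if log is not None:
        for i, rec in enumerate(trace):
            log(
                f"iter {i + 1:3d}  T={rec['T']:.4g}  E_best={rec['E_best']:.4g}  "
                f"acc={rec['acceptance_rate']:.2f}"
            )

    sim_best = simulate_for_target(best, target, cable, cfg)
    breakdown = error_components(
        sim_best, target, cfg.weights, cfg.uncovered_penalty, cfg.morph_largest_only
    )
    return FitResult(
        best_params=best,
        best_errors=breakdown,
        trace=trace,
        accepted_moves=stats["accepted"],
        n_evaluations=stats["n_evaluations"],
        n_failures=stats["n_failures"],
        seed=cfg.seed,
        config=cfg,
    )
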