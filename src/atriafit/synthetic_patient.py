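"""Synthetic patient-style datasets.

The clinical recordings this pipeline was designed around (MAP-catheter
AP morphologies and pacing-derived restitution tables) are not publicly
available, so this module generates datasets with the same statistical
structure for development, testing and parameter-recovery studies:

* ``parametric`` mode draws the curves directly from a specified
  logarithmic APD restitution, a flat or drooping CV profile, and a
  morphology template bank, plus Gaussian measurement noise; and
* ``model_truth`` mode runs the full cable protocols on a known
  ground-truth parameter set, so a fit can be scored against the truth.

Emulated features of the clinical data: CL-independent normalized AP
shape with a masked initial artifact window, logarithmic APD restitution
with maximum APD in the 220-380 ms range and maximum slope ~0.6-1.2, and
CV restitution either flat or decreasing toward short DI.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .cable_sim import CableConfig
from .clinical_curves import ClinicalDataset, average_morphology
from .params import ModelParameters
from .restitution import MorphologyShape, s1s2_restitution

#: Clinical decremental pacing ladder: 50-ms steps to 300 ms, then 10-ms steps.
def clinical_cl_ladder(block_cl: float = 250.0) -> np.ndarray:
    cls = [500.0, 450.0, 400.0, 350.0, 300.0]
    cl = 290.0
    while cl >= block_cl:
        cls.append(cl)
        cl -= 10.0
    return np.asarray(cls)


MORPHOLOGY_TEMPLATES = ("plateau", "monotone", "triangular")


class InfeasibleSpecError(ValueError):
    """The requested curves cannot be realized on the pacing ladder."""


@dataclass(frozen=True)
class PatientSpec:
    """Specification of one synthetic patient.

    ``apd_max`` is the APD at the longest diastolic interval of the ladder
    (baseline CL 500 ms); ``max_slope`` the maximum restitution slope,
    attained at the shortest realized DI.  If ``apd_logfit`` is given it
    overrides both.  Noise standard deviations are per-channel defaults of
    realistic clinical magnitude.
    """

    mode: str = "parametric"            # parametric | model_truth
    label: str = "synthetic"
    apd_max: float = 300.0              # ms
    max_slope: float = 0.8
    slope_reference_di: float = 40.0    # ms, DI at which max_slope is anchored
    apd_logfit: tuple[float, float] | None = None
    cv_profile: str = "flat"            # flat | decreasing
    cv_level: float = 60.0              # cm/s
    cv_droop: float = 0.3               # fractional droop at shortest DI
    cv_droop_tau: float = 50.0          # ms, droop decay scale
    morphology_template: str = "plateau"
    truth_params: ModelParameters | None = None
    cable: CableConfig | None = None
    s1_cl: float = 500.0
    n_s1: int = 8
    s2_list: tuple[float, ...] | None = None
    noise_sd_apd: float = 5.0           # ms
    noise_sd_cv: float = 3.0            # cm/s
    noise_sd_morph: float = 0.0         # normalized units
    artifact_cutoff_ms: float = 10.0
    block_cl: float = 250.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("parametric", "model_truth"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (150.0 <= self.apd_max <= 450.0):
            raise InfeasibleSpecError(f"apd_max {self.apd_max} outside [150, 450] ms")
        if self.max_slope < 0:
            raise InfeasibleSpecError("max_slope must be >= 0")
        for name in ("noise_sd_apd", "noise_sd_cv", "noise_sd_morph"):
            if getattr(self, name) < 0:
                raise InfeasibleSpecError(f"{name} must be >= 0")
        if self.morphology_template not in MORPHOLOGY_TEMPLATES:
            raise ValueError(f"unknown morphology template {self.morphology_template!r}")


@dataclass
class GeneratedPatient:
    """A synthetic dataset together with its generating ground truth."""

    dataset: ClinicalDataset
    spec: PatientSpec
    truth_logfit: tuple[float, float] | None = None
    truth_params: ModelParameters | None = None
    truth_curves: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------

def _solve_di(cl: float, a: float, b: float) -> float:
    """DI consistent with steady pacing at CL: DI = CL - (a + b ln DI)."""
    f = lambda di: di + a + b * np.log(di) - cl
    lo, hi = 1e-3, cl
    if f(lo) > 0 or f(hi) < 0:
        raise InfeasibleSpecError(
            f"no consistent DI at CL={cl} ms for logfit (a={a:.1f}, b={b:.1f})"
        )
    return float(brentq(f, lo, hi))


def _derive_logfit(spec: PatientSpec, ladder: np.ndarray) -> tuple[float, float]:
    """(a, b) such that APD at the baseline-CL DI equals apd_max and the
    restitution slope b/DI equals ``max_slope`` at the reference DI.

    For APD = a + b ln(DI) the slope is b/DI, so anchoring the quoted
    maximum slope at ``slope_reference_di`` fixes b; the APD at the
    baseline cycle length (where DI = CL_max - apd_max under steady
    pacing) then fixes a.
    """
    if spec.apd_logfit is not None:
        return spec.apd_logfit
    di_max = ladder.max() - spec.apd_max
    if di_max <= 0:
        raise InfeasibleSpecError(
            f"apd_max {spec.apd_max} leaves no diastolic interval at CL {ladder.max()}"
        )
    b = spec.max_slope * spec.slope_reference_di
    a = spec.apd_max - b * np.log(di_max)
    return float(a), float(b)


def _template_shape(name: str, grid: np.ndarray) -> np.ndarray:
    """Morphology archetypes on normalized time, spanning the variety of
    clinical AP shapes: plateaued, spike-free monotone decay, triangular.
    All end at the 90%-repolarization level (0.1) at t = 1."""
    if name == "triangular":
        v = 1.0 - 0.9 * grid
    elif name == "monotone":
        v = 0.1 + 0.9 * (1.0 - grid) ** 1.6
    else:  # plateau
        f = (1.0 + np.tanh((0.72 - grid) / 0.18)) / 2.0
        v = 0.1 + 0.9 * (f - f[-1]) / (f[0] - f[-1])
    return v


def _cv_at(di: np.ndarray, spec: PatientSpec, di_min: float) -> np.ndarray:
    di = np.asarray(di, dtype=float)
    if spec.cv_profile == "flat":
        return np.full_like(di, spec.cv_level)
    if spec.cv_profile != "decreasing":
        raise ValueError(f"unknown cv_profile {spec.cv_profile!r}")
    return spec.cv_level * (
        1.0 - spec.cv_droop * np.exp(-(di - di_min) / spec.cv_droop_tau)
    )


def _generate_parametric(spec: PatientSpec) -> GeneratedPatient:
    rng = np.random.default_rng(spec.seed)
    ladder = clinical_cl_ladder(spec.block_cl)
    a, b = _derive_logfit(spec, ladder)

    di = np.array([_solve_di(cl, a, b) for cl in ladder])
    apd = a + b * np.log(di)
    if np.any(apd <= 0):
        raise InfeasibleSpecError("APD from logfit is non-positive on the ladder")
    cv = _cv_at(di, spec, di.min())

    apd_noisy = apd + rng.normal(0.0, spec.noise_sd_apd, apd.size)
    di_noisy = di + rng.normal(0.0, spec.noise_sd_apd, di.size)
    cv_noisy = cv + rng.normal(0.0, spec.noise_sd_cv, cv.size)

    grid = MorphologyShape.common_grid()
    v = _template_shape(spec.morphology_template, grid)
    if spec.noise_sd_morph > 0:
        v = v + rng.normal(0.0, spec.noise_sd_morph, v.size)
    lo, hi = float(v.min()), float(v.max())
    shape = MorphologyShape(
        t=grid,
        v=(v - lo) / (hi - lo),
        artifact_cutoff=spec.artifact_cutoff_ms / spec.apd_max,
    )

    dataset = ClinicalDataset(
        label=spec.label,
        morphology=shape,
        apd_points=np.column_stack([di, apd_noisy]),
        cv_cl_points=np.column_stack([ladder, cv_noisy]),
        di_cl_points=np.column_stack([ladder, di_noisy]),
        meta={"generator": "parametric", "seed": spec.seed},
    )
    return GeneratedPatient(
        dataset=dataset,
        spec=spec,
        truth_logfit=(a, b),
        truth_curves={"DI": di, "APD": apd, "CV": cv, "CL": ladder},
    )


def _generate_model_truth(spec: PatientSpec) -> GeneratedPatient:
    rng = np.random.default_rng(spec.seed)
    truth = spec.truth_params or ModelParameters()
    cable = spec.cable or CableConfig()
    res = s1s2_restitution(
        truth, cable, s1_cl=spec.s1_cl, n_s1=spec.n_s1, s2_list=spec.s2_list,
        artifact_cutoff_ms=0.0,
    )
    pts = res.captured_points()
    if len(pts) < 3:
        raise InfeasibleSpecError("truth parameters capture fewer than 3 S2 beats")
    di = np.array([p.DI for p in pts])
    apd = np.array([p.APD for p in pts])
    cv = np.array([p.CV for p in pts])
    s2 = np.array([p.CL for p in pts])

    shape = average_morphology(
        [res.morphologies[p.CL] for p in pts if p.CL in res.morphologies]
    )
    if spec.noise_sd_morph > 0:
        v = shape.v + rng.normal(0.0, spec.noise_sd_morph, shape.v.size)
        shape = MorphologyShape(
            t=shape.t, v=np.clip(v, 0.0, 1.0), artifact_cutoff=shape.artifact_cutoff
        )
    apd_noisy = apd + rng.normal(0.0, spec.noise_sd_apd, apd.size)
    cv_noisy = cv + rng.normal(0.0, spec.noise_sd_cv, cv.size)

    largest_s2 = float(s2.max())
    dataset = ClinicalDataset(
        label=spec.label,
        morphology=shape,
        apd_points=np.column_stack([di, apd_noisy]),
        cv_cl_points=np.column_stack([s2, cv_noisy]),
        di_cl_points=np.column_stack([s2, di]),
        cv_di_points=np.column_stack([di, cv_noisy]),
        upstroke_dt=res.upstroke_dt.get(largest_s2),
        meta={
            "generator": "model_truth",
            "seed": spec.seed,
            "truth_params": truth.to_dict(),
            "s1_cl": spec.s1_cl,
            "n_s1": spec.n_s1,
            "s2_list": [p.CL for p in pts],
        },
    )
    return GeneratedPatient(
        dataset=dataset,
        spec=spec,
        truth_params=truth,
        truth_curves={"DI": di, "APD": apd, "CV": cv, "S2": s2},
    )


def generate_patient(spec: PatientSpec) -> GeneratedPatient:
    """Generate one synthetic patient dataset (deterministic given seed)."""
    if spec.mode == "parametric":
        return _generate_parametric(spec)
    return _generate_model_truth(spec)
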