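"""Pacing protocols and trace analysis.

Turns cable recordings into the quantities the clinical data report:
activation times, APD90, diastolic interval, conduction velocity,
normalized AP morphology and the upstroke interval, via the two pacing
protocols used clinically (S1-S2 premature stimulation and the
decremental dynamic ladder).
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .cable_sim import CableConfig, calibrate_stim_amplitude, run_cable
from .params import ModelParameters

#: Common normalized-time grid for all morphology comparisons.
MORPHOLOGY_GRID_POINTS = 200


class ProtocolError(RuntimeError):
    """A pacing protocol could not be completed (e.g. S1 failure to capture)."""


class UnresolvedAPDError(RuntimeError):
    """The trace does not repolarize to 90% before the beat window ends."""


@dataclass(frozen=True)
class RestitutionPoint:
    """One beat on a restitution curve.

    ``DI`` is the diastolic interval preceding the beat, ``APD`` the
    beat's APD90, ``CV`` its conduction velocity (cm/s, None when not
    measured or not captured), ``CL`` the pacing interval (S2 coupling
    interval for premature beats).  ``captured`` is False for beats that
    failed to propagate; such points are flagged, never dropped silently.
    """

    DI: float
    APD: float | None
    CV: float | None
    CL: float
    captured: bool = True


@dataclass
class MorphologyShape:
    """Normalized AP shape: time 0 (activation) to 1 (90% repolarization),
    voltage min-max rescaled to [0, 1].  ``artifact_cutoff`` is the
    normalized time below which samples are considered stimulus artifact
    and excluded from comparisons."""

    t: np.ndarray
    v: np.ndarray
    artifact_cutoff: float = 0.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.v.shape:
            raise ValueError("t and v must be 1D arrays of equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")

    def resample(self, grid: np.ndarray) -> np.ndarray:
        return np.interp(grid, self.t, self.v)

    @staticmethod
    def common_grid(n: int = MORPHOLOGY_GRID_POINTS) -> np.ndarray:
        return np.linspace(0.0, 1.0, n)

    def on_common_grid(self, n: int = MORPHOLOGY_GRID_POINTS) -> np.ndarray:
        return self.resample(self.common_grid(n))

    def mask_on(self, grid: np.ndarray) -> np.ndarray:
        """Boolean mask of grid points outside the artifact window."""
        return grid >= self.artifact_cutoff


@dataclass
class S1S2Result:
    """Output of the S1-S2 protocol: restitution points plus the premature
    beat's morphology per S2 coupling interval."""

    points: list[RestitutionPoint]
    morphologies: dict[float, MorphologyShape]
    upstroke_dt: dict[float, float]
    s1_cl: float

    def captured_points(self) -> list[RestitutionPoint]:
        return [p for p in self.points if p.captured]


# ---------------------------------------------------------------------------
# trace analysis primitives
# ---------------------------------------------------------------------------

def activation_times(
    times: np.ndarray,
    values: np.ndarray,
    threshold: float = 0.2,
    refractory: float = 50.0,
) -> np.ndarray:
    """Upward crossings of ``threshold``, linearly interpolated between
    samples, with a ``refractory`` guard (ms) between detections."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size == 0:
        raise ValueError("empty trace")
    below = values[:-1] < threshold
    above = values[1:] >= threshold
    idx = np.nonzero(below & above)[0]
    out: list[float] = []
    last = -np.inf
    for i in idx:
        frac = (threshold - values[i]) / (values[i + 1] - values[i])
        t_cross = times[i] + frac * (times[i + 1] - times[i])
        if t_cross - last > refractory:
            out.append(t_cross)
            last = t_cross
    return np.asarray(out)


def _beat_window(times, activation_time, next_activation):
    i0 = int(np.searchsorted(times, activation_time))
    i1 = times.size if next_activation is None else int(np.searchsorted(times, next_activation))
    return i0, i1


def _baseline(times, values, activation_time, i0, i1, lookback=100.0):
    # strictly pre-upstroke samples; fall back to the beat minimum when the
    # beat starts at the trace edge
    pre = (times >= activation_time - lookback) & (times < activation_time)
    if np.any(pre):
        return float(values[pre].min())
    return float(values[i0:i1].min())


def apd90(
    times: np.ndarray,
    values: np.ndarray,
    activation_time: float,
    next_activation: float | None = None,
    lookback: float = 100.0,
) -> float:
    """APD at 90% repolarization.

    Duration from ``activation_time`` until the voltage first falls below
    baseline + 0.1 x (peak - baseline), where the peak is the beat maximum
    and the baseline the pre-upstroke minimum (window ``lookback`` ms before
    activation; beat minimum if no earlier samples exist).  Sub-sample
    linear interpolation at the crossing.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    i0, i1 = _beat_window(times, activation_time, next_activation)
    if i1 - i0 < 2:
        raise UnresolvedAPDError("beat window contains fewer than 2 samples")
    seg_t, seg_v = times[i0:i1], values[i0:i1]
    base = _baseline(times, values, activation_time, i0, i1, lookback)
    ipk = int(np.argmax(seg_v))
    peak = float(seg_v[ipk])
    if peak <= base:
        raise UnresolvedAPDError("beat has no positive amplitude")
    level = base + 0.1 * (peak - base)
    vv = seg_v[ipk:]
    cross = np.nonzero((vv[:-1] >= level) & (vv[1:] < level))[0]
    if cross.size == 0:
        raise UnresolvedAPDError(
            f"no 90% repolarization before the beat window ends (level={level:.3f})"
        )
    i = ipk + int(cross[0])
    frac = (seg_v[i] - level) / (seg_v[i] - seg_v[i + 1])
    t90 = seg_t[i] + frac * (seg_t[i + 1] - seg_t[i])
    return float(t90 - activation_time)


def conduction_velocity(t_a: float, t_b: float, distance: float) -> float:
    """CV = distance / (t_b - t_a), in cm/s (inputs: ms, cm)."""
    if distance <= 0:
        raise ValueError("distance must be positive")
    if t_b <= t_a:
        raise ValueError(
            f"retrograde or absent propagation: t_b={t_b} <= t_a={t_a}"
        )
    return distance / (t_b - t_a) * 1000.0


def upstroke_interval(
    times: np.ndarray,
    values: np.ndarray,
    activation_time: float,
    next_activation: float | None = None,
    lookback: float = 20.0,
) -> float:
    """Interval from 10% to 100% (peak) of the beat's upstroke amplitude.

    The 10% point is the first upward crossing of baseline + 0.1 x amplitude
    in a window starting ``lookback`` ms before the detected activation
    (the 10% point precedes the activation-threshold crossing); the 100%
    point is the global beat peak.  Noisy, non-monotone upstrokes are
    handled by taking the first crossing and the global peak.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    j0 = int(np.searchsorted(times, activation_time - lookback))
    i0, i1 = _beat_window(times, activation_time, next_activation)
    if i1 - j0 < 2:
        raise ValueError("beat window too short for upstroke analysis")
    seg_t, seg_v = times[j0:i1], values[j0:i1]
    base = float(seg_v[: max(1, i0 - j0 + 1)].min())
    ipk = int(np.argmax(seg_v))
    peak = float(seg_v[ipk])
    if peak <= base:
        raise ValueError("beat has no rising phase")
    level = base + 0.1 * (peak - base)
    vv = seg_v[: ipk + 1]
    cross = np.nonzero((vv[:-1] < level) & (vv[1:] >= level))[0]
    if cross.size == 0:
        # upstroke faster than one sample: report one sample interval
        return float(seg_t[min(ipk, 1)] - seg_t[0]) if ipk > 0 else 0.0
    i = int(cross[0])
    frac = (level - seg_v[i]) / (seg_v[i + 1] - seg_v[i])
    t10 = seg_t[i] + frac * (seg_t[i + 1] - seg_t[i])
    return float(seg_t[ipk] - t10)


def normalize_morphology(
    times: np.ndarray,
    values: np.ndarray,
    artifact_cutoff_ms: float = 0.0,
    activation_time: float | None = None,
    next_activation: float | None = None,
) -> MorphologyShape:
    """Min-max normalized AP shape on the normalized time axis.

    Voltage is rescaled to span [0, 1] (invariant under affine transforms
    of the trace); time is rescaled so that the activation maps to 0 and
    90% repolarization to 1.  Samples earlier than ``artifact_cutoff_ms``
    after activation are flagged as stimulus artifact via the shape's
    normalized ``artifact_cutoff``.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if activation_time is None:
        base0, peak0 = float(values.min()), float(values.max())
        if peak0 <= base0:
            raise ValueError("zero-amplitude trace")
        acts = activation_times(times, values, threshold=base0 + 0.2 * (peak0 - base0))
        if acts.size == 0:
            raise ValueError("no activation found in segment")
        activation_time = float(acts[0])
    apd = apd90(times, values, activation_time, next_activation)
    i0, i1 = _beat_window(times, activation_time, next_activation)
    base = _baseline(times, values, activation_time, i0, i1)
    seg_t, seg_v = times[i0:i1], values[i0:i1]
    peak = float(seg_v.max())
    if peak <= base:
        raise ValueError("zero-amplitude beat")
    t_norm = (seg_t - activation_time) / apd
    keep = (t_norm >= 0.0) & (t_norm <= 1.0)
    v_norm = (seg_v[keep] - base) / (peak - base)
    return MorphologyShape(
        t=t_norm[keep],
        v=np.clip(v_norm, 0.0, 1.0),
        artifact_cutoff=artifact_cutoff_ms / apd,
    )


# ---------------------------------------------------------------------------
# pacing protocols
# ---------------------------------------------------------------------------

def _with_amplitude(params: ModelParameters, cfg: CableConfig) -> CableConfig:
    if cfg.stim_amplitude is None:
        return replace(cfg, stim_amplitude=calibrate_stim_amplitude(params, cfg))
    return cfg


def s1s2_restitution(
    params: ModelParameters,
    cfg: CableConfig,
    s1_cl: float = 500.0,
    n_s1: int = 8,
    s2_list=None,
    artifact_cutoff_ms: float = 0.0,
    tail: float = 600.0,
) -> S1S2Result:
    """S1-S2 premature-stimulation protocol on the cable.

    Paces ``n_s1`` conditioning beats at ``s1_cl``, then delivers a single
    premature S2 at each coupling interval in ``s2_list`` (each S2 restarts
    from a snapshot of the state after the conditioning train, so the S1
    phase is simulated once).  For each S2 the premature beat's APD90, CV
    (between the two CV electrodes) and morphology at the distal site are
    measured; DI = S2 - APD90 of the final S1 beat at the distal site.
    When ``s2_list`` is None, a ladder from ``s1_cl`` down in 20-ms steps
    (10-ms below 300 ms) runs until loss of capture.
    """
    if n_s1 < 8:
        raise ValueError("need at least 8 conditioning S1 beats")
    cfg = _with_amplitude(params, cfg)
    distal = cfg.distal_site
    site_a, site_b = cfg.cv_sites
    dist = (site_b - site_a) * cfg.dx

    # conditioning phase: stimuli 0 .. (n_s1-2)*CL; the final S1 stimulus is
    # delivered in each per-S2 continuation so its beat is fully recorded.
    t_snap = (n_s1 - 1) * s1_cl
    cfg_a = replace(cfg, record_every=max(1, int(round(1.0 / cfg.dt))))
    rec_a = run_cable(params, cfg_a, [k * s1_cl for k in range(n_s1 - 1)], t_snap)
    if rec_a.activation_times[distal].size < n_s1 - 1:
        raise ProtocolError(
            f"S1 train failed to capture: {rec_a.activation_times[distal].size} of "
            f"{n_s1 - 1} conditioning beats reached the distal site"
        )
    snapshot = tuple(a.copy() for a in rec_a.final_state)

    if s2_list is None:
        s2_iter = _s2_ladder(s1_cl)
        stop_on_failure = True
    else:
        s2_iter = list(s2_list)
        stop_on_failure = False

    points: list[RestitutionPoint] = []
    morphologies: dict[float, MorphologyShape] = {}
    upstrokes: dict[float, float] = {}
    for s2 in s2_iter:
        point, shape, dt_up = _run_single_s2(
            params, cfg, snapshot, t_snap, s1_cl, s2, dist,
            distal, site_a, site_b, artifact_cutoff_ms, tail,
        )
        points.append(point)
        if shape is not None:
            morphologies[s2] = shape
        if dt_up is not None:
            upstrokes[s2] = dt_up
        if stop_on_failure and not point.captured:
            break
    return S1S2Result(points=points, morphologies=morphologies,
                      upstroke_dt=upstrokes, s1_cl=s1_cl)


def _s2_ladder(s1_cl: float):
    """S2 coupling intervals from the S1 CL down: 20-ms steps to 300 ms,
    then 10-ms steps (mirrors the clinical ladder granularity)."""
    s2 = s1_cl
    while s2 > 0:
        yield s2
        s2 -= 20.0 if s2 > 300.0 else 10.0


def _run_single_s2(params, cfg, snapshot, t_snap, s1_cl, s2, dist,
                   distal, site_a, site_b, artifact_cutoff_ms, tail):
    state = tuple(a.copy() for a in snapshot)
    t_end = t_snap + s2 + tail
    rec = run_cable(params, cfg, [t_snap, t_snap + s2], t_end,
                    initial_state=state, t_start=t_snap)
    acts = rec.activation_times[distal]
    tr_t, tr_v = rec.times, rec.trace(distal)
    if acts.size < 1:
        return RestitutionPoint(DI=np.nan, APD=None, CV=None, CL=s2, captured=False), None, None
    apd_s1 = apd90(tr_t, tr_v, acts[0], acts[1] if acts.size > 1 else None)
    di = s2 - apd_s1
    if acts.size < 2:
        return RestitutionPoint(DI=di, APD=None, CV=None, CL=s2, captured=False), None, None
    apd_s2 = apd90(tr_t, tr_v, acts[1])
    a_acts = rec.activation_times[site_a]
    b_acts = rec.activation_times[site_b]
    cv = None
    if a_acts.size >= 2 and b_acts.size >= 2:
        cv = conduction_velocity(a_acts[1], b_acts[1], dist)
    shape = normalize_morphology(tr_t, tr_v, artifact_cutoff_ms, activation_time=acts[1])
    dt_up = upstroke_interval(tr_t, tr_v, acts[1])
    return RestitutionPoint(DI=di, APD=apd_s2, CV=cv, CL=s2), shape, dt_up


DEFAULT_CL_LADDER = (500.0, 450.0, 400.0, 350.0, 300.0)


def dynamic_pacing_protocol(
    params: ModelParameters,
    cfg: CableConfig,
    beats_per_cl: int = 85,
    cl_ladder=DEFAULT_CL_LADDER,
    decrement: float = 10.0,
    min_cl: float = 100.0,
    n_measure: int = 3,
) -> list[RestitutionPoint]:
    """Decremental ("dynamic") pacing ladder.

    Paces ``beats_per_cl`` beats at each CL of the clinical ladder
    (500, 450, 400, 350, 300 ms), then continues in ``decrement``-ms steps
    until capture failure — defined as a stimulus with no activation at the
    distal site within one CL (2:1 block).  For each completed CL the mean
    APD90/DI/CV over the final ``n_measure`` beats is recorded; on failure
    at CL*, all recorded points have CL > CL*.  Tissue state carries over
    between CL stages, as in the clinical protocol.
    """
    cfg = _with_amplitude(params, cfg)
    cfg = replace(cfg, record_every=max(1, int(round(0.5 / cfg.dt))))
    distal = cfg.distal_site
    site_a, site_b = cfg.cv_sites
    dist = (site_b - site_a) * cfg.dx

    cls = list(cl_ladder)
    next_cl = cls[-1] - decrement
    while next_cl >= min_cl:
        cls.append(next_cl)
        next_cl -= decrement

    points: list[RestitutionPoint] = []
    state = None
    t0 = 0.0
    for cl in cls:
        stims = t0 + cl * np.arange(beats_per_cl)
        t_end = t0 + cl * beats_per_cl
        rec = run_cable(params, cfg, stims, t_end, initial_state=state, t_start=t0)
        acts = rec.activation_times[distal]
        captured = all(
            np.any((acts > t_s) & (acts <= t_s + cl)) for t_s in stims
        )
        if not captured:
            break
        tr_t, tr_v = rec.times, rec.trace(distal)
        apds, dis = [], []
        for k in range(max(0, acts.size - n_measure - 1), acts.size - 1):
            a = apd90(tr_t, tr_v, acts[k], acts[k + 1])
            apds.append(a)
            dis.append(acts[k + 1] - (acts[k] + a))
        a_acts = rec.activation_times[site_a]
        b_acts = rec.activation_times[site_b]
        cv = conduction_velocity(a_acts[-1], b_acts[-1], dist)
        points.append(
            RestitutionPoint(DI=float(np.mean(dis)), APD=float(np.mean(apds)),
                             CV=cv, CL=cl)
        )
        state = tuple(a.copy() for a in rec.final_state)
        t0 = rec.t_end
    return points
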