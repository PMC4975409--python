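"""2D isotropic sheet simulation, spiral initiation and tip analysis.

Spiral-wave reentry is initiated by cross-activation: a planar S1 wave is
launched from one edge and a premature S2 stimulus is applied to a
quadrant of the sheet inside the S1 repolarization wake, creating a free
wave end that curls into a rotor.  Spiral tips are located as the
intersections of the u = u_iso isopotential line with the du/dt = 0
contour (frame differencing), the classic isopotential-intersection
method; tips are linked into trajectories by nearest-neighbor gating.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from shapely.geometry import MultiLineString
from skimage import measure

from . import _kernels
from .cable_sim import CableConfig, ConfigError, InstabilityError, calibrate_stim_amplitude
from .ionic_model import resting_state
from .params import ModelParameters
from .restitution import activation_times


@dataclass(frozen=True)
class Grid2DConfig:
    """Geometry, discretization and cross-field stimulation of the sheet."""

    side: float = 9.6           # cm (square sheet)
    dx: float = 0.02            # cm
    dt: float = 0.01            # ms
    D: float = 0.001            # cm^2/ms
    total_time: float = 2000.0  # ms
    frame_interval: float = 1.0  # ms
    probe: tuple[float, float] = (0.75, 0.75)  # fractions of side (x, y)
    probe_interval: float = 1.0  # ms
    s1_width: float = 0.06      # cm, stimulated strip at the x=0 edge
    s2_time: float | None = None  # ms; None -> auto-scan of the S1 wake
    s2_fraction: tuple[float, float] = (0.5, 0.5)  # quadrant (x, y extent)
    stim_amplitude: float | None = None
    stim_duration: float = 2.0  # ms

    def __post_init__(self) -> None:
        if self.dx <= 0 or self.dt <= 0 or self.D <= 0 or self.side <= 0:
            raise ConfigError("side, dx, dt and D must be positive")
        if self.D * self.dt / self.dx**2 >= 0.25:
            raise ConfigError(
                f"unstable 2D discretization: D*dt/dx^2 = "
                f"{self.D * self.dt / self.dx ** 2:.3f} >= 0.25"
            )

    @property
    def n(self) -> int:
        return int(round(self.side / self.dx))

    def to_dict(self) -> dict:
        return {
            "side": self.side, "dx": self.dx, "dt": self.dt, "D": self.D,
            "total_time": self.total_time, "frame_interval": self.frame_interval,
            "probe": list(self.probe), "probe_interval": self.probe_interval,
            "s1_width": self.s1_width, "s2_time": self.s2_time,
            "s2_fraction": list(self.s2_fraction),
            "stim_amplitude": self.stim_amplitude,
            "stim_duration": self.stim_duration,
        }


@dataclass
class SheetResult:
    """Voltage frames and probe traces from one sheet run."""

    frames: np.ndarray          # (n_frames, ny, nx) float32
    frame_times: np.ndarray     # ms
    probe_times: np.ndarray
    probe_trace: np.ndarray
    config: Grid2DConfig
    s2_time: float | None

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("frames", data=self.frames, compression="gzip")
            fh.create_dataset("frame_times", data=self.frame_times)
            fh.create_dataset("probe_times", data=self.probe_times)
            fh.create_dataset("probe_trace", data=self.probe_trace)
            fh.attrs["config"] = json.dumps(self.config.to_dict())
            fh.attrs["s2_time"] = -1.0 if self.s2_time is None else self.s2_time


@dataclass
class TipTrajectory:
    """Per-frame spiral-tip detections and linked trajectories."""

    times: np.ndarray                  # ms, one per analyzed frame
    tips_per_frame: list[np.ndarray]   # each (k, 2) of (x, y) cm
    tracks: list[tuple[np.ndarray, np.ndarray]]  # (times, (k,2) positions)
    dx: float

    @property
    def counts(self) -> np.ndarray:
        return np.array([t.shape[0] for t in self.tips_per_frame])

    @property
    def main_track(self) -> tuple[np.ndarray, np.ndarray] | None:
        if not self.tracks:
            return None
        return max(self.tracks, key=lambda tr: tr[0][-1] - tr[0][0])

    def to_csv(self, path) -> None:
        import pandas as pd

        rows = []
        for ti, tips in zip(self.times, self.tips_per_frame):
            if tips.shape[0] == 0:
                rows.append({"t_ms": ti, "x_cm": np.nan, "y_cm": np.nan,
                             "n_tips": 0})
            for x, y in tips:
                rows.append({"t_ms": ti, "x_cm": x, "y_cm": y,
                             "n_tips": tips.shape[0]})
        pd.DataFrame(rows).to_csv(path, index=False)


def run_2d(params: ModelParameters, cfg: Grid2DConfig) -> SheetResult:
    """Cross-activation sheet run.

    S1 planar wave from the x = 0 edge at t = 0; S2 over the configured
    quadrant at ``cfg.s2_time`` (auto-scanned across the S1 wake when
    None).  No-flux mirror-ghost boundaries on all edges.  If the S2 lands
    outside the vulnerable window the run completes normally and the
    downstream classification reports no reentry.
    """
    if cfg.s2_time is None:
        s2_time, result = scan_s2_times(params, cfg)
        return result

    amp = cfg.stim_amplitude
    if amp is None:
        amp = calibrate_stim_amplitude(
            params, CableConfig(dx=cfg.dx, dt=cfg.dt, D=cfg.D)
        )
        cfg = replace(cfg, stim_amplitude=amp)

    n = cfg.n
    rest = resting_state(params)
    u = np.full((n, n), rest.u)
    v = np.full((n, n), rest.v)
    w = np.full((n, n), rest.w)
    s = np.full((n, n), rest.s)

    n_steps = int(round(cfg.total_time / cfg.dt))
    frame_every = max(1, int(round(cfg.frame_interval / cfg.dt)))
    probe_every = max(1, int(round(cfg.probe_interval / cfg.dt)))
    n_frames = n_steps // frame_every + 1
    n_probe_samples = n_steps // probe_every + 1
    frames = np.empty((n_frames, n, n), dtype=np.float32)
    frame_times = np.empty(n_frames)
    probe_traces = np.empty((1, n_probe_samples))
    probe_times = np.empty(n_probe_samples)
    pi = min(n - 1, int(round(cfg.probe[1] * cfg.side / cfg.dx)))
    pj = min(n - 1, int(round(cfg.probe[0] * cfg.side / cfg.dx)))

    s1_cols = max(1, int(round(cfg.s1_width / cfg.dx)))
    s2_i1 = int(round(cfg.s2_fraction[1] * n))
    s2_j1 = int(round(cfg.s2_fraction[0] * n))

    status, t_fail = _kernels.simulate_sheet(
        u, v, w, s, params.to_vector(),
        cfg.dx, cfg.dt, cfg.D,
        n_steps, 0.0,
        0.0, cfg.stim_duration, s1_cols,
        cfg.s2_time, cfg.stim_duration,
        0, s2_i1, 0, s2_j1,
        amp,
        frame_every, frames, frame_times,
        np.array([pi], dtype=np.int64), np.array([pj], dtype=np.int64),
        probe_every, probe_traces, probe_times,
    )
    if status != 0:
        raise InstabilityError(f"sheet simulation blew up at t = {t_fail:.2f} ms", t_fail)
    return SheetResult(
        frames=frames, frame_times=frame_times,
        probe_times=probe_times, probe_trace=probe_traces[0],
        config=cfg, s2_time=cfg.s2_time,
    )


def scan_s2_times(params: ModelParameters, cfg: Grid2DConfig, candidates=None):
    """Scan S2 timings across the S1 wake for the earliest sustained reentry.

    The candidate window is centered on the 90%-repolarization time of the
    S2-region corner farthest from the S1 edge, stepped in 10-ms increments.
    Returns (s2_time, SheetResult) of the first run classified as sustained
    (stable or breakup); raises ProtocolError when no candidate reenters.
    """
    from .restitution import ProtocolError, apd90

    amp = cfg.stim_amplitude
    if amp is None:
        amp = calibrate_stim_amplitude(params, CableConfig(dx=cfg.dx, dt=cfg.dt, D=cfg.D))
    cfg = replace(cfg, stim_amplitude=amp)

    if candidates is None:
        # S1-only pilot probing the S2 quadrant's far corner
        probe_frac = (max(0.05, cfg.s2_fraction[0] - 0.05),
                      max(0.05, cfg.s2_fraction[1] / 2))
        pilot_cfg = replace(
            cfg, s2_time=1e9, total_time=min(cfg.total_time, 800.0),
            frame_interval=cfg.total_time, probe=probe_frac,
        )
        pilot = run_2d(params, pilot_cfg)
        acts = activation_times(pilot.probe_times, pilot.probe_trace)
        if acts.size == 0:
            raise ProtocolError("S1 wave did not reach the S2 region")
        t90 = acts[0] + apd90(pilot.probe_times, pilot.probe_trace, acts[0])
        candidates = np.arange(t90 - 30.0, t90 + 61.0, 10.0)

    last = None
    for t_s2 in candidates:
        result = run_2d(params, replace(cfg, s2_time=float(t_s2)))
        traj = track_tips(result.frames, result.frame_times, cfg.dx)
        label = classify_dynamics(
            traj, run_length=cfg.total_time, s2_time=float(t_s2)
        )
        last = result
        if label in ("stable", "breakup"):
            return float(t_s2), result
    raise ProtocolError(
        f"no S2 timing in {candidates} produced sustained reentry"
    )


# ---------------------------------------------------------------------------
# tip tracking
# ---------------------------------------------------------------------------

def _frame_tips(frame, prev_frame, u_iso, dx):
    """Intersections of the u = u_iso isoline with the du/dt = 0 contour."""
    f = frame.astype(float) - u_iso
    g = frame.astype(float) - prev_frame.astype(float)
    if f.min() >= 0 or f.max() <= 0 or g.min() >= 0 or g.max() <= 0:
        return np.empty((0, 2))
    iso_u = measure.find_contours(f, 0.0)
    iso_dudt = measure.find_contours(g, 0.0)
    if not iso_u or not iso_dudt:
        return np.empty((0, 2))
    mls_u = MultiLineString([c[:, ::-1] for c in iso_u if c.shape[0] > 1])
    mls_g = MultiLineString([c[:, ::-1] for c in iso_dudt if c.shape[0] > 1])
    inter = mls_u.intersection(mls_g)
    pts = []
    if inter.is_empty:
        return np.empty((0, 2))
    geoms = getattr(inter, "geoms", [inter])
    for geom in geoms:
        if geom.geom_type == "Point":
            pts.append((geom.x, geom.y))
        elif hasattr(geom, "coords"):
            xs, ys = np.array(geom.coords).mean(axis=0)
            pts.append((xs, ys))
    return np.asarray(pts) * dx if pts else np.empty((0, 2))


def track_tips(
    frames: np.ndarray,
    frame_times: np.ndarray,
    dx: float,
    u_iso: float = 0.5,
    gate: float = 0.3,
    start_time: float | None = None,
    max_gap: int = 2,
) -> TipTrajectory:
    """Locate and link spiral tips across a frame stack.

    Tips in each frame are the intersection points of the ``u = u_iso``
    isoline with the zero contour of the frame difference (du/dt = 0),
    located by the contour geometry with sub-cell interpolation.  Linking
    is greedy nearest-neighbor with a ``gate`` (cm) radius; a track
    survives up to ``max_gap`` consecutive frames without a detection
    (tip localization can flicker near wavefront-waveback collisions);
    unmatched detections start new tracks.
    """
    if frames.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    times = []
    tips_per_frame = []
    open_tracks: list[dict] = []
    closed: list[dict] = []
    for k in range(1, frames.shape[0]):
        t = frame_times[k]
        if start_time is not None and t < start_time:
            continue
        tips = _frame_tips(frames[k], frames[k - 1], u_iso, dx)
        times.append(t)
        tips_per_frame.append(tips)
        # greedy NN assignment tips <-> open tracks
        unmatched = list(range(tips.shape[0]))
        used_t: set[int] = set()
        if open_tracks and unmatched:
            pairs = []
            for ti, tr in enumerate(open_tracks):
                last = tr["xy"][-1]
                for di in unmatched:
                    d = float(np.hypot(*(tips[di] - last)))
                    if d <= gate:
                        pairs.append((d, ti, di))
            pairs.sort()
            used_d: set[int] = set()
            for d, ti, di in pairs:
                if ti in used_t or di in used_d:
                    continue
                open_tracks[ti]["t"].append(t)
                open_tracks[ti]["xy"].append(tips[di])
                open_tracks[ti]["misses"] = 0
                used_t.add(ti)
                used_d.add(di)
            unmatched = [di for di in unmatched if di not in used_d]
        still_open = []
        for ti, tr in enumerate(open_tracks):
            if ti in used_t:
                still_open.append(tr)
            else:
                tr["misses"] = tr.get("misses", 0) + 1
                if tr["misses"] <= max_gap:
                    still_open.append(tr)
                else:
                    closed.append(tr)
        open_tracks = still_open
        for di in unmatched:
            open_tracks.append({"t": [t], "xy": [tips[di]], "misses": 0})
    closed.extend(open_tracks)
    tracks = [
        (np.asarray(tr["t"]), np.asarray(tr["xy"]))
        for tr in closed
        if len(tr["t"]) >= 2
    ]
    return TipTrajectory(
        times=np.asarray(times), tips_per_frame=tips_per_frame,
        tracks=tracks, dx=dx,
    )


# ---------------------------------------------------------------------------
# rotation period and classification
# ---------------------------------------------------------------------------

@dataclass
class PeriodEstimate:
    """Rotation-period estimates; None marks an unsustained rotor."""

    probe_period: float | None = None
    tip_period: float | None = None
    n_probe_cycles: int = 0
    tip_windings: float = 0.0


def rotation_period_from_probe(
    times: np.ndarray,
    values: np.ndarray,
    threshold: float = 0.5,
    final_fraction: float = 2.0 / 3.0,
    refractory: float = 40.0,
) -> tuple[float | None, int]:
    """Mean inter-activation interval at a point probe over the final
    fraction of the run; (None, n) when fewer than 3 activations."""
    times = np.asarray(times, dtype=float)
    t_lo = times[-1] - final_fraction * (times[-1] - times[0])
    keep = times >= t_lo
    acts = activation_times(times[keep], np.asarray(values)[keep],
                            threshold=threshold, refractory=refractory)
    if acts.size < 3:
        return None, int(acts.size)
    return float(np.mean(np.diff(acts))), int(acts.size)


def _rotation_center(xy: np.ndarray) -> np.ndarray:
    """Least-squares circle center (Kasa fit); the raw centroid is biased
    when the track covers a non-integer number of revolutions.  Falls back
    to the centroid for degenerate (collinear) tracks."""
    A = np.column_stack([2 * xy[:, 0], 2 * xy[:, 1], np.ones(xy.shape[0])])
    b = (xy**2).sum(axis=1)
    try:
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
        center = sol[:2]
    except np.linalg.LinAlgError:
        return xy.mean(axis=0)
    if not np.all(np.isfinite(center)):
        return xy.mean(axis=0)
    # reject wildly extrapolated centers from near-collinear tracks
    if np.linalg.norm(center - xy.mean(axis=0)) > 10 * xy.std():
        return xy.mean(axis=0)
    return center


def rotation_period_from_tips(
    track_times: np.ndarray, track_xy: np.ndarray, min_windings: float = 2.0
) -> tuple[float | None, float]:
    """Period from the mean angular speed of the tip about its trajectory
    centroid, 2*pi / <|d theta/dt|>; (None, windings) when the accumulated
    angular path is less than ``min_windings`` revolutions.

    The angular path (total variation of the unwrapped angle) rather than
    the net angle is used so that meandering cores, whose net rotation
    about the centroid can nearly cancel over a petal, still register
    their revolutions.
    """
    xy = np.asarray(track_xy, dtype=float)
    tt = np.asarray(track_times, dtype=float)
    if xy.shape[0] < 3:
        return None, 0.0
    center = _rotation_center(xy)
    theta = np.unwrap(np.arctan2(xy[:, 1] - center[1], xy[:, 0] - center[0]))
    path = float(np.sum(np.abs(np.diff(theta))))
    windings = path / (2 * np.pi)
    if windings < min_windings:
        return None, float(windings)
    omega = path / (tt[-1] - tt[0])
    return float(2 * np.pi / omega), float(windings)


def rotation_period(
    result: SheetResult | None = None,
    trajectory: TipTrajectory | None = None,
) -> PeriodEstimate:
    """Combined rotation-period estimate (probe-based and tip-based)."""
    est = PeriodEstimate()
    if result is not None:
        est.probe_period, est.n_probe_cycles = rotation_period_from_probe(
            result.probe_times, result.probe_trace
        )
    if trajectory is not None and trajectory.main_track is not None:
        tt, xy = trajectory.main_track
        est.tip_period, est.tip_windings = rotation_period_from_tips(tt, xy)
    return est


def classify_dynamics(
    traj: TipTrajectory,
    run_length: float,
    s2_time: float = 0.0,
    transient: float = 200.0,
    breakup_span: float = 200.0,
    end_margin: float = 50.0,
) -> str:
    """Classify a run as stable / breakup / no_reentry / terminated.

    no_reentry: no tips after the post-S2 transient; breakup: more than
    one concurrent tip sustained for longer than ``breakup_span``;
    terminated: tips vanish before the run ends after at least one full
    rotation; otherwise stable.
    """
    t_eval = s2_time + transient
    sel = traj.times >= t_eval
    if not np.any(sel):
        return "no_reentry"
    times = traj.times[sel]
    counts = traj.counts[sel]
    if counts.max(initial=0) == 0:
        return "no_reentry"

    # longest contiguous span with >1 tip
    multi = counts > 1
    span = 0.0
    start = None
    for t, m in zip(times, multi):
        if m and start is None:
            start = t
        elif not m and start is not None:
            span = max(span, t - start)
            start = None
    if start is not None:
        span = max(span, times[-1] - start)
    if span > breakup_span:
        return "breakup"

    last_tip_time = times[counts > 0][-1]
    if last_tip_time < run_length - end_margin:
        windings = 0.0
        if traj.main_track is not None:
            _, windings = rotation_period_from_tips(*traj.main_track, min_windings=1.0)
        return "terminated" if windings >= 1.0 else "no_reentry"
    return "stable"
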