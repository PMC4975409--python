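"""Spiral-wave machinery: tip localization on constructed fields, period
estimation, dynamics classification, and a scaled-down reentry run."""
import numpy as np
import pytest

from atriafit import (
    Grid2DConfig,
    classify_dynamics,
    run_2d,
    track_tips,
)
from atriafit.cable_sim import ConfigError
from atriafit.spiral2d import (
    TipTrajectory,
    rotation_period_from_probe,
    rotation_period_from_tips,
)


def _rotating_field(n=40, dx=0.05, omega=2 * np.pi / 200.0, times=None):
    """Rigidly rotating scalar field u = tanh(r/w) cos(theta - omega t)
    whose phase singularity sits at the grid center."""
    if times is None:
        times = np.arange(0.0, 30.0, 5.0)
    c = (n - 1) / 2.0
    jj, ii = np.meshgrid(np.arange(n), np.arange(n))
    r = np.hypot(ii - c, jj - c) * dx
    theta = np.arctan2(ii - c, jj - c)
    frames = np.stack(
        [np.tanh(r / (2 * dx)) * np.cos(theta - omega * t) for t in times]
    ).astype(np.float32)
    center_cm = (c * dx, c * dx)
    return frames, np.asarray(times), center_cm


class TestTrackTips:
    def test_uniform_frames_have_no_tips(self):
        frames = np.full((4, 30, 30), 0.8, dtype=np.float32)
        traj = track_tips(frames, np.arange(4.0), dx=0.05)
        assert traj.counts.max(initial=0) == 0

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            track_tips(np.zeros((1, 20, 20), dtype=np.float32), np.array([0.0]), 0.05)

    def test_rotating_field_tip_near_center(self):
        """A rigidly rotating field yields one tip within 2 dx of the
        rotation center in every frame."""
        dx = 0.05
        frames, times, center = _rotating_field(dx=dx)
        traj = track_tips(frames, times, dx=dx, u_iso=0.5)
        assert len(traj.tips_per_frame) == len(times) - 1
        for tips in traj.tips_per_frame:
            assert tips.shape[0] >= 1
            d = np.hypot(tips[:, 0] - center[0], tips[:, 1] - center[1])
            assert d.min() < 2 * dx

    def test_planar_wave_has_no_interior_tips(self):
        """For a translating planar front the isopotential line and the
        du/dt = 0 contour are parallel: no intersections."""
        n, dx = 40, 0.05
        x = np.arange(n) * dx
        frames = []
        for t in (0.0, 1.0, 2.0, 3.0):
            front = 0.5 * (1 + np.tanh((0.04 * t + 0.5 - x) / 0.1))
            frames.append(np.tile(front, (n, 1)))
        traj = track_tips(np.stack(frames).astype(np.float32),
                         np.arange(4.0), dx=dx)
        assert traj.counts.max(initial=0) == 0

    def test_linked_track_follows_moving_tip(self):
        dx = 0.05
        frames, times, center = _rotating_field(
            dx=dx, times=np.arange(0.0, 100.0, 5.0)
        )
        traj = track_tips(frames, times, dx=dx)
        tt, xy = traj.main_track
        assert tt.size >= 10  # one continuous track across frames
        assert np.all(np.hypot(xy[:, 0] - center[0], xy[:, 1] - center[1]) < 4 * dx)


class TestRotationPeriod:
    def test_probe_trace_with_regular_activations(self):
        t = np.arange(0.0, 1500.0, 1.0)
        v = ((t % 150.0) < 30.0).astype(float)  # activation every 150 ms
        period, n = rotation_period_from_probe(t, v, threshold=0.5)
        assert period == pytest.approx(150.0, abs=0.01)
        assert n >= 3

    def test_probe_with_too_few_cycles_is_unsustained(self):
        t = np.arange(0.0, 200.0, 1.0)
        v = ((t % 150.0) < 30.0).astype(float)
        period, _ = rotation_period_from_probe(t, v, threshold=0.5)
        assert period is None

    def test_circular_trajectory_recovers_angular_period(self):
        omega = 2 * np.pi / 200.0
        t = np.arange(0.0, 900.0, 5.0)
        xy = np.column_stack([3 + 0.5 * np.cos(omega * t),
                              3 + 0.5 * np.sin(omega * t)])
        period, windings = rotation_period_from_tips(t, xy)
        assert period == pytest.approx(200.0, rel=1e-6)
        assert windings > 4

    def test_partial_winding_is_unsustained(self):
        omega = 2 * np.pi / 200.0
        t = np.arange(0.0, 150.0, 5.0)  # < 1 revolution
        xy = np.column_stack([np.cos(omega * t), np.sin(omega * t)])
        period, _ = rotation_period_from_tips(t, xy)
        assert period is None


class TestClassifyDynamics:
    @staticmethod
    def _traj(times, tips_per_frame, tracks=()):
        return TipTrajectory(
            times=np.asarray(times, dtype=float),
            tips_per_frame=[np.asarray(t, dtype=float).reshape(-1, 2)
                            for t in tips_per_frame],
            tracks=list(tracks), dx=0.02,
        )

    def test_empty_trajectory_is_no_reentry(self):
        traj = self._traj(np.arange(0.0, 1000.0, 10.0),
                          [np.empty((0, 2))] * 100)
        assert classify_dynamics(traj, run_length=1000.0, s2_time=100.0) == "no_reentry"

    def test_sustained_multi_tip_state_is_breakup(self):
        times = np.arange(0.0, 1000.0, 10.0)
        tips = [np.random.default_rng(0).uniform(0, 5, (4, 2)) for _ in times]
        traj = self._traj(times, tips)
        assert classify_dynamics(traj, run_length=1000.0, s2_time=0.0) == "breakup"

    def test_single_persistent_tip_is_stable(self):
        omega = 2 * np.pi / 150.0
        times = np.arange(0.0, 1000.0, 10.0)
        xy = np.column_stack([2 + 0.4 * np.cos(omega * times),
                              2 + 0.4 * np.sin(omega * times)])
        tips = [xy[k].reshape(1, 2) for k in range(times.size)]
        traj = self._traj(times, tips, tracks=[(times, xy)])
        assert classify_dynamics(traj, run_length=1000.0, s2_time=0.0) == "stable"

    def test_tips_vanishing_after_rotation_is_terminated(self):
        omega = 2 * np.pi / 100.0
        times = np.arange(0.0, 1000.0, 10.0)
        alive = times < 500.0
        xy = np.column_stack([2 + 0.4 * np.cos(omega * times),
                              2 + 0.4 * np.sin(omega * times)])
        tips = [xy[k].reshape(1, 2) if alive[k] else np.empty((0, 2))
                for k in range(times.size)]
        traj = self._traj(times, tips, tracks=[(times[alive], xy[alive])])
        assert classify_dynamics(traj, run_length=1000.0, s2_time=0.0) == "terminated"


class TestSheetSimulation:
    def test_unstable_2d_discretization_rejected(self):
        with pytest.raises(ConfigError):
            Grid2DConfig(dx=0.02, dt=0.2, D=0.001)  # D*dt/dx^2 = 0.5

    def test_default_geometry(self):
        cfg = Grid2DConfig()
        assert cfg.side == pytest.approx(9.6)
        assert cfg.n == 480
        assert cfg.dx == 0.02 and cfg.dt == 0.01

    def test_s1_only_sweep_returns_to_rest(self, params):
        """Without an S2 the planar wave sweeps the sheet and the domain
        returns to rest with zero tips throughout."""
        cfg = Grid2DConfig(
            side=3.2, dx=0.04, dt=0.02, total_time=400.0, s2_time=1e9,
            stim_amplitude=0.6, frame_interval=5.0,
        )
        res = run_2d(params, cfg)
        assert res.frames[-1].max() < 0.05
        traj = track_tips(res.frames, res.frame_times, cfg.dx)
        assert traj.counts.max(initial=0) == 0
        assert classify_dynamics(traj, cfg.total_time, 0.0) == "no_reentry"

    def test_cross_activation_creates_sustained_reentry(self, spiral_run):
        """Cross-field S2 inside the vulnerable window creates a rotor that
        persists to the end of the run (scaled-down domain, shortened-APD
        parameter set)."""
        res, traj, label = spiral_run
        assert label in ("stable", "breakup")
        late = traj.times > res.s2_time + 300.0
        # a tip is present in essentially every late frame
        assert (traj.counts[late] > 0).mean() > 0.9

    def test_rotor_core_is_localized(self, spiral_run):
        """Late tip detections concentrate in a compact core region."""
        res, traj, _ = spiral_run
        pts = np.vstack([
            tips for t, tips in zip(traj.times, traj.tips_per_frame)
            if t > 500.0 and tips.size
        ])
        center = pts.mean(axis=0)
        assert np.hypot(*(pts - center).T).max() < 2.0  # cm

    def test_probe_period_is_stationary(self, spiral_run):
        """The rotation period measured at the probe is the same (within
        10%) over two disjoint late windows of the run: the reentry is
        periodic, not a transient."""
        from atriafit import activation_times

        res, traj, _ = spiral_run
        t, v = res.probe_times, res.probe_trace
        acts = activation_times(t, v, threshold=0.5, refractory=40.0)
        acts = acts[acts > res.s2_time + 200.0]  # drop the S2 transient
        intervals = np.diff(acts)
        assert intervals.size >= 4
        half = intervals.size // 2
        p1, p2 = intervals[:half].mean(), intervals[half:].mean()
        assert p2 == pytest.approx(p1, rel=0.10)
        assert 80.0 < p1 < 350.0  # physiological rotor period range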