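"""Shared fixtures.

Simulation-backed fixtures are session-scoped and deliberately small
(short cables, dt = 0.02 ms) so the whole suite stays fast; tests that
probe discretization accuracy build their own configurations.
"""
from __future__ import annotations

import dataclasses

import pytest

from atriafit import (
    CableConfig,
    PatientSpec,
    default_parameters,
    generate_patient,
    run_cable,
    s1s2_restitution,
)

#: Stimulus amplitude used by the small-cable fixtures (twice the
#: threshold amplitude of the default parameter set on this geometry).
STIM_AMP = 0.46


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def small_cable():
    """Short cable for protocol tests: 60 cells (1.2 cm), dt = 0.02 ms."""
    return CableConfig(
        n_cells=60, dx=0.02, dt=0.02, cv_positions=(0.3, 0.9),
        stim_amplitude=STIM_AMP,
    )


@pytest.fixture(scope="session")
def paced_recording(params, small_cable):
    """Ten beats at CL 400 ms on the small cable, 0.5-ms trace cadence."""
    cfg = dataclasses.replace(small_cable, record_every=25)
    stims = [10.0 + 400.0 * k for k in range(10)]
    return run_cable(params, cfg, stims, 10.0 + 400.0 * 10)


@pytest.fixture(scope="session")
def s1s2_small(params, small_cable):
    """S1-S2 result on the small cable at four coupling intervals."""
    return s1s2_restitution(
        params, small_cable, s1_cl=500.0, n_s1=8,
        s2_list=(500.0, 420.0, 360.0, 320.0),
    )


@pytest.fixture(scope="session")
def spiral_run(params):
    """Sustained cross-activation reentry on a reduced sheet.

    Uses a shortened-APD parameter variant (APD ~120 ms, CV ~41 cm/s at
    D = 0.0005 cm^2/ms) so the rotor's wavelength fits a 6.4-cm domain;
    the S2 time sits inside the vulnerable window found by the auto-scan
    for this configuration.
    """
    from atriafit import classify_dynamics, run_2d, track_tips
    from atriafit.spiral2d import Grid2DConfig

    variant = params.replace(tau_si=2.4, tau_so1=22.0, tau_w1m=50.0)
    cfg = Grid2DConfig(
        side=6.4, dx=0.04, dt=0.02, D=0.0005, total_time=1500.0,
        frame_interval=2.0, stim_amplitude=0.9, s2_time=227.8,
        probe=(0.8, 0.8),
    )
    res = run_2d(variant, cfg)
    traj = track_tips(res.frames, res.frame_times, cfg.dx)
    label = classify_dynamics(traj, run_length=cfg.total_time, s2_time=cfg.s2_time)
    return res, traj, label


@pytest.fixture(scope="session")
def model_truth_patient(params, small_cable):
    """Noise-free synthetic patient generated by the model itself."""
    spec = PatientSpec(
        mode="model_truth", truth_params=params, cable=small_cable,
        s2_list=(500.0, 440.0, 380.0, 330.0),
        noise_sd_apd=0.0, noise_sd_cv=0.0, seed=3,
    )
    return generate_patient(spec)
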