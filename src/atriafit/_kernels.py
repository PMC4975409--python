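"""Numba-compiled integration kernels for the cable and sheet solvers.

The ionic right-hand side here mirrors :func:`atriafit.ionic_model.
ionic_derivatives` exactly (same Heaviside H(0)=1 convention); a unit test
pins the two implementations against each other.  Parameters travel as a
flat float64 vector in :data:`atriafit.params.PARAM_ORDER`.
"""
from __future__ import annotations

import numpy as np
from numba import njit

# Indices into the flat parameter vector (PARAM_ORDER).
_U_O, _U_U, _THETA_V, _THETA_W, _THETA_VM, _THETA_O = 0, 1, 2, 3, 4, 5
_TAU_V1M, _TAU_V2M, _TAU_VP = 6, 7, 8
_TAU_W1M, _TAU_W2M, _K_WM, _U_WM, _TAU_WP = 9, 10, 11, 12, 13
_TAU_FI, _TAU_O1, _TAU_O2 = 14, 15, 16
_TAU_SO1, _TAU_SO2, _K_SO, _U_SO = 17, 18, 19, 20
_TAU_S1, _TAU_S2, _K_S, _U_S = 21, 22, 23, 24
_TAU_SI, _TAU_WINF, _W_INF_STAR = 25, 26, 27

U_LO = -0.5
U_HI = 2.0


@njit(cache=True, inline="always")
def _tanh(x):
    """tanh via one exp with saturation cutoff.

    For |x| >= 20, tanh(x) differs from +/-1 by < 1e-17 in double
    precision, so the cutoff is exact at machine precision; elsewhere the
    identity tanh(x) = 1 - 2/(exp(2x)+1) agrees with libm tanh to ~1 ulp
    and costs roughly half as much (the tissue kernels evaluate this three
    times per grid point per step).
    """
    if x >= 20.0:
        return 1.0
    if x <= -20.0:
        return -1.0
    return 1.0 - 2.0 / (np.exp(2.0 * x) + 1.0)


@njit(cache=True, inline="always")
def point_rates(u, v, w, s, p):
    """Ionic rates at one grid point; returns (J_ion, dv, dw, ds) in 1/ms."""
    Hv = 1.0 if u >= p[_THETA_V] else 0.0
    Hw = 1.0 if u >= p[_THETA_W] else 0.0
    Hvm = 1.0 if u >= p[_THETA_VM] else 0.0
    Ho = 1.0 if u >= p[_THETA_O] else 0.0

    tau_vm = p[_TAU_V2M] if Hvm == 1.0 else p[_TAU_V1M]
    tau_wm = p[_TAU_W1M] + (p[_TAU_W2M] - p[_TAU_W1M]) * (
        1.0 + _tanh(p[_K_WM] * (u - p[_U_WM]))
    ) / 2.0
    tau_so = p[_TAU_SO1] + (p[_TAU_SO2] - p[_TAU_SO1]) * (
        1.0 + _tanh(p[_K_SO] * (u - p[_U_SO]))
    ) / 2.0
    tau_s = p[_TAU_S2] if Hw == 1.0 else p[_TAU_S1]
    tau_o = p[_TAU_O2] if Ho == 1.0 else p[_TAU_O1]

    v_inf = 1.0 - Hvm
    w_inf = (1.0 - Ho) * (1.0 - u / p[_TAU_WINF]) + Ho * p[_W_INF_STAR]
    s_inf = (1.0 + _tanh(p[_K_S] * (u - p[_U_S]))) / 2.0

    J_fi = -v * Hv * (u - p[_THETA_V]) * (p[_U_U] - u) / p[_TAU_FI]
    J_so = (u - p[_U_O]) * (1.0 - Hw) / tau_o + Hw / tau_so
    J_si = -Hw * w * s / p[_TAU_SI]

    dv = (1.0 - Hv) * (v_inf - v) / tau_vm - Hv * v / p[_TAU_VP]
    dw = (1.0 - Hw) * (w_inf - w) / tau_wm - Hw * w / p[_TAU_WP]
    ds = (s_inf - s) / tau_s
    return J_fi + J_so + J_si, dv, dw, ds


@njit(cache=True)
def point_rates_array(u, v, w, s, p):
    """Vectorized wrapper over :func:`point_rates` for testing."""
    n = u.shape[0]
    J = np.empty(n)
    dv = np.empty(n)
    dw = np.empty(n)
    ds = np.empty(n)
    for i in range(n):
        J[i], dv[i], dw[i], ds[i] = point_rates(u[i], v[i], w[i], s[i], p)
    return J, dv, dw, ds


@njit(cache=True)
def _clip01(x):
    if x < 0.0:
        return 0.0
    if x > 1.0:
        return 1.0
    return x


@njit(cache=True)
def simulate_cable(
    u, v, w, s, p,
    dx, dt, D,
    n_steps, t0,
    stim_starts, stim_dur, stim_lo, stim_hi, stim_amp,
    rec_sites, rec_every,
    act_threshold, refractory,
    act_times, act_counts,
    traces, trace_times,
):
    """Explicit-Euler monodomain integration on a 1D cable with no-flux ends.

    State arrays are advanced in place.  Activation times (upward crossings
    of ``act_threshold`` with a ``refractory`` guard, linearly interpolated
    inside the step) are appended per cell into ``act_times``/``act_counts``.
    Voltage at ``rec_sites`` is sampled every ``rec_every`` steps into
    ``traces`` (first sample at ``t0``).  Returns (status, t_fail):
    status 0 = completed, 1 = blow-up at time t_fail.
    """
    n = u.shape[0]
    n_rec = rec_sites.shape[0]
    inv_dx2 = 1.0 / (dx * dx)
    max_act = act_times.shape[1]

    last_act = np.full(n, -1.0e18)
    # seed previous-activation clocks from already recorded activations
    for i in range(n):
        if act_counts[i] > 0:
            last_act[i] = act_times[i, act_counts[i] - 1]

    sample = 0
    for r in range(n_rec):
        traces[r, 0] = u[rec_sites[r]]
    trace_times[0] = t0
    sample = 1

    n_stim = stim_starts.shape[0]
    stim_ptr = 0

    u_new = np.empty(n)
    for step in range(n_steps):
        t = t0 + step * dt
        # advance past finished stimuli
        while stim_ptr < n_stim and t >= stim_starts[stim_ptr] + stim_dur:
            stim_ptr += 1
        stim_on = stim_ptr < n_stim and stim_starts[stim_ptr] <= t

        for i in range(n):
            if i == 0:
                lap = 2.0 * (u[1] - u[0]) * inv_dx2
            elif i == n - 1:
                lap = 2.0 * (u[n - 2] - u[n - 1]) * inv_dx2
            else:
                lap = (u[i - 1] - 2.0 * u[i] + u[i + 1]) * inv_dx2
            J, dv, dw, ds = point_rates(u[i], v[i], w[i], s[i], p)
            I = stim_amp if (stim_on and stim_lo <= i < stim_hi) else 0.0
            un = u[i] + dt * (D * lap - J + I)
            if not np.isfinite(un) or un < U_LO or un > U_HI:
                return 1, t
            u_new[i] = un
            v[i] = _clip01(v[i] + dt * dv)
            w[i] = _clip01(w[i] + dt * dw)
            s[i] = _clip01(s[i] + dt * ds)

        # activation detection with sub-step interpolation
        for i in range(n):
            if u[i] < act_threshold <= u_new[i]:
                if t - last_act[i] > refractory:
                    frac = (act_threshold - u[i]) / (u_new[i] - u[i])
                    t_act = t + frac * dt
                    if act_counts[i] < max_act:
                        act_times[i, act_counts[i]] = t_act
                        act_counts[i] += 1
                    last_act[i] = t_act

        for i in range(n):
            u[i] = u_new[i]

        if (step + 1) % rec_every == 0 and sample < traces.shape[1]:
            for r in range(n_rec):
                traces[r, sample] = u[rec_sites[r]]
            trace_times[sample] = t0 + (step + 1) * dt
            sample += 1

    return 0, t0 + n_steps * dt


@njit(cache=True)
def simulate_sheet(
    u, v, w, s, p,
    dx, dt, D,
    n_steps, t0,
    s1_start, s1_dur, s1_cols, s2_start, s2_dur,
    s2_i0, s2_i1, s2_j0, s2_j1,
    stim_amp,
    frame_every, frames, frame_times,
    probe_is, probe_js, probe_every, probe_traces, probe_times,
):
    """Explicit-Euler monodomain integration on an isotropic 2D sheet.

    No-flux (mirror ghost) boundaries on all edges.  S1 stimulates the first
    ``s1_cols`` columns at ``s1_start``; S2 stimulates the index rectangle
    [s2_i0:s2_i1, s2_j0:s2_j1] at ``s2_start`` (cross-field initiation).
    Voltage frames (float32) are stored every ``frame_every`` steps; probe
    traces every ``probe_every`` steps.  Returns (status, t_fail).
    """
    ny, nx = u.shape
    inv_dx2 = 1.0 / (dx * dx)
    n_probe = probe_is.shape[0]

    frame_idx = 0
    if frames.shape[0] > 0:
        for i in range(ny):
            for j in range(nx):
                frames[0, i, j] = np.float32(u[i, j])
        frame_times[0] = t0
        frame_idx = 1

    probe_idx = 0
    for k in range(n_probe):
        probe_traces[k, 0] = u[probe_is[k], probe_js[k]]
    probe_times[0] = t0
    probe_idx = 1

    u_new = np.empty((ny, nx))
    for step in range(n_steps):
        t = t0 + step * dt
        s1_on = s1_start <= t < s1_start + s1_dur
        s2_on = s2_start <= t < s2_start + s2_dur

        for i in range(ny):
            im = i - 1 if i > 0 else 1
            ip = i + 1 if i < ny - 1 else ny - 2
            for j in range(nx):
                jm = j - 1 if j > 0 else 1
                jp = j + 1 if j < nx - 1 else nx - 2
                lap = (
                    u[im, j] + u[ip, j] + u[i, jm] + u[i, jp] - 4.0 * u[i, j]
                ) * inv_dx2
                J, dv, dw, ds = point_rates(u[i, j], v[i, j], w[i, j], s[i, j], p)
                I = 0.0
                if s1_on and j < s1_cols:
                    I = stim_amp
                if s2_on and s2_i0 <= i < s2_i1 and s2_j0 <= j < s2_j1:
                    I = stim_amp
                un = u[i, j] + dt * (D * lap - J + I)
                if not np.isfinite(un) or un < U_LO or un > U_HI:
                    return 1, t
                u_new[i, j] = un
                v[i, j] = _clip01(v[i, j] + dt * dv)
                w[i, j] = _clip01(w[i, j] + dt * dw)
                s[i, j] = _clip01(s[i, j] + dt * ds)

        for i in range(ny):
            for j in range(nx):
                u[i, j] = u_new[i, j]

        if (step + 1) % frame_every == 0 and frame_idx < frames.shape[0]:
            for i in range(ny):
                for j in range(nx):
                    frames[frame_idx, i, j] = np.float32(u[i, j])
            frame_times[frame_idx] = t0 + (step + 1) * dt
            frame_idx += 1

        if (step + 1) % probe_every == 0 and probe_idx < probe_traces.shape[1]:
            for k in range(n_probe):
                probe_traces[k, probe_idx] = u[probe_is[k], probe_js[k]]
            probe_times[probe_idx] = t0 + (step + 1) * dt
            probe_idx += 1

    return 0, t0 + n_steps * dt
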