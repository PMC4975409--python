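"""Four-variable minimal ionic model evaluated pointwise.

The model describes the transmembrane potential ``u`` (dimensionless,
0 ~ rest, ~1 ~ plateau) and three gates ``v``, ``w``, ``s`` in [0, 1].
Three phenomenological currents stand in for the grouped ion channels:

* ``J_fi`` — fast inward (sodium-like), responsible for the upstroke;
* ``J_so`` — slow outward (potassium-like), responsible for repolarization;
* ``J_si`` — slow inward (calcium-like), responsible for the plateau.

Switching between current regimes uses the Heaviside step with the
convention ``H(0) = 1``: a state exactly at a threshold counts as
supra-threshold.  This convention is applied consistently here, in the
tissue kernels, and in the tests.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParameters

#: Guard range for the membrane potential; values outside indicate
#: numerical blow-up of the explicit integrator.
U_GUARD = (-0.5, 2.0)

#: Permitted gate overshoot before an Euler step is declared unstable.
GATE_TOL = 1e-9


class BlowUpError(RuntimeError):
    """Numerical blow-up: non-finite state or membrane potential outside guard range."""

    def __init__(self, message: str, state=None):
        super().__init__(message)
        self.state = state


@dataclass(frozen=True)
class ModelState:
    """Pointwise model state: membrane potential and the three gates."""

    u: float
    v: float
    w: float
    s: float

    def validate(self) -> None:
        arr = np.array([self.u, self.v, self.w, self.s])
        if not np.all(np.isfinite(arr)):
            raise BlowUpError(f"non-finite state {self}", state=self)
        if not (U_GUARD[0] <= self.u <= U_GUARD[1]):
            raise BlowUpError(
                f"membrane potential {self.u} outside guard range {U_GUARD}", state=self
            )
        for name in ("v", "w", "s"):
            g = getattr(self, name)
            if not (-GATE_TOL <= g <= 1 + GATE_TOL):
                raise BlowUpError(f"gate {name}={g} outside [0,1]", state=self)


def _heaviside(x):
    """H(0) = 1 convention, vectorized."""
    return np.where(np.asarray(x) >= 0, 1.0, 0.0)


def ionic_currents(state: ModelState, params: ModelParameters):
    """The three phenomenological currents ``(J_fi, J_so, J_si)`` in 1/ms."""
    p = params
    u, v, w, s = state.u, state.v, state.w, state.s
    Hv = _heaviside(u - p.theta_v)
    Hw = _heaviside(u - p.theta_w)
    Ho = _heaviside(u - p.theta_o)
    tau_so = p.tau_so1 + (p.tau_so2 - p.tau_so1) * (
        1.0 + np.tanh(p.k_so * (u - p.u_so))
    ) / 2.0
    tau_o = (1.0 - Ho) * p.tau_o1 + Ho * p.tau_o2
    J_fi = -v * Hv * (u - p.theta_v) * (p.u_u - u) / p.tau_fi
    J_so = (u - p.u_o) * (1.0 - Hw) / tau_o + Hw / tau_so
    J_si = -Hw * w * s / p.tau_si
    return J_fi, J_so, J_si


def ionic_derivatives(state: ModelState, params: ModelParameters):
    """Total ionic rate and gate derivatives at a single state.

    Returns ``(J_ion, dv, dw, ds)`` in 1/ms.  ``J_ion = J_fi + J_so + J_si``
    enters the voltage equation as ``du/dt = -J_ion + I_stim``.
    Accepts array-valued states for vectorized evaluation.
    """
    p = params
    u, v, w, s = state.u, state.v, state.w, state.s

    Hv = _heaviside(u - p.theta_v)
    Hw = _heaviside(u - p.theta_w)
    Hvm = _heaviside(u - p.theta_vminus)
    Ho = _heaviside(u - p.theta_o)

    tau_vm = (1.0 - Hvm) * p.tau_v1m + Hvm * p.tau_v2m
    tau_wm = p.tau_w1m + (p.tau_w2m - p.tau_w1m) * (
        1.0 + np.tanh(p.k_wm * (u - p.u_wm))
    ) / 2.0
    tau_s = (1.0 - Hw) * p.tau_s1 + Hw * p.tau_s2

    v_inf = 1.0 - Hvm
    w_inf = (1.0 - Ho) * (1.0 - u / p.tau_winf) + Ho * p.w_inf_star
    s_inf = (1.0 + np.tanh(p.k_s * (u - p.u_s))) / 2.0

    J_fi, J_so, J_si = ionic_currents(state, params)

    dv = (1.0 - Hv) * (v_inf - v) / tau_vm - Hv * v / p.tau_vp
    dw = (1.0 - Hw) * (w_inf - w) / tau_wm - Hw * w / p.tau_wp
    ds = (s_inf - s) / tau_s

    J_ion = J_fi + J_so + J_si
    out = (J_ion, dv, dw, ds)
    if not all(np.all(np.isfinite(x)) for x in out):
        raise BlowUpError("non-finite ionic derivatives", state=state)
    return out


def resting_state(params: ModelParameters) -> ModelState:
    """Quiescent fixed point of the model at ``u = u_o``.

    Each gate is set to its steady-state value at the resting potential,
    so all derivatives vanish and the state is invariant under unstimulated
    integration.
    """
    p = params
    u = p.u_o
    v = 1.0 if u < p.theta_vminus else 0.0
    w = (1.0 - u / p.tau_winf) if u < p.theta_o else p.w_inf_star
    w = min(max(w, 0.0), 1.0)
    s = (1.0 + np.tanh(p.k_s * (u - p.u_s))) / 2.0
    return ModelState(u=float(u), v=float(v), w=float(w), s=float(s))


def step_euler(
    state: ModelState, I_stim: float, dt: float, params: ModelParameters
) -> ModelState:
    """One explicit-Euler step of the pointwise model.

    ``du/dt = -J_ion + I_stim``; gates integrate their own ODEs.  Gates are
    clipped back to [0, 1] only for round-off-scale overshoot; a larger
    excursion means the step size is too coarse and raises
    :class:`BlowUpError` naming ``dt``.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    J_ion, dv, dw, ds = ionic_derivatives(state, params)
    u = state.u + dt * (-J_ion + I_stim)
    gates = {}
    for name, g, dg in (("v", state.v, dv), ("w", state.w, dw), ("s", state.s, ds)):
        g_new = g + dt * dg
        if g_new < -GATE_TOL or g_new > 1.0 + GATE_TOL:
            raise BlowUpError(
                f"gate {name} overshoot to {g_new} at dt={dt} ms; reduce the time step",
                state=state,
            )
        gates[name] = min(max(g_new, 0.0), 1.0)
    if not np.isfinite(u) or not (U_GUARD[0] <= u <= U_GUARD[1]):
        raise BlowUpError(
            f"membrane potential {u} outside guard range at dt={dt} ms", state=state
        )
    return ModelState(u=float(u), **gates)
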