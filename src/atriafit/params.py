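"""Parameter set of the minimal four-variable atrial ionic model.

The model has one membrane-potential variable and three gates, with 28
named constants: time constants (ms), dimensionless thresholds/midpoints
and sigmoid steepnesses.  The bundled default set is the published
epicardial reference parameterization of the minimal human model, which
serves as the initial condition for patient fits.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, fields, replace
from importlib import resources
from pathlib import Path

import numpy as np

#: Canonical ordering used when parameters travel as a flat vector
#: (simulation kernels, annealing moves).
PARAM_ORDER: tuple[str, ...] = (
    "u_o", "u_u", "theta_v", "theta_w", "theta_vminus", "theta_o",
    "tau_v1m", "tau_v2m", "tau_vp",
    "tau_w1m", "tau_w2m", "k_wm", "u_wm", "tau_wp",
    "tau_fi", "tau_o1", "tau_o2",
    "tau_so1", "tau_so2", "k_so", "u_so",
    "tau_s1", "tau_s2", "k_s", "u_s",
    "tau_si", "tau_winf", "w_inf_star",
)

#: Parameters perturbed multiplicatively during fitting (positive scale
#: parameters: time constants and sigmoid steepnesses).
MULTIPLICATIVE_PARAMS: frozenset[str] = frozenset(
    name for name in PARAM_ORDER if name.startswith(("tau_", "k_"))
)

#: Parameters perturbed additively (voltage levels, thresholds, midpoints).
ADDITIVE_PARAMS: frozenset[str] = frozenset(PARAM_ORDER) - MULTIPLICATIVE_PARAMS

#: Parameters frozen by default during fitting: the normalization anchors
#: (resting and peak voltage levels) and the fast-current threshold.
DEFAULT_FROZEN: tuple[str, ...] = ("u_o", "u_u", "theta_v")


class InvalidParametersError(ValueError):
    """Raised when a parameter set violates the model's structural invariants."""


@dataclass(frozen=True)
class ModelParameters:
    """Full parameter roster of the four-variable model.

    Defaults are the published epicardial reference set of the minimal
    human model.  Voltage-like quantities are dimensionless (0 ~ rest,
    ~1 ~ peak plateau); time constants are in ms.
    """

    u_o: float = 0.0
    u_u: float = 1.55
    theta_v: float = 0.3
    theta_w: float = 0.13
    theta_vminus: float = 0.006
    theta_o: float = 0.006
    tau_v1m: float = 60.0
    tau_v2m: float = 1150.0
    tau_vp: float = 1.4506
    tau_w1m: float = 60.0
    tau_w2m: float = 15.0
    k_wm: float = 65.0
    u_wm: float = 0.03
    tau_wp: float = 200.0
    tau_fi: float = 0.11
    tau_o1: float = 400.0
    tau_o2: float = 6.0
    tau_so1: float = 30.0181
    tau_so2: float = 0.9957
    k_so: float = 2.0458
    u_so: float = 0.65
    tau_s1: float = 2.7342
    tau_s2: float = 16.0
    k_s: float = 2.0994
    u_s: float = 0.9087
    tau_si: float = 1.8875
    tau_winf: float = 0.07
    w_inf_star: float = 0.94

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in PARAM_ORDER:
            value = getattr(self, name)
            if not np.isfinite(value):
                raise InvalidParametersError(f"{name} is not finite: {value}")
            if name.startswith("tau_") and value <= 0:
                raise InvalidParametersError(f"{name} must be > 0, got {value}")
            if name.startswith("k_") and value <= 0:
                raise InvalidParametersError(f"{name} must be > 0, got {value}")
        if not (0 <= self.u_o < self.theta_v < self.u_u):
            raise InvalidParametersError(
                "require 0 <= u_o < theta_v < u_u, got "
                f"u_o={self.u_o}, theta_v={self.theta_v}, u_u={self.u_u}"
            )
        for name in ("theta_v", "theta_w", "theta_vminus", "theta_o"):
            value = getattr(self, name)
            if not (0 <= value < 1):
                raise InvalidParametersError(f"{name} must be in [0,1), got {value}")

    # -- flat-vector round trip -------------------------------------------
    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in PARAM_ORDER], dtype=np.float64)

    @classmethod
    def from_vector(cls, vec: np.ndarray) -> "ModelParameters":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (len(PARAM_ORDER),):
            raise InvalidParametersError(
                f"expected vector of length {len(PARAM_ORDER)}, got shape {vec.shape}"
            )
        return cls(**dict(zip(PARAM_ORDER, vec.tolist())))

    def replace(self, **changes: float) -> "ModelParameters":
        return replace(self, **changes)

    # -- JSON serialization ------------------------------------------------
    def to_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in PARAM_ORDER}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidParametersError(f"unknown parameter names: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})

    @classmethod
    def from_json(cls, path: str | Path) -> "ModelParameters":
        return cls.from_dict(json.loads(Path(path).read_text()))


def default_parameters() -> ModelParameters:
    """The bundled reference parameter set (fitting initial condition)."""
    with resources.files("atriafit.data").joinpath("default.json").open() as fh:
        return ModelParameters.from_dict(json.load(fh))
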