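"""Fitting targets built from patient-style measurements.

A :class:`ClinicalDataset` bundles, for one patient: the averaged
normalized AP morphology (with its polynomial fit), APD-vs-DI points with
a logarithmic fit APD = a + b ln(DI), and the CV restitution CV(DI)
composed from the measured CV(CL) and DI(CL) tables.  The same CSV schema
is used for clinical-style and simulated data, so simulated and measured
curves are directly comparable.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .restitution import MorphologyShape

#: Default polynomial degrees: "high-order" for morphology, low for CV(CL).
MORPHOLOGY_POLY_DEGREE = 12
CV_CL_POLY_DEGREE = 2


@dataclass
class ClinicalDataset:
    """One patient's fitting targets."""

    label: str
    morphology: MorphologyShape
    apd_points: np.ndarray          # (n, 2): DI ms, APD ms
    cv_cl_points: np.ndarray        # (n, 2): CL ms, CV cm/s
    di_cl_points: np.ndarray        # (n, 2): CL ms, DI ms
    cv_di_points: np.ndarray | None = None  # (n, 2): DI ms, CV cm/s
    apd_logfit: tuple[float, float] | None = None  # (a, b) ms
    morph_poly: np.ndarray | None = None           # polynomial coefficients
    upstroke_dt: float | None = None               # ms
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.apd_points = np.asarray(self.apd_points, dtype=float)
        self.cv_cl_points = np.asarray(self.cv_cl_points, dtype=float)
        self.di_cl_points = np.asarray(self.di_cl_points, dtype=float)
        if self.cv_di_points is None:
            self.cv_di_points = cv_of_di(self.cv_cl_points, self.di_cl_points)
        else:
            self.cv_di_points = np.asarray(self.cv_di_points, dtype=float)
        if self.apd_logfit is None and len(self.apd_points) >= 3:
            a, b, _ = fit_apd_log(self.apd_points)
            self.apd_logfit = (a, b)

    # -- bundle IO ---------------------------------------------------------
    def save(self, directory: str | Path) -> Path:
        """Write the patient bundle (morphology.csv, apd_restitution.csv,
        cv_vs_cl.csv, di_vs_cl.csv, meta.json) to ``directory``."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({"t_norm": self.morphology.t, "v_norm": self.morphology.v}).to_csv(
            d / "morphology.csv", index=False
        )
        pd.DataFrame(self.apd_points, columns=["DI_ms", "APD_ms"]).to_csv(
            d / "apd_restitution.csv", index=False
        )
        pd.DataFrame(self.cv_cl_points, columns=["CL_ms", "CV_cm_s"]).to_csv(
            d / "cv_vs_cl.csv", index=False
        )
        pd.DataFrame(self.di_cl_points, columns=["CL_ms", "DI_ms"]).to_csv(
            d / "di_vs_cl.csv", index=False
        )
        meta = dict(self.meta)
        meta.update(
            {
                "label": self.label,
                "artifact_cutoff_norm": self.morphology.artifact_cutoff,
                "apd_logfit": list(self.apd_logfit) if self.apd_logfit else None,
                "upstroke_dt_ms": self.upstroke_dt,
            }
        )
        (d / "meta.json").write_text(json.dumps(meta, indent=2) + "\n")
        return d

    @classmethod
    def load(cls, directory: str | Path) -> "ClinicalDataset":
        d = Path(directory)
        meta = json.loads((d / "meta.json").read_text())
        morph_df = pd.read_csv(d / "morphology.csv")
        _require_columns(morph_df, ("t_norm", "v_norm"), "morphology.csv")
        apd_df = pd.read_csv(d / "apd_restitution.csv")
        _require_columns(apd_df, ("DI_ms", "APD_ms"), "apd_restitution.csv")
        cv_df = pd.read_csv(d / "cv_vs_cl.csv")
        _require_columns(cv_df, ("CL_ms", "CV_cm_s"), "cv_vs_cl.csv")
        di_df = pd.read_csv(d / "di_vs_cl.csv")
        _require_columns(di_df, ("CL_ms", "DI_ms"), "di_vs_cl.csv")
        shape = MorphologyShape(
            t=morph_df["t_norm"].to_numpy(),
            v=morph_df["v_norm"].to_numpy(),
            artifact_cutoff=float(meta.get("artifact_cutoff_norm", 0.0)),
        )
        logfit = meta.get("apd_logfit")
        return cls(
            label=meta.get("label", d.name),
            morphology=shape,
            apd_points=apd_df[["DI_ms", "APD_ms"]].to_numpy(),
            cv_cl_points=cv_df[["CL_ms", "CV_cm_s"]].to_numpy(),
            di_cl_points=di_df[["CL_ms", "DI_ms"]].to_numpy(),
            apd_logfit=tuple(logfit) if logfit else None,
            upstroke_dt=meta.get("upstroke_dt_ms"),
            meta=meta,
        )


def _require_columns(df: pd.DataFrame, cols, name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{name} is missing columns {missing}")


# ---------------------------------------------------------------------------
# curve construction
# ---------------------------------------------------------------------------

def average_morphology(shapes: list[MorphologyShape]) -> MorphologyShape:
    """Pointwise mean of normalized shapes on the common 200-point grid,
    re-normalized to unit peak.

    All inputs must share the same artifact cutoff (they come from the
    same recording protocol); averaging exploits that AP shape is roughly
    CL-independent once time is normalized to the APD.
    """
    if not shapes:
        raise ValueError("need at least one shape")
    cutoffs = {round(s.artifact_cutoff, 6) for s in shapes}
    if len(cutoffs) > 1:
        raise ValueError(f"inconsistent artifact cutoffs: {sorted(cutoffs)}")
    grid = MorphologyShape.common_grid()
    mean = np.mean([s.resample(grid) for s in shapes], axis=0)
    hi = float(mean.max())
    if hi <= 0:
        raise ValueError("averaged shape has zero amplitude")
    # restore unit peak (averaging misaligned peaks can lower it) without
    # stretching the baseline, so averaging identical shapes is the identity
    return MorphologyShape(
        t=grid, v=np.clip(mean / hi, 0.0, 1.0),
        artifact_cutoff=shapes[0].artifact_cutoff,
    )


def fit_morphology_polynomial(shape: MorphologyShape, degree: int = MORPHOLOGY_POLY_DEGREE):
    """Least-squares polynomial fit of the unmasked part of a shape.

    Uses an orthogonal (Chebyshev) basis internally for conditioning and
    returns standard power-basis coefficients (ascending) plus the RMS
    residual.  Evaluate with :func:`eval_morphology_polynomial`, which
    clamps to [0, 1].
    """
    mask = shape.t >= shape.artifact_cutoff
    t, v = shape.t[mask], shape.v[mask]
    if t.size < degree + 1:
        raise ValueError(f"need at least {degree + 1} unmasked samples, have {t.size}")
    cheb = np.polynomial.Chebyshev.fit(t, v, degree, domain=[0.0, 1.0])
    poly = cheb.convert(kind=np.polynomial.Polynomial)
    resid = v - cheb(t)
    return poly.coef, float(np.sqrt(np.mean(resid**2)))


def eval_morphology_polynomial(coef: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.clip(np.polynomial.polynomial.polyval(np.asarray(t, dtype=float), coef), 0.0, 1.0)


def fit_apd_log(points) -> tuple[float, float, float]:
    """Least-squares logarithmic restitution fit APD = a + b ln(DI).

    Returns ``(a, b, max_slope)`` where the maximum slope of the fitted
    curve over the data range is b / min(DI) (dAPD/dDI = b/DI is largest
    at the shortest diastolic interval).
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 (DI, APD) points")
    di, apd = pts[:, 0], pts[:, 1]
    if np.any(di <= 0):
        raise ValueError("all DI must be positive")
    b, a = np.polyfit(np.log(di), apd, 1)
    max_slope = b / float(di.min())
    return float(a), float(b), float(max_slope)


def cv_of_di(
    cv_cl_points, di_cl_points, poly_degree: int = CV_CL_POLY_DEGREE
) -> np.ndarray:
    """Compose the CV restitution curve CV(DI) from CV(CL) and DI(CL).

    CV(CL) is smoothed with a low-order polynomial; DI(CL) is interpolated
    monotonically (isotonic correction, with a warning, if the measured
    DI(CL) is not monotone after sorting).  The curve is emitted at each
    measured CL as (DI(CL), CV_fit(CL)) pairs, sorted by DI.
    """
    cv_pts = np.asarray(cv_cl_points, dtype=float)
    di_pts = np.asarray(di_cl_points, dtype=float)
    if cv_pts.shape[0] < poly_degree + 1 or di_pts.shape[0] < 2:
        raise ValueError("not enough points to compose CV(DI)")
    lo = max(cv_pts[:, 0].min(), di_pts[:, 0].min())
    hi = min(cv_pts[:, 0].max(), di_pts[:, 0].max())
    if hi <= lo:
        raise ValueError("CV(CL) and DI(CL) tables have no overlapping CL range")

    coef = np.polynomial.polynomial.polyfit(cv_pts[:, 0], cv_pts[:, 1], poly_degree)
    order = np.argsort(di_pts[:, 0])
    cl_sorted = di_pts[order, 0]
    di_sorted = di_pts[order, 1]
    if np.any(np.diff(di_sorted) < 0):
        warnings.warn(
            "DI(CL) is not monotone; applying isotonic correction", stacklevel=2
        )
        di_sorted = _isotonic_increasing(di_sorted)

    cls = cl_sorted[(cl_sorted >= lo) & (cl_sorted <= hi)]
    di = np.interp(cls, cl_sorted, di_sorted)
    cv = np.polynomial.polynomial.polyval(cls, coef)
    out = np.column_stack([di, cv])
    return out[np.argsort(out[:, 0])]


def _isotonic_increasing(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators projection onto non-decreasing sequences."""
    y = y.astype(float).copy()
    n = y.size
    w = np.ones(n)
    vals = list(y)
    wts = list(w)
    i = 0
    while i < len(vals) - 1:
        if vals[i] > vals[i + 1]:
            tot = wts[i] + wts[i + 1]
            vals[i] = (vals[i] * wts[i] + vals[i + 1] * wts[i + 1]) / tot
            wts[i] = tot
            del vals[i + 1], wts[i + 1]
            if i > 0:
                i -= 1
        else:
            i += 1
    return np.repeat(vals, [int(x) for x in wts])
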