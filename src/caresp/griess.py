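"""Griess-assay nitrite quantification.

The Griess reaction converts nitrite (the stable byproduct of nitric
oxide) into an azo dye read by absorbance.  A sodium-nitrite standard
series (typically 0, 5, 25, 50 μM) is fit by ordinary least squares,

    absorbance = slope * concentration + intercept,

and unknown wells are inverted through the line.  A Pearson correlation
below the QC floor (default 0.989, the plausible lower edge for a good
standard run) flags a questionable curve without blocking quantification.
Treated-versus-control time courses report, per day in vitro (DIV), the
mean treated-minus-control concentration increase with the SEM of the
difference propagated in quadrature across the two independent arms.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardCurve",
    "NoTimecourse",
    "fit_standard_curve",
    "quantify_nitrite",
    "summarize_no_timecourse",
    "DEFAULT_R_FLOOR",
]

DEFAULT_R_FLOOR = 0.989


@dataclass(frozen=True)
class StandardCurve:
    """Linear nitrite calibration (absorbance per μM)."""

    slope: float
    intercept: float
    r: float
    slope_stderr: float
    standards: tuple[tuple[float, float], ...]

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r": self.r,
            "slope_stderr": self.slope_stderr,
            "standards": [list(s) for s in self.standards],
        }


@dataclass
class NoTimecourse:
    """Treated-minus-control NO increase (μM) per DIV."""

    records: pd.DataFrame  # columns: div, mean_increase, sem, n_treated, n_control

    def increase_at(self, div: int) -> float:
        row = self.records.loc[self.records["div"] == div]
        if row.empty:
            raise KeyError(f"no record for DIV {div}")
        return float(row["mean_increase"].iloc[0])


def fit_standard_curve(
    points: list[tuple[float, float]], r_floor: float = DEFAULT_R_FLOOR
) -> StandardCurve:
    """OLS line through (concentration μM, absorbance) standards.

    Requires at least two distinct concentrations; warns when |r| falls
    below ``r_floor``.
    """
    pts = [(float(c), float(a)) for c, a in points]
    if len({c for c, _ in pts}) < 2:
        raise ValueError("need at least 2 distinct standard concentrations")
    x = np.array([c for c, _ in pts])
    y = np.array([a for _, a in pts])
    if len(pts) == 2:
        # exact two-point line; linregress stderr is undefined here
        slope = (y[1] - y[0]) / (x[1] - x[0])
        intercept = y[0] - slope * x[0]
        r = 1.0 if slope > 0 else (-1.0 if slope < 0 else 0.0)
        stderr = 0.0
    else:
        fit = stats.linregress(x, y)
        slope, intercept, r, stderr = fit.slope, fit.intercept, fit.rvalue, fit.stderr
    if abs(r) < r_floor:
        warnings.warn(
            f"standard curve correlation |r|={abs(r):.4f} below QC floor "
            f"{r_floor}; check the standards",
            stacklevel=2,
        )
    return StandardCurve(
        slope=float(slope),
        intercept=float(intercept),
        r=float(r),
        slope_stderr=float(stderr),
        standards=tuple(pts),
    )


def quantify_nitrite(absorbance, curve: StandardCurve):
    """Invert absorbance through the standard curve: (A - b) / m, in μM.

    Negative results (below-blank wells) are returned as-is; callers can
    flag them with ``concentration < 0``.
    """
    if curve.slope == 0:
        raise ValueError("standard curve slope is zero; cannot invert")
    a = np.asarray(absorbance, dtype=float)
    conc = (a - curve.intercept) / curve.slope
    return float(conc) if conc.ndim == 0 else conc


def _arm_stats(values: np.ndarray) -> tuple[float, float, int]:
    n = len(values)
    mean = float(np.mean(values))
    sem = float(np.std(values, ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return mean, sem, n


def summarize_no_timecourse(
    treated: pd.DataFrame,
    control: pd.DataFrame,
    value_col: str = "concentration",
    div_col: str = "div",
    experiment_col: str = "experiment",
) -> NoTimecourse:
    """Per-DIV mean treated-minus-control increase with quadrature SEM.

    Input frames need ``div`` and ``concentration`` columns (μM); when an
    ``experiment`` column is present, wells are averaged within each
    experiment first and the SEM is taken across experiment means.
    Single-well (or single-experiment) arms get SEM 0 and carry n=1.
    """
    def _collapse(df: pd.DataFrame) -> pd.DataFrame:
        if experiment_col in df.columns:
            return (
                df.groupby([div_col, experiment_col], as_index=False)[value_col].mean()
            )
        return df[[div_col, value_col]].copy()

    t, c = _collapse(treated), _collapse(control)
    divs_t, divs_c = set(t[div_col]), set(c[div_col])
    if divs_t != divs_c:
        raise ValueError(
            f"treated and control cover different DIV sets: "
            f"{sorted(divs_t)} vs {sorted(divs_c)}"
        )
    rows = []
    for div in sorted(divs_t):
        mt, st, nt = _arm_stats(t.loc[t[div_col] == div, value_col].to_numpy())
        mc, sc, nc = _arm_stats(c.loc[c[div_col] == div, value_col].to_numpy())
        rows.append(
            {
                "div": div,
                "mean_increase": mt - mc,
                "sem": math.sqrt(st**2 + sc**2),
                "n_treated": nt,
                "n_control": nc,
            }
        )
    return NoTimecourse(records=pd.DataFrame(rows))
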