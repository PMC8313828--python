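"""Object morphometry: size statistics and the nuclear area factor.

Works on pre-measured object tables (one row per ROI, nucleus or
stained cell outline) with an ``area`` column in pixel² or μm² and,
for nuclei, a ``roundness`` column in (0, 1].  The nuclear area factor
(NAF) condenses nuclear shrinkage and irregularity into one number,

    NAF = area x roundness,

so a small or ragged (apoptotic-looking) nucleus scores low.  A pixel
to μm calibration is a plain scalar applied by the caller; no image
metadata is interpreted here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["MeasureStats", "object_stats", "nuclear_area_factor"]


@dataclass(frozen=True)
class MeasureStats:
    """n / mean / sample SD for one measured quantity."""

    measure: str
    n: int
    mean: float
    sd: float
    single: bool  # True when n == 1 and the SD is undefined (reported 0)

    def to_dict(self) -> dict:
        return {
            "measure": self.measure,
            "n": self.n,
            "mean": self.mean,
            "sd": self.sd,
            "single": self.single,
        }


def object_stats(
    records: pd.DataFrame, measures: list[str] | None = None
) -> dict[str, MeasureStats]:
    """Mean and sample SD (n-1 denominator) per numeric measure column.

    ``measures`` defaults to every numeric column except identifiers.
    An empty table is an error; n=1 yields SD 0 with the ``single`` flag.
    """
    if len(records) == 0:
        raise ValueError("object_stats needs at least one record")
    if measures is None:
        measures = [
            c for c in records.columns
            if c != "object_id" and pd.api.types.is_numeric_dtype(records[c])
        ]
    out: dict[str, MeasureStats] = {}
    for m in measures:
        vals = records[m].dropna().to_numpy(dtype=float)
        if len(vals) == 0:
            raise ValueError(f"measure {m!r} has no values")
        n = len(vals)
        sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
        out[m] = MeasureStats(measure=m, n=n, mean=float(np.mean(vals)), sd=sd,
                              single=(n == 1))
    return out


def nuclear_area_factor(record) -> float:
    """NAF of one object: area x roundness.

    ``record`` is a mapping (or DataFrame row) with ``area`` > 0 and
    ``roundness`` in (0, 1]; NAF never exceeds the area.
    """
    try:
        area = float(record["area"])
        roundness = float(record["roundness"])
    except (KeyError, TypeError, ValueError) as err:
        raise ValueError(f"record needs numeric 'area' and 'roundness': {err}") from None
    if math.isnan(roundness):
        raise ValueError("record is missing roundness")
    if area <= 0:
        raise ValueError(f"area must be positive, got {area}")
    if not 0 < roundness <= 1:
        raise ValueError(f"roundness must lie in (0, 1], got {roundness}")
    return area * roundness


def add_naf_column(records: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of an object table with a ``naf`` column appended."""
    out = records.copy()
    out["naf"] = [nuclear_area_factor(r) for _, r in records.iterrows()]
    return out
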