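"""Culture-level aggregation of per-cell response profiles and
between-culture comparison statistics.

Percentages are computed over *valid* cells only (cells that passed the
ionomycin positive control); the number excluded is always reported.
The headline statistics mirror how such experiments are reported:
percent non-responders (code "000"), percent responding to all three
events ("111"), percent responding to more than one event
({"110","011","101","111"}), and per-event means of spike counts and
dominant-peak amplitudes (baseline window plus events 1-3).

Cultures are compared by fold ratios of percentages — with the
"comparative difference" convention (fold - 1) x 100 — and by a Pearson
chi-square on the 2 x k contingency table of category counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .classify import CATEGORY_CODES, ResponseProfile

__all__ = [
    "CultureSummary",
    "ComparisonResult",
    "summarize_culture",
    "fold_ratio",
    "comparative_difference",
    "compare_category_distributions",
]

#: Codes counted as "responded to more than one event".
MULTI_EVENT_CODES: tuple[str, ...] = ("011", "101", "110", "111")


@dataclass
class CultureSummary:
    """Aggregate statistics for one culture condition."""

    label: str
    n_valid: int
    n_excluded: int
    category_counts: dict[str, int]
    mean_spikes_per_event: tuple[float, float, float, float]  # baseline, e1..e3
    mean_dominant_peak_per_event: tuple[float, float, float, float]

    @property
    def category_percent(self) -> dict[str, float]:
        return {c: 100.0 * k / self.n_valid for c, k in self.category_counts.items()}

    @property
    def percent_non_responders(self) -> float:
        return self.category_percent["000"]

    @property
    def percent_all_events(self) -> float:
        return self.category_percent["111"]

    @property
    def percent_multi(self) -> float:
        return sum(self.category_percent[c] for c in MULTI_EVENT_CODES)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n_valid": self.n_valid,
            "n_excluded": self.n_excluded,
            "category_counts": dict(self.category_counts),
            "category_percent": {c: round(p, 2) for c, p in self.category_percent.items()},
            "percent_non_responders": round(self.percent_non_responders, 2),
            "percent_all_events": round(self.percent_all_events, 2),
            "percent_multi": round(self.percent_multi, 2),
            "mean_spikes_per_event": list(self.mean_spikes_per_event),
            "mean_dominant_peak_per_event": list(self.mean_dominant_peak_per_event),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CultureSummary":
        return cls(
            label=d["label"],
            n_valid=d["n_valid"],
            n_excluded=d["n_excluded"],
            category_counts={c: int(d["category_counts"].get(c, 0)) for c in CATEGORY_CODES},
            mean_spikes_per_event=tuple(d["mean_spikes_per_event"]),
            mean_dominant_peak_per_event=tuple(d["mean_dominant_peak_per_event"]),
        )


@dataclass
class ComparisonResult:
    """Two-culture comparison: fold arithmetic plus contingency test."""

    fold: float
    comparative_difference: float
    chi2: float
    dof: int
    p_value: float
    categories_used: list[str]

    def to_dict(self) -> dict:
        return {
            "fold": self.fold,
            "comparative_difference": self.comparative_difference,
            "chi2": self.chi2,
            "dof": self.dof,
            "p_value": self.p_value,
            "categories_used": list(self.categories_used),
        }


def summarize_culture(
    profiles: list[ResponseProfile],
    label: str = "",
    responders_only: bool = False,
) -> CultureSummary:
    """Aggregate per-cell profiles into a :class:`CultureSummary`.

    Parameters
    ----------
    responders_only : bool
        When True, per-event spike/peak means average only cells that
        responded to that event; default averages over all valid cells.
    """
    valid = [p for p in profiles if p.valid]
    n_excluded = len(profiles) - len(valid)
    if not valid:
        raise ValueError(
            f"culture {label!r}: no valid cells "
            f"({n_excluded} failed the positive control)"
        )
    counts = {c: 0 for c in CATEGORY_CODES}
    for p in valid:
        counts[p.category_code] += 1

    mean_spikes = [float(np.mean([p.baseline_spikes for p in valid]))]
    mean_peaks = [float(np.mean([p.baseline_peak for p in valid]))]
    for e in range(3):
        pool = [p for p in valid if p.responder_flags[e]] if responders_only else valid
        if pool:
            mean_spikes.append(float(np.mean([p.spikes_per_event[e] for p in pool])))
            mean_peaks.append(float(np.mean([p.dominant_peak_per_event[e] for p in pool])))
        else:
            mean_spikes.append(0.0)
            mean_peaks.append(0.0)

    return CultureSummary(
        label=label,
        n_valid=len(valid),
        n_excluded=n_excluded,
        category_counts=counts,
        mean_spikes_per_event=tuple(mean_spikes),
        mean_dominant_peak_per_event=tuple(mean_peaks),
    )


def fold_ratio(a: float, b: float) -> float:
    """Ratio a/b of two percentages (or sizes); the field's 'x-fold'."""
    if b <= 0:
        raise ValueError(f"fold_ratio denominator must be positive, got {b}")
    return a / b


def comparative_difference(fold: float) -> float:
    """Percent difference implied by a fold change: (fold - 1) x 100."""
    if fold <= 0:
        raise ValueError(f"fold must be positive, got {fold}")
    return (fold - 1.0) * 100.0


def compare_category_distributions(
    a: CultureSummary, b: CultureSummary
) -> ComparisonResult:
    """Pearson chi-square on the 2 x k table of category counts.

    Categories with zero total across both cultures are dropped;
    ``dof = k - 1`` for the remaining k categories.  Expected counts
    below 5 trigger a warning (no continuity correction or exact test
    is substituted).  The fold entry compares the two non-responder
    percentages (larger over smaller).
    """
    rows = []
    used = []
    for c in CATEGORY_CODES:
        ka, kb = a.category_counts.get(c, 0), b.category_counts.get(c, 0)
        if ka + kb > 0:
            rows.append([ka, kb])
            used.append(c)
    if len(used) < 2:
        raise ValueError("need at least 2 categories with nonzero totals")
    table = np.array(rows).T  # 2 x k
    chi2, p, dof, expected = stats.chi2_contingency(table, correction=False)
    if (expected < 5).any():
        warnings.warn(
            f"chi-square expected counts below 5 in {int((expected < 5).sum())} "
            "cells; the asymptotic p-value may be inaccurate",
            stacklevel=2,
        )
    pa, pb = a.percent_non_responders, b.percent_non_responders
    if pa > 0 and pb > 0:
        fold = max(pa, pb) / min(pa, pb)
        cd = comparative_difference(fold)
    else:
        fold, cd = float("nan"), float("nan")
    return ComparisonResult(
        fold=fold,
        comparative_difference=cd,
        chi2=float(chi2),
        dof=int(dof),
        p_value=float(p),
        categories_used=used,
    )
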