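"""Baseline normalization and per-cell response classification.

The procedure, per cell:

1. Divide the raw trace by the mean of the baseline window, so the
   untreated baseline sits at 1 (fold units, ΔF/F0 + 1).
2. In each of the three stimulus windows, a cell is a *responder* when
   the normalized trace reaches at least the threshold fold (default
   1.2, i.e. a 20% rise over baseline; the boundary is inclusive).
3. The three responder flags form a 3-character category code, e.g.
   "101" = responded to events 1 and 3 only; "000" with a positive
   ionomycin control is a Non-Responder; 8 codes are possible.
4. A cell that fails the ionomycin positive control is invalid (dead or
   unloaded ROI) and excluded from every denominator downstream.

Per responding window we also report the dominant peak (window maximum,
fold units) and a spike count: strict local maxima at or above the
threshold, with a minimum frame separation between accepted spikes
(larger of a conflicting pair wins; ties keep the earlier).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import EventSchedule
from .traces import TraceMatrix

__all__ = [
    "Threshold",
    "ResponseProfile",
    "CATEGORY_CODES",
    "normalize_trace",
    "detect_event_response",
    "count_spikes",
    "classify_cell",
    "classify_culture",
    "profiles_to_frame",
]

#: The 8 possible response combinations across events 1-3, in binary order.
CATEGORY_CODES: tuple[str, ...] = tuple(f"{i:03b}" for i in range(8))

DEFAULT_MIN_SEPARATION = 2


@dataclass(frozen=True)
class Threshold:
    """Responder criterion: minimum fold over baseline (inclusive)."""

    fold: float = 1.2

    def __post_init__(self) -> None:
        if not self.fold > 1:
            raise ValueError(f"threshold fold must exceed 1, got {self.fold}")


@dataclass(frozen=True)
class ResponseProfile:
    """Classification outcome for one cell."""

    cell_id: str
    responder_flags: tuple[bool, bool, bool]
    control_responder: bool
    spikes_per_event: tuple[int, int, int]
    dominant_peak_per_event: tuple[float, float, float]
    control_peak: float
    baseline_spikes: int = 0
    baseline_peak: float = 1.0

    @property
    def category_code(self) -> str:
        return "".join("1" if f else "0" for f in self.responder_flags)

    @property
    def valid(self) -> bool:
        """Cells must respond to the ionomycin positive control."""
        return self.control_responder

    @property
    def is_non_responder(self) -> bool:
        return self.valid and self.category_code == "000"


def _window_slice(series: np.ndarray, window: tuple[int, int]) -> np.ndarray:
    lo, hi = window
    if not (0 <= lo < hi <= len(series)):
        raise ValueError(f"empty or out-of-range window {window} for series of length {len(series)}")
    return series[lo:hi]


def normalize_trace(raw: np.ndarray, schedule: EventSchedule) -> np.ndarray:
    """Express a raw trace as fold over its own baseline mean.

    The divisor is the mean over the whole baseline window (not frame 0
    alone), which keeps the normalization robust to frame noise.
    """
    raw = np.asarray(raw, dtype=float)
    if len(raw) != schedule.n_frames:
        raise ValueError(
            f"trace length {len(raw)} does not match schedule n_frames {schedule.n_frames}"
        )
    if not np.all(np.isfinite(raw)):
        raise ValueError("trace contains non-finite values")
    b0 = _window_slice(raw, schedule.baseline_window).mean()
    if b0 <= 0:
        raise ValueError(f"nonpositive baseline mean {b0}")
    return raw / b0


def detect_event_response(
    normalized: np.ndarray,
    window: tuple[int, int],
    threshold: Threshold = Threshold(),
) -> tuple[bool, float]:
    """Responder decision and dominant peak for one event window.

    Returns ``(responder, dominant_peak)`` where dominant_peak is the
    window maximum of the normalized trace and responder is True when it
    reaches the threshold fold ("at least": the boundary counts).
    """
    seg = _window_slice(np.asarray(normalized, dtype=float), window)
    peak = float(seg.max())
    return peak >= threshold.fold, peak


def count_spikes(
    normalized: np.ndarray,
    window: tuple[int, int],
    threshold: Threshold = Threshold(),
    min_separation_frames: int = DEFAULT_MIN_SEPARATION,
) -> int:
    """Count spikes (calcium transients) in a window.

    A candidate spike is a strict local maximum within the window — a
    frame strictly greater than both immediate neighbours, neighbours
    taken inside the window — whose value is at or above the threshold
    fold.  Candidates closer than ``min_separation_frames`` are resolved
    by keeping the larger one (the earlier on a tie).
    """
    if min_separation_frames < 1:
        raise ValueError("min_separation_frames must be >= 1")
    seg = _window_slice(np.asarray(normalized, dtype=float), window)
    fold = threshold.fold
    candidates = [
        i
        for i in range(1, len(seg) - 1)
        if seg[i] > seg[i - 1] and seg[i] > seg[i + 1] and seg[i] >= fold
    ]
    if min_separation_frames <= 2 or len(candidates) < 2:
        # strict local maxima are already >= 2 frames apart
        return len(candidates)
    accepted: list[int] = []
    for i in sorted(candidates, key=lambda i: (-seg[i], i)):
        if all(abs(i - j) >= min_separation_frames for j in accepted):
            accepted.append(i)
    return len(accepted)


def classify_cell(
    raw: np.ndarray,
    schedule: EventSchedule,
    cell_id: str = "cell",
    threshold: Threshold = Threshold(),
    min_separation_frames: int = DEFAULT_MIN_SEPARATION,
) -> ResponseProfile:
    """Classify one raw trace into a :class:`ResponseProfile`."""
    norm = normalize_trace(raw, schedule)
    flags: list[bool] = []
    peaks: list[float] = []
    spikes: list[int] = []
    for window in schedule.event_windows:
        responder, peak = detect_event_response(norm, window, threshold)
        flags.append(responder)
        peaks.append(peak)
        spikes.append(count_spikes(norm, window, threshold, min_separation_frames))
    control_responder, control_peak = detect_event_response(
        norm, schedule.control_window, threshold
    )
    _, base_peak = detect_event_response(norm, schedule.baseline_window, threshold)
    base_spikes = count_spikes(
        norm, schedule.baseline_window, threshold, min_separation_frames
    )
    return ResponseProfile(
        cell_id=cell_id,
        responder_flags=tuple(flags),
        control_responder=control_responder,
        spikes_per_event=tuple(spikes),
        dominant_peak_per_event=tuple(peaks),
        control_peak=control_peak,
        baseline_spikes=base_spikes,
        baseline_peak=base_peak,
    )


def classify_culture(
    matrix: TraceMatrix,
    schedule: EventSchedule,
    threshold: Threshold = Threshold(),
    min_separation_frames: int = DEFAULT_MIN_SEPARATION,
) -> list[ResponseProfile]:
    """Classify every cell of a culture; output order follows input order."""
    if matrix.normalized:
        raise ValueError("classify_culture expects raw (un-normalized) traces")
    return [
        classify_cell(matrix.values[i], schedule, matrix.cell_ids[i],
                      threshold, min_separation_frames)
        for i in range(matrix.n_cells)
    ]


def profiles_to_frame(profiles: list[ResponseProfile]) -> pd.DataFrame:
    """Tabulate profiles: one row per cell, flat columns for CSV export."""
    rows = []
    for p in profiles:
        row = {
            "cell_id": p.cell_id,
            "code": p.category_code,
            "valid": p.valid,
            "r1": p.responder_flags[0],
            "r2": p.responder_flags[1],
            "r3": p.responder_flags[2],
            "peak1": p.dominant_peak_per_event[0],
            "peak2": p.dominant_peak_per_event[1],
            "peak3": p.dominant_peak_per_event[2],
            "spikes1": p.spikes_per_event[0],
            "spikes2": p.spikes_per_event[1],
            "spikes3": p.spikes_per_event[2],
            "baseline_peak": p.baseline_peak,
            "baseline_spikes": p.baseline_spikes,
            "control_peak": p.control_peak,
        }
        rows.append(row)
    columns = [
        "cell_id", "code", "valid", "r1", "r2", "r3",
        "peak1", "peak2", "peak3", "spikes1", "spikes2", "spikes3",
        "baseline_peak", "baseline_spikes", "control_peak",
    ]
    return pd.DataFrame(rows, columns=columns)


def profiles_from_frame(df: pd.DataFrame) -> list[ResponseProfile]:
    """Inverse of :func:`profiles_to_frame` (codes rebuilt from flags)."""
    out = []
    for _, r in df.iterrows():
        out.append(
            ResponseProfile(
                cell_id=str(r["cell_id"]),
                responder_flags=(bool(r["r1"]), bool(r["r2"]), bool(r["r3"])),
                control_responder=bool(r["valid"]),
                spikes_per_event=(int(r["spikes1"]), int(r["spikes2"]), int(r["spikes3"])),
                dominant_peak_per_event=(
                    float(r["peak1"]), float(r["peak2"]), float(r["peak3"])),
                control_peak=float(r["control_peak"]),
                baseline_spikes=int(r.get("baseline_spikes", 0)),
                baseline_peak=float(r.get("baseline_peak", 1.0)),
            )
        )
    return out
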