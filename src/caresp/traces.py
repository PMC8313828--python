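"""Per-ROI fluorescence trace matrices and their CSV dialects.

Two tabular text layouts are supported:

* ``wide`` — first column ``frame`` (contiguous from 0), one column per
  cell, one row per frame.
* ``long`` — columns ``cell_id, frame, value``, one row per observation.

Values are raw fluorescence (arbitrary units, positive) or fold-over-
baseline after normalization; the ``normalized`` flag records which.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TraceMatrix", "read_trace_table", "write_trace_table"]

_DIALECTS = ("wide", "long")


@dataclass
class TraceMatrix:
    """Equal-length fluorescence series for a set of cells (ROIs)."""

    cell_ids: list[str]
    values: np.ndarray  # shape (n_cells, n_frames), float64
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            if self.values.size == 0:
                self.values = self.values.reshape(len(self.cell_ids), 0)
            else:
                raise ValueError("values must be a 2-D (cells x frames) array")
        if len(self.cell_ids) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.cell_ids)} cell ids but {self.values.shape[0]} rows"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell ids")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite (no NaN/inf)")
        if self.values.size and not self.normalized and not np.all(self.values > 0):
            raise ValueError("raw fluorescence must be strictly positive")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def trace(self, cell_id: str) -> np.ndarray:
        return self.values[self.cell_ids.index(cell_id)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TraceMatrix):
            return NotImplemented
        return (
            self.cell_ids == other.cell_ids
            and self.normalized == other.normalized
            and self.values.shape == other.values.shape
            and bool(np.array_equal(self.values, other.values))
        )


def _to_frame(matrix: TraceMatrix, dialect: str) -> pd.DataFrame:
    if dialect == "wide":
        df = pd.DataFrame(
            matrix.values.T, columns=matrix.cell_ids, copy=True
        )
        df.insert(0, "frame", np.arange(matrix.n_frames))
        return df
    rows = {
        "cell_id": np.repeat(matrix.cell_ids, matrix.n_frames),
        "frame": np.tile(np.arange(matrix.n_frames), matrix.n_cells),
        "value": matrix.values.reshape(-1),
    }
    return pd.DataFrame(rows)


def write_trace_table(matrix: TraceMatrix, path_or_buf, dialect: str = "wide") -> None:
    """Write a trace matrix as CSV; round-trips losslessly via
    :func:`read_trace_table` (floats serialized with repr precision)."""
    if dialect not in _DIALECTS:
        raise ValueError(f"dialect must be one of {_DIALECTS}, got {dialect!r}")
    df = _to_frame(matrix, dialect)
    df.to_csv(path_or_buf, index=False, float_format=None, lineterminator="\n")


def read_trace_table(
    path_or_buf, dialect: str = "wide", normalized: bool = False
) -> TraceMatrix:
    """Read a trace CSV into a validated :class:`TraceMatrix`.

    Frame indices must be contiguous from 0 for every cell; ragged or
    missing frames, non-numeric values and duplicate (cell, frame) pairs
    are rejected with the offending cell named.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"dialect must be one of {_DIALECTS}, got {dialect!r}")
    df = pd.read_csv(path_or_buf, dtype=str)
    if dialect == "wide":
        return _read_wide(df, normalized)
    return _read_long(df, normalized)


def _numeric(col: pd.Series, what: str) -> np.ndarray:
    # numpy's parser is correctly rounded (pd.to_numeric's fast path is not),
    # which the full-precision round-trip guarantee depends on
    vals = col.to_numpy()
    try:
        out = np.asarray(vals, dtype=float)
    except (ValueError, TypeError):
        for row, v in enumerate(vals):
            try:
                float(v)
            except (ValueError, TypeError):
                raise ValueError(
                    f"non-numeric {what} at row {row + 2}: {v!r}"
                ) from None
        raise
    if np.isnan(out).any():
        row = int(np.flatnonzero(np.isnan(out))[0])
        raise ValueError(f"missing {what} at row {row + 2}")
    return out


def _read_wide(df: pd.DataFrame, normalized: bool) -> TraceMatrix:
    if df.columns[0] != "frame":
        raise ValueError("wide dialect requires a leading 'frame' column")
    cell_ids = [str(c) for c in df.columns[1:]]
    if len(df) == 0:
        return TraceMatrix(cell_ids, np.empty((len(cell_ids), 0)), normalized)
    frames = _numeric(df["frame"], "frame index").astype(int)
    expected = np.arange(len(df))
    if not np.array_equal(frames, expected):
        missing = sorted(set(expected) - set(frames.tolist()))
        raise ValueError(
            f"frame indices must be contiguous from 0; first problem near "
            f"{missing[0] if missing else frames.tolist()[:5]}"
        )
    values = np.column_stack(
        [_numeric(df[c], f"value for cell {c!r}") for c in df.columns[1:]]
    ).T if cell_ids else np.empty((0, len(df)))
    return TraceMatrix(cell_ids, values, normalized)


def _read_long(df: pd.DataFrame, normalized: bool) -> TraceMatrix:
    required = ["cell_id", "frame", "value"]
    if list(df.columns[:3]) != required:
        raise ValueError(f"long dialect requires columns {required}, got {list(df.columns)}")
    if len(df) == 0:
        return TraceMatrix([], np.empty((0, 0)), normalized)
    frames = _numeric(df["frame"], "frame index").astype(int)
    values = _numeric(df["value"], "value")
    cells = df["cell_id"].astype(str)
    dup = df.assign(_f=frames).duplicated(subset=["cell_id", "_f"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValueError(
            f"duplicate (cell, frame) pair for cell {cells.iloc[row]!r} "
            f"frame {frames[row]}"
        )
    # preserve first-appearance order of cells
    cell_ids = list(dict.fromkeys(cells))
    n_frames = int(frames.max()) + 1
    mat = np.full((len(cell_ids), n_frames), np.nan)
    idx = {c: i for i, c in enumerate(cell_ids)}
    mat[[idx[c] for c in cells], frames] = values
    gaps = np.isnan(mat)
    if gaps.any():
        ci, fi = np.argwhere(gaps)[0]
        raise ValueError(
            f"cell {cell_ids[ci]!r} is missing frame {fi} "
            f"(every cell needs frames 0..{n_frames - 1})"
        )
    return TraceMatrix(cell_ids, mat, normalized)
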