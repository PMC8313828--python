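"""Ground-truthed synthetic data: calcium recordings, Griess plates,
morphometry tables.

The trace generator emulates mixed neuron/astrocyte culture recordings:
a noisy positive baseline, stimulus-locked transients (instantaneous
rise, exponential decay) placed only in a cell's true responding event
windows, optional extra spikes forming short oscillation trains, a
universal ionomycin response in the control window for every valid
cell, and a configurable fraction of invalid cells (dead or unloaded
ROIs, flat noise throughout).  Every cell's true category code, spike
counts and validity are returned alongside the traces so downstream
classification can be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import CATEGORY_CODES
from .events import EventSchedule
from .traces import TraceMatrix

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_traces",
    "simulate_griess_plate",
    "simulate_objects",
]


def _default_pattern_probs() -> dict[str, float]:
    # A plausible mixed-culture spectrum: many all-responders, a solid
    # non-responder fraction, the rest spread over partial combinations.
    return {
        "000": 0.15,
        "001": 0.05,
        "010": 0.05,
        "011": 0.10,
        "100": 0.10,
        "101": 0.10,
        "110": 0.10,
        "111": 0.35,
    }


@dataclass
class SimulationConfig:
    """Parameters of one synthetic culture recording.

    Amplitudes are folds over baseline; the responder threshold the
    downstream classifier will apply is 1.2, so ``peak_fold_range`` must
    stay above it and the per-frame noise must be small enough that
    nominally silent windows stay below it.
    """

    n_cells: int = 500
    pattern_probs: dict[str, float] = field(default_factory=_default_pattern_probs)
    baseline_mean: float = 100.0
    baseline_noise_sd: float = 2.0
    peak_fold_range: tuple[float, float] = (1.5, 3.0)
    decay_frames: int = 8
    spikes_per_response_range: tuple[int, int] = (1, 3)
    iono_fold: float = 4.0
    invalid_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        probs = {str(k): float(v) for k, v in self.pattern_probs.items()}
        unknown = set(probs) - set(CATEGORY_CODES)
        if unknown:
            raise ValueError(f"unknown category codes in pattern_probs: {sorted(unknown)}")
        if any(v < 0 for v in probs.values()):
            raise ValueError("pattern_probs must be nonnegative")
        total = sum(probs.values())
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError(f"pattern_probs must sum to 1, got {total}")
        self.pattern_probs = {c: probs.get(c, 0.0) for c in CATEGORY_CODES}
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        if self.baseline_noise_sd < 0:
            raise ValueError("baseline_noise_sd must be >= 0")
        lo, hi = self.peak_fold_range
        if not 1.2 < lo <= hi:
            raise ValueError("peak_fold_range must satisfy 1.2 < min <= max")
        if self.decay_frames < 1:
            raise ValueError("decay_frames must be >= 1")
        slo, shi = self.spikes_per_response_range
        if not 1 <= slo <= shi:
            raise ValueError("spikes_per_response_range must satisfy 1 <= min <= max")
        if self.iono_fold < 1.2:
            raise ValueError("iono_fold must be >= 1.2 (positive control must respond)")
        if not 0 <= self.invalid_fraction <= 1:
            raise ValueError("invalid_fraction must be a probability")

    def to_dict(self) -> dict:
        return {
            "n_cells": self.n_cells,
            "pattern_probs": dict(self.pattern_probs),
            "baseline_mean": self.baseline_mean,
            "baseline_noise_sd": self.baseline_noise_sd,
            "peak_fold_range": list(self.peak_fold_range),
            "decay_frames": self.decay_frames,
            "spikes_per_response_range": list(self.spikes_per_response_range),
            "iono_fold": self.iono_fold,
            "invalid_fraction": self.invalid_fraction,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("peak_fold_range", "spikes_per_response_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GroundTruth:
    """Per-cell truth record for one simulated culture."""

    table: pd.DataFrame  # columns: cell_id, true_code, valid, spikes_e1..e3
    config: SimulationConfig

    @property
    def codes(self) -> pd.Series:
        return self.table.set_index("cell_id")["true_code"]

    def __len__(self) -> int:
        return len(self.table)


def _spike_frames(
    rng: np.random.Generator,
    window: tuple[int, int],
    n_spikes: int,
    guard: int,
    min_gap: int = 3,
) -> list[int]:
    """Place spikes in (window start, window end - guard), >= min_gap apart.

    The first spike is stimulus-locked one frame after stimulus addition
    (so it is a strict local maximum inside its own window); extras land
    at uniformly random admissible frames.  The guard keeps each decay
    tail from contaminating the next window above threshold.
    """
    lo, hi = window
    first = lo + 1
    usable_hi = max(first + 1, hi - guard)
    frames = [first]
    choices = [f for f in range(first + min_gap, usable_hi)]
    rng.shuffle(choices)
    for f in choices:
        if len(frames) >= n_spikes:
            break
        if all(abs(f - g) >= min_gap for g in frames):
            frames.append(f)
    return sorted(frames)


def _add_transient(clean: np.ndarray, frame: int, excess: float, tau: float) -> None:
    """Instantaneous rise of `excess` (fold units) at `frame`, exp decay."""
    n = len(clean)
    t = np.arange(n - frame)
    clean[frame:] += excess * np.exp(-t / tau)


def simulate_traces(
    config: SimulationConfig, schedule: EventSchedule
) -> tuple[TraceMatrix, GroundTruth]:
    """Generate raw traces plus ground truth for one culture.

    Deterministic: identical (config, schedule) including ``config.seed``
    give bit-identical output.
    """
    if schedule.control_frame >= schedule.n_frames:
        raise ValueError("schedule control frame falls outside the recording")
    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    codes = list(config.pattern_probs)
    probs = np.array([config.pattern_probs[c] for c in codes])

    cell_ids = [f"cell{str(i).zfill(len(str(max(n - 1, 1))))}" for i in range(n)]
    values = np.empty((n, schedule.n_frames))
    records = []
    tau = float(config.decay_frames)
    # decay tail must drop below ~0.05 fold before the next window starts
    max_excess = max(config.peak_fold_range[1], config.iono_fold) - 1.0
    guard = int(math.ceil(tau * math.log(max(max_excess, 0.05) / 0.05)))

    for i in range(n):
        valid = bool(rng.random() >= config.invalid_fraction)
        code = codes[int(rng.choice(len(codes), p=probs))] if valid else "000"
        clean = np.ones(schedule.n_frames)
        spikes = [0, 0, 0]
        if valid:
            for e, window in enumerate(schedule.event_windows):
                if code[e] != "1":
                    continue
                k = int(rng.integers(*config.spikes_per_response_range, endpoint=True))
                frames = _spike_frames(rng, window, k, guard)
                for f in frames:
                    fold = rng.uniform(*config.peak_fold_range)
                    _add_transient(clean, f, fold - 1.0, tau)
                spikes[e] = len(frames)
            _add_transient(clean, schedule.control_frame, config.iono_fold - 1.0, tau)
        raw = clean * config.baseline_mean
        if config.baseline_noise_sd > 0:
            raw = raw + rng.normal(0.0, config.baseline_noise_sd, schedule.n_frames)
            np.maximum(raw, 1e-6, out=raw)  # truncate: fluorescence stays positive
        values[i] = raw
        records.append(
            {
                "cell_id": cell_ids[i],
                "true_code": code,
                "valid": valid,
                "spikes_e1": spikes[0],
                "spikes_e2": spikes[1],
                "spikes_e3": spikes[2],
            }
        )

    matrix = TraceMatrix(cell_ids, values, normalized=False)
    truth = GroundTruth(
        table=pd.DataFrame(
            records,
            columns=["cell_id", "true_code", "valid", "spikes_e1", "spikes_e2", "spikes_e3"],
        ),
        config=config,
    )
    return matrix, truth


def simulate_griess_plate(
    true_concs: list[float],
    slope: float,
    intercept: float,
    noise_sd: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate Griess-reagent absorbance wells from true nitrite
    concentrations: absorbance = intercept + slope * conc + N(0, noise_sd)."""
    if slope <= 0:
        raise ValueError("slope must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    concs = np.asarray(true_concs, dtype=float)
    if np.any(concs < 0):
        raise ValueError("concentrations must be >= 0")
    rng = np.random.default_rng(seed)
    absorbance = intercept + slope * concs
    if noise_sd > 0:
        absorbance = absorbance + rng.normal(0.0, noise_sd, len(concs))
    return pd.DataFrame(
        {
            "well": [f"W{i + 1}" for i in range(len(concs))],
            "absorbance": absorbance,
            "true_conc": concs,
        }
    )


def simulate_objects(
    n: int,
    area_mean: float,
    area_sd: float,
    roundness_mean: float = 0.8,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a morphometry object table (e.g. DAPI nuclei or Diffquik
    cell outlines): Gaussian areas truncated positive, beta-distributed
    roundness in (0, 1]."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if area_mean <= 0:
        raise ValueError("area_mean must be positive")
    if area_sd < 0:
        raise ValueError("area_sd must be >= 0")
    if not 0 < roundness_mean <= 1:
        raise ValueError("roundness_mean must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    areas = rng.normal(area_mean, area_sd, n) if area_sd > 0 else np.full(n, area_mean)
    areas = np.maximum(areas, area_mean * 1e-3)
    if roundness_mean == 1.0:
        roundness = np.ones(n)
    else:
        # beta with mean roundness_mean, fixed concentration
        conc = 20.0
        roundness = rng.beta(roundness_mean * conc, (1 - roundness_mean) * conc, n)
        roundness = np.clip(roundness, 1e-6, 1.0)
    return pd.DataFrame(
        {
            "object_id": [f"obj{i + 1}" for i in range(n)],
            "area": areas,
            "roundness": roundness,
        }
    )
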