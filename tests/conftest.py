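import numpy as np
import pytest

from caresp import ResponseProfile, paper_default_schedule


@pytest.fixture
def schedule():
    """Standard protocol: 4 s frames, baseline [0,50), stimuli at
    50/100/150, ionomycin at 200, 215 frames total."""
    return paper_default_schedule()


def make_profile(code: str, valid: bool = True, cell_id: str = "c",
                 spikes=(0, 0, 0), peaks=None) -> ResponseProfile:
    """Build a profile directly from a category code (test helper)."""
    flags = tuple(ch == "1" for ch in code)
    if peaks is None:
        peaks = tuple(1.5 if f else 1.0 for f in flags)
    return ResponseProfile(
        cell_id=cell_id,
        responder_flags=flags,
        control_responder=valid,
        spikes_per_event=tuple(spikes),
        dominant_peak_per_event=tuple(peaks),
        control_peak=4.0 if valid else 1.0,
    )


def make_profiles(counts: dict[str, int], n_invalid: int = 0) -> list[ResponseProfile]:
    """A culture with `counts[code]` valid cells per category code."""
    out = []
    i = 0
    for code, k in counts.items():
        for _ in range(k):
            out.append(make_profile(code, cell_id=f"c{i}"))
            i += 1
    for _ in range(n_invalid):
        out.append(make_profile("000", valid=False, cell_id=f"c{i}"))
        i += 1
    return out


def flat_trace_with_transients(schedule, transient_frames, fold=2.0,
                               baseline=100.0, decay=8.0) -> np.ndarray:
    """Raw trace: constant baseline plus exponential-decay transients."""
    trace = np.ones(schedule.n_frames)
    for f in transient_frames:
        t = np.arange(schedule.n_frames - f)
        trace[f:] += (fold - 1.0) * np.exp(-t / decay)
    return trace * baseline
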