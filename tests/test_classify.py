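"""Normalization, responder thresholding, spike counting, category codes."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from caresp import (
    SimulationConfig,
    Threshold,
    classify_cell,
    classify_culture,
    count_spikes,
    detect_event_response,
    normalize_trace,
    simulate_traces,
)
from conftest import flat_trace_with_transients


def spike_oracle(series, window, fold, min_sep):
    """Brute-force spike enumerator, independent of the implementation:
    list strict interior local maxima at/above the fold, then resolve
    separation conflicts highest-first (earlier wins ties)."""
    lo, hi = window
    seg = list(series[lo:hi])
    cands = []
    for i in range(1, len(seg) - 1):
        if seg[i] > seg[i - 1] and seg[i] > seg[i + 1] and seg[i] >= fold:
            cands.append(i)
    kept = []
    for i in sorted(cands, key=lambda j: (-seg[j], j)):
        if not any(abs(i - k) < min_sep for k in kept):
            kept.append(i)
    return len(kept)


class TestNormalize:
    def test_constant_series_maps_to_one(self, schedule):
        out = normalize_trace(np.full(schedule.n_frames, 100.0), schedule)
        assert np.allclose(out, 1.0)

    def test_fold_arithmetic(self, schedule):
        raw = np.full(schedule.n_frames, 200.0)
        raw[60] = 300.0
        out = normalize_trace(raw, schedule)
        assert out[60] == pytest.approx(1.5)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_output_baseline_mean_is_one(self, seed):
        from caresp import paper_default_schedule

        schedule = paper_default_schedule()
        rng = np.random.default_rng(seed)
        raw = rng.uniform(50, 150, schedule.n_frames)
        out = normalize_trace(raw, schedule)
        # independent recomputation of the baseline mean
        assert abs(sum(out[:50]) / 50 - 1.0) < 1e-12

    def test_length_mismatch_rejected(self, schedule):
        with pytest.raises(ValueError, match="length"):
            normalize_trace(np.ones(10), schedule)


class TestDetectEventResponse:
    @pytest.mark.parametrize(
        "peak,expected",
        [(1.25, True), (1.19, False), (1.20, True)],  # boundary is inclusive
    )
    def test_threshold_rule(self, peak, expected):
        series = np.ones(20)
        series[10] = peak
        responder, dominant = detect_event_response(series, (5, 15))
        assert responder is expected
        assert dominant == pytest.approx(peak)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            detect_event_response(np.ones(10), (5, 5))


class TestCountSpikes:
    def test_flat_window_has_no_spikes(self):
        assert count_spikes(np.ones(20), (0, 20)) == 0

    def test_single_transient_is_one_spike(self):
        s = np.ones(20)
        s[8:12] = [1.3, 1.5, 1.35, 1.1]
        assert count_spikes(s, (0, 20)) == 1

    @pytest.mark.parametrize("k", range(1, 7))
    def test_separated_train_counts_exactly_k(self, schedule, k):
        frames = [52 + 5 * i for i in range(k)]
        raw = flat_trace_with_transients(schedule, frames, fold=1.8, decay=1.5)
        norm = normalize_trace(raw, schedule)
        window = schedule.event_windows[0]
        assert count_spikes(norm, window) == k
        assert count_spikes(norm, window) == spike_oracle(norm, window, 1.2, 2)

    @pytest.mark.parametrize("min_sep", [2, 3, 4])
    def test_matches_oracle_on_exhaustive_short_grid(self, min_sep):
        """All 3^8 series over {1.0, 1.1, 1.5} agree with the oracle."""
        thr = Threshold(1.2)
        window = (0, 8)
        for vals in itertools.product((1.0, 1.1, 1.5), repeat=8):
            series = np.array(vals)
            assert count_spikes(series, window, thr, min_sep) == spike_oracle(
                series, window, 1.2, min_sep
            ), vals

    def test_conflicting_pair_keeps_larger(self):
        s = np.array([1.0, 1.5, 1.0, 1.4, 1.0, 1.0])
        assert count_spikes(s, (0, 6), min_separation_frames=3) == 1
        assert count_spikes(s, (0, 6), min_separation_frames=2) == 2


class TestClassifyCell:
    def test_all_events_and_control(self, schedule):
        raw = flat_trace_with_transients(schedule, [51, 101, 151, 201])
        p = classify_cell(raw, schedule)
        assert p.category_code == "111"
        assert p.valid

    def test_non_responder_still_answers_ionomycin(self, schedule):
        raw = flat_trace_with_transients(schedule, [201])
        p = classify_cell(raw, schedule)
        assert p.category_code == "000"
        assert p.valid
        assert p.is_non_responder

    def test_flat_cell_is_invalid(self, schedule):
        raw = flat_trace_with_transients(schedule, [])
        p = classify_cell(raw, schedule)
        assert not p.valid
        assert not p.is_non_responder

    @pytest.mark.parametrize("code", [f"{i:03b}" for i in range(8)])
    def test_every_category_code_reachable(self, schedule, code):
        frames = [w[0] + 1 for w, ch in zip(schedule.event_windows, code) if ch == "1"]
        raw = flat_trace_with_transients(schedule, frames + [201])
        assert classify_cell(raw, schedule).category_code == code

    def test_code_matches_flags(self, schedule):
        raw = flat_trace_with_transients(schedule, [101, 201])
        p = classify_cell(raw, schedule)
        for ch, flag in zip(p.category_code, p.responder_flags):
            assert (ch == "1") == flag

    def test_responder_peak_at_least_threshold(self, schedule):
        raw = flat_trace_with_transients(schedule, [51, 151, 201], fold=1.6)
        p = classify_cell(raw, schedule)
        for flag, peak in zip(p.responder_flags, p.dominant_peak_per_event):
            if flag:
                assert peak >= 1.2


class TestThresholdMonotonicity:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_raising_threshold_never_creates_responders(self, seed):
        from caresp import paper_default_schedule

        schedule = paper_default_schedule()
        rng = np.random.default_rng(seed)
        raw = rng.uniform(80, 140, schedule.n_frames)
        lo = classify_cell(raw, schedule, threshold=Threshold(1.2))
        hi = classify_cell(raw, schedule, threshold=Threshold(1.5))
        for f_lo, f_hi in zip(lo.responder_flags, hi.responder_flags):
            assert not (f_hi and not f_lo)


class TestClassifyCulture:
    def test_empty_matrix_gives_empty_list(self, schedule):
        from caresp import TraceMatrix

        assert classify_culture(TraceMatrix([], np.empty((0, 0))), schedule) == []

    def test_noiseless_culture_recovers_ground_truth(self, schedule):
        cfg = SimulationConfig(n_cells=300, baseline_noise_sd=0.0, seed=17)
        matrix, gt = simulate_traces(cfg, schedule)
        profiles = classify_culture(matrix, schedule)
        pred_codes = [p.category_code for p in profiles]
        assert pred_codes == gt.table.true_code.tolist()
        assert [p.valid for p in profiles] == gt.table.valid.tolist()
        pred_spikes = [p.spikes_per_event for p in profiles]
        true_spikes = list(
            gt.table[["spikes_e1", "spikes_e2", "spikes_e3"]].itertuples(
                index=False, name=None)
        )
        for ps, ts, v in zip(pred_spikes, true_spikes, gt.table.valid):
            if v:
                assert ps == ts

    def test_order_equivariance(self, schedule):
        from caresp import TraceMatrix

        cfg = SimulationConfig(n_cells=20, seed=23)
        matrix, _ = simulate_traces(cfg, schedule)
        perm = np.arange(20)[::-1]
        permuted = TraceMatrix(
            [matrix.cell_ids[i] for i in perm], matrix.values[perm]
        )
        a = classify_culture(matrix, schedule)
        b = classify_culture(permuted, schedule)
        assert [a[i] for i in perm] == b
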