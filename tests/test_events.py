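"""Swing-out detection, event counting and time normalization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hemegate.events import SwingRecord, count_events, detect_swing, normalized_swing_times
from hemegate.geometry import DistanceTrace


def _trace(values, spacing=0.2, cutoff=1.0):
    values = np.asarray(values, dtype=float)
    return DistanceTrace("t", np.arange(len(values)) * spacing, values,
                         equilibration_cutoff=cutoff)


def brute_force_scan(trace, threshold=0.7, down_threshold=0.7, dwell_min=5.0):
    """Independent frame-by-frame reference for detect_swing."""
    times, values = trace.analyzed()
    above = [v > threshold for v in values]
    swung = any(above)
    first = times[above.index(True)] if swung else None
    excursions = []
    start = None
    for t, up in zip(times, above):
        if up and start is None:
            start = t
        elif not up and start is not None:
            excursions.append((start, t))
            start = None
    if start is not None:
        excursions.append((start, None))
    returned = False
    if excursions and excursions[0][1] is not None:
        end = excursions[0][1]
        run = None
        for t, v in zip(times, values):
            if t < end:
                continue
            if v <= down_threshold:
                if run is None:
                    run = t
            else:
                if run is not None and t - run >= dwell_min:
                    returned = True
                run = None
        if run is not None and times[-1] - run >= dwell_min:
            returned = True
    return swung, first, excursions, returned


class TestDetectSwing:
    def test_constant_down_trace(self):
        rec = detect_swing(_trace(np.full(100, 0.45)))
        assert not rec.swung_out
        assert rec.first_exceed_time is None
        assert rec.excursions == ()
        assert not rec.returned_down

    def test_step_up_and_stay(self):
        values = np.full(200, 0.45)
        values[62:] = 0.9  # t = 12.4 ns at 0.2 ns spacing
        rec = detect_swing(_trace(values))
        assert rec.swung_out
        assert rec.first_exceed_time == pytest.approx(12.4)
        assert not rec.returned_down
        assert rec.excursions == ((pytest.approx(12.4), None),)

    def test_threshold_tie_is_not_exceeded(self):
        rec = detect_swing(_trace(np.full(50, 0.7)))
        assert not rec.swung_out

    def test_brief_dip_does_not_count_as_return(self):
        values = np.full(300, 0.9)
        values[:20] = 0.45
        values[150:160] = 0.5  # 2 ns dip < 5 ns dwell
        rec = detect_swing(_trace(values))
        assert rec.swung_out and not rec.returned_down

    def test_long_dwell_counts_as_return(self):
        values = np.full(300, 0.9)
        values[:20] = 0.45
        values[150:] = 0.5
        rec = detect_swing(_trace(values))
        assert rec.returned_down

    def test_equilibration_cutoff_excluded(self):
        values = np.full(100, 0.45)
        values[:4] = 0.95  # excursion entirely before 1 ns
        rec = detect_swing(_trace(values))
        assert not rec.swung_out

    def test_empty_analyzed_trace(self):
        with pytest.raises(ValueError):
            detect_swing(_trace([0.4, 0.4], cutoff=10.0))

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 100_000))
    def test_equals_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.uniform(0.4, 1.0, size=rng.integers(10, 200))
        trace = _trace(values)
        rec = detect_swing(trace)
        swung, first, excursions, returned = brute_force_scan(trace)
        assert rec.swung_out == swung
        if swung:
            assert rec.first_exceed_time == pytest.approx(first)
        assert len(rec.excursions) == len(excursions)
        for (a, b), (c, d) in zip(rec.excursions, excursions):
            assert a == pytest.approx(c)
            assert (b is None) == (d is None)
            if b is not None:
                assert b == pytest.approx(d)
        assert rec.returned_down == returned

    def test_raw_count_invariant_to_frame_refinement(self):
        coarse = np.array([0.45] * 30 + [0.9] * 30 + [0.45] * 30)
        fine = np.repeat(coarse, 4)
        rec_c = detect_swing(_trace(coarse, spacing=0.2))
        rec_f = detect_swing(_trace(fine, spacing=0.05))
        assert rec_c.swung_out == rec_f.swung_out
        assert len(rec_c.excursions) == len(rec_f.excursions)


def _record(rep, swung, t=None, total=150.0, chain="A", returned=False):
    return SwingRecord(
        replicate_id=rep, chain_id=chain, swung_out=swung, first_exceed_time=t,
        excursions=((t, None),) if swung else (), returned_down=returned,
        replicate_total_time=total,
    )


class TestCountEvents:
    def test_eight_of_ten_equal_time(self):
        records = []
        for r in range(5):
            for chain in ("A", "B"):
                idx = r * 2 + (chain == "B")
                records.append(_record(f"rep{r}", idx < 8, 10.0 if idx < 8 else None,
                                       chain=chain))
        summary = count_events(records, reference_total_time=5 * 150.0)
        assert summary.raw_event_count == 8
        assert summary.normalized_event_count == pytest.approx(8.0)
        assert summary.n_chain_replicates == 10

    def test_no_events_is_zero(self):
        records = [_record(f"rep{r}", False, total=37.0) for r in range(5)]
        assert count_events(records, 999.0).normalized_event_count == 0.0

    def test_half_time_doubles_count(self):
        records = [_record(f"rep{r}", r < 5, 10.0 if r < 5 else None, total=10.0)
                   for r in range(10)]
        summary = count_events(records, reference_total_time=200.0)
        assert summary.raw_event_count == 5
        assert summary.normalized_event_count == pytest.approx(10.0)

    def test_shared_replicate_time_counted_once(self):
        # two chains of one replicate share one simulation
        records = [_record("rep1", True, 5.0, total=100.0, chain="A"),
                   _record("rep1", False, total=100.0, chain="B")]
        summary = count_events(records, reference_total_time=100.0)
        assert summary.total_time == 100.0
        assert summary.normalized_event_count == pytest.approx(1.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            count_events([_record("rep1", False)], 0.0)


class TestNormalizedSwingTimes:
    def test_unit_factors_reduce_to_raw_times(self):
        records = [_record(f"rep{r}", True, 10.0 + r, total=150.0) for r in range(3)]
        times = normalized_swing_times(records, 150.0, 450.0, 450.0)
        assert times == pytest.approx([10.0, 11.0, 12.0])

    def test_half_length_replicate_doubles_time(self):
        records = [_record("rep1", True, 20.0, total=75.0)]
        times = normalized_swing_times(records, 150.0, 75.0, 75.0)
        assert times == pytest.approx([40.0])

    def test_no_events_gives_empty_list(self):
        records = [_record("rep1", False, total=150.0)]
        assert normalized_swing_times(records, 150.0, 150.0, 150.0) == []

    def test_record_invariants_enforced(self):
        with pytest.raises(ValueError):
            SwingRecord("r", "A", True, None, (), False, 100.0)
        with pytest.raises(ValueError):
            SwingRecord("r", "A", False, None, (), True, 100.0)
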