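from __future__ import annotations

from datetime import datetime, timedelta

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cgmagree.model import Cohort, GlucoseSample, PatientRecord, Source
from cgmagree.pairing import (
    ExclusionReason,
    ExclusionWindow,
    apply_exclusions,
    assign_postop_day,
    build_exclusions,
    match_pairs,
)
from conftest import T0, make_pair
from oracles import brute_force_match


def _patient(pid="A", doses=(), excluded=False):
    return PatientRecord(pid, T0, T0, list(doses), excluded, "dialysis" if excluded else None)


def _cohort_from_times(serum_minutes, cgm_minutes, pid="A"):
    samples = [
        GlucoseSample(pid, T0 + timedelta(seconds=int(m * 60)), 100.0, Source.SERUM)
        for m in serum_minutes
    ] + [
        GlucoseSample(pid, T0 + timedelta(seconds=int(m * 60)), 110.0, Source.CGM)
        for m in cgm_minutes
    ]
    return Cohort(patients=[_patient(pid)], samples=samples)


class TestPostopDay:
    @pytest.mark.parametrize(
        "elapsed_hours, day", [(0, 1), (23.99, 1), (24, 2), (150, 7), (167.9, 7)]
    )
    def test_half_open_24h_blocks(self, elapsed_hours, day):
        t = T0 + timedelta(hours=elapsed_hours)
        assert assign_postop_day(t, _patient()) == day

    def test_sample_before_anchor_is_an_error(self):
        with pytest.raises(ValueError, match="precedes"):
            assign_postop_day(T0 - timedelta(seconds=1), _patient())

    def test_surgery_end_anchor_selectable(self):
        p = PatientRecord("A", T0 + timedelta(hours=12), T0)
        t = T0 + timedelta(hours=13)
        assert assign_postop_day(t, p, anchor="sensor_start") == 1
        assert assign_postop_day(t, p, anchor="surgery_end") == 1
        assert assign_postop_day(T0 + timedelta(hours=37), p, anchor="sensor_start") == 2


class TestMatchPairs:
    def test_nearest_reading_wins(self):
        res = match_pairs(_cohort_from_times([10], [6, 12]))
        assert len(res.pairs) == 1
        assert res.pairs[0].delta_seconds == 120  # +2 min beats -4 min

    def test_window_boundary_inclusive_at_300s(self):
        res = match_pairs(_cohort_from_times([10], [15]))  # +300 s exactly
        assert len(res.pairs) == 1 and res.pairs[0].delta_seconds == 300

    def test_reading_one_second_outside_window_dropped_and_counted(self):
        res = match_pairs(_cohort_from_times([10], [15 + 1 / 60]))  # +301 s
        assert res.pairs == [] and res.dropped_serum == 1

    def test_tie_at_equal_delta_takes_earlier_reading(self):
        res = match_pairs(_cohort_from_times([10], [8, 12]))
        assert res.pairs[0].delta_seconds == -120

    def test_consumed_reading_skipped_next_nearest_used(self):
        # two draws at the same minute grid; the second must take the
        # remaining reading even though the first one is nearer
        res = match_pairs(_cohort_from_times([10, 11], [10.5, 14]))
        assert [p.delta_seconds for p in res.pairs] == [30, 180]

    def test_poc_samples_never_paired(self):
        cohort = _cohort_from_times([10], [10])
        cohort.samples.append(GlucoseSample("A", T0 + timedelta(minutes=20), 90.0, Source.POC))
        res = match_pairs(cohort)
        assert len(res.pairs) == 1

    def test_output_sorted_by_patient_then_time(self):
        samples = []
        for pid in ("B", "A"):
            for m in (30, 10):
                samples.append(GlucoseSample(pid, T0 + timedelta(minutes=m), 100.0, Source.SERUM))
                samples.append(GlucoseSample(pid, T0 + timedelta(minutes=m + 1), 105.0, Source.CGM))
        cohort = Cohort(patients=[_patient("A"), _patient("B")], samples=samples)
        keys = [(p.patient_id, p.serum_time) for p in match_pairs(cohort).pairs]
        assert keys == sorted(keys)

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(data=st.data())
    def test_agrees_with_exhaustive_all_pairs_search(self, data):
        # times on a 30 s grid so exact ties and |dt| = 300 s boundaries occur
        serum = data.draw(st.lists(st.integers(0, 240), min_size=1, max_size=6, unique=True))
        cgm = data.draw(st.lists(st.integers(0, 240), min_size=0, max_size=15, unique=True))
        serum_s = [m * 30 for m in serum]
        cgm_s = [m * 30 for m in cgm]
        expected = brute_force_match(serum_s, cgm_s, window=300)

        res = match_pairs(_cohort_from_times([s / 60 for s in serum_s], [c / 60 for c in cgm_s]))
        got = {
            (p.serum_time, p.cgm_time) for p in res.pairs
        }
        want = {
            (T0 + timedelta(seconds=serum_s[i]), T0 + timedelta(seconds=cgm_s[j]))
            for i, j in expected
        }
        assert got == want
        assert res.dropped_serum == len(serum_s) - len(expected)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(data=st.data())
    def test_shrinking_window_never_increases_pair_count(self, data):
        serum = data.draw(st.lists(st.integers(0, 100), min_size=1, max_size=6, unique=True))
        cgm = data.draw(st.lists(st.integers(0, 100), min_size=0, max_size=12, unique=True))
        cohort = _cohort_from_times(serum, cgm)
        counts = [len(match_pairs(cohort, window_seconds=w).pairs) for w in (60, 180, 300, 600)]
        assert counts == sorted(counts)


class TestExclusions:
    def test_no_doses_day1_off_gives_no_windows(self):
        assert build_exclusions([_patient()], exclude_day1=False) == []

    def test_first_dose_opens_an_unbounded_interference_window(self):
        dose = T0 + timedelta(days=3, hours=9)  # first dose on post-op day 4
        (w,) = build_exclusions([_patient(doses=[dose, dose + timedelta(days=1)])], exclude_day1=False)
        assert w.reason == ExclusionReason.DRUG_INTERFERENCE
        assert w.start == dose and w.end is None
        assert w.contains(dose)  # start-inclusive
        assert w.contains(dose + timedelta(days=30))  # open-ended

    def test_whole_patient_exclusion_covers_everything(self):
        (w,) = build_exclusions([_patient(excluded=True)], exclude_day1=False)
        assert w.reason == ExclusionReason.PATIENT_EXCLUDED
        assert w.contains(T0 - timedelta(days=999)) and w.contains(T0 + timedelta(days=999))

    def test_warmup_window_covers_exactly_day_one(self):
        (w,) = build_exclusions([_patient()], exclude_day1=True)
        assert w.reason == ExclusionReason.WARMUP_DAY1
        assert w.contains(T0)
        assert w.contains(T0 + timedelta(hours=23, minutes=59))
        assert not w.contains(T0 + timedelta(hours=24))  # end-exclusive

    def test_no_windows_is_identity(self):
        pairs = [make_pair(100, 110), make_pair(100, 90)]
        kept, removed = apply_exclusions(pairs, [])
        assert kept == pairs and removed == {}

    def test_pair_exactly_at_first_dose_time_removed(self):
        t = T0 + timedelta(days=3)
        pairs = [make_pair(100, 110, day=4, t=t)]
        windows = [ExclusionWindow("P001", t, None, ExclusionReason.DRUG_INTERFERENCE)]
        kept, removed = apply_exclusions(pairs, windows)
        assert kept == [] and removed == {ExclusionReason.DRUG_INTERFERENCE: 1}

    def test_windows_only_apply_to_their_own_patient(self):
        pairs = [make_pair(100, 110, pid="P001"), make_pair(100, 110, pid="P002")]
        windows = [ExclusionWindow("P001", None, None, ExclusionReason.PATIENT_EXCLUDED)]
        kept, removed = apply_exclusions(pairs, windows)
        assert [p.patient_id for p in kept] == ["P002"]
        assert removed == {ExclusionReason.PATIENT_EXCLUDED: 1}

    def test_constructed_drug_exclusion_count(self):
        # 30 pairs placed inside the interference window, 12 before it
        dose = T0 + timedelta(days=3)
        pairs = [
            make_pair(100, 110, day=4, t=dose + timedelta(hours=h)) for h in range(30)
        ] + [make_pair(100, 110, day=2, t=T0 + timedelta(days=1, hours=h)) for h in range(12)]
        windows = [ExclusionWindow("P001", dose, None, ExclusionReason.DRUG_INTERFERENCE)]
        kept, removed = apply_exclusions(pairs, windows)
        assert removed == {ExclusionReason.DRUG_INTERFERENCE: 30}
        assert len(kept) == 12

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(data=st.data())
    def test_kept_and_removed_partition_the_input(self, data):
        n = data.draw(st.integers(0, 40))
        pairs = [
            make_pair(100, 110, day=1 + h // 24, t=T0 + timedelta(hours=h))
            for h in data.draw(st.lists(st.integers(0, 96), min_size=n, max_size=n))
        ]
        pairs.sort(key=lambda p: p.serum_time)
        windows = build_exclusions(
            [_patient("P001", doses=[T0 + timedelta(hours=data.draw(st.integers(0, 96)))],
                      excluded=data.draw(st.booleans()))],
            exclude_day1=data.draw(st.booleans()),
        )
        kept, removed = apply_exclusions(pairs, windows)
        assert len(kept) + sum(removed.values()) == len(pairs)
        assert kept == [p for p in pairs if p in kept]  # order preserved
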