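"""CED windowing, shortlisting, recurrence and age banding."""

from datetime import date, timedelta

import pytest
from hypothesis import given
from hypothesis import strategies as st

from cedlar import (
    DEFAULT_SCHEME,
    Modality,
    Patient,
    PatientHistory,
    Protocol,
    Sex,
    assign_age_group,
    average_study_interval,
    compute_ced,
    recurrent_ct_rate,
    shortlist_patients,
)
from cedlar.errors import EmptyHistoryError, OutOfSchemeError, UndefinedRateError
from conftest import history_from_days, make_ct


def brute_force_ced(history, window_years=5):
    """Independent O(n^2) oracle: for every anchor exam, sum doses in the
    half-open window (anchor - window_years, anchor]."""
    exams = [e for e in history.exams if e.modality is not Modality.NUCLEAR]
    best = None
    for anchor in exams:
        try:
            start = anchor.study_date.replace(
                year=anchor.study_date.year - window_years
            )
        except ValueError:
            start = anchor.study_date.replace(
                year=anchor.study_date.year - window_years, day=28
            )
        total = sum(
            e.effective_dose_mSv
            for e in exams
            if start < e.study_date <= anchor.study_date
        )
        if best is None or total > best:
            best = total
    return best


class TestComputeCed:
    def test_single_exam(self):
        res = compute_ced(history_from_days([(0, 12.5)]))
        assert res.ced_mSv == 12.5
        assert res.contributing_exam_count == 1

    def test_exams_six_years_apart_never_co_windowed(self):
        hist = history_from_days([(0, 60.0), (6 * 365 + 2, 60.0)])
        assert compute_ced(hist, window_years=5).ced_mSv == 60.0

    def test_boundary_exam_at_window_start_excluded(self):
        # half-open window: an exam exactly 5 calendar years before the
        # anchor does not co-window with it
        origin = date(2015, 3, 1)
        hist = PatientHistory(
            [
                make_ct(day=0, dose=50.0, origin=origin),
                make_ct(day=0, dose=60.0, origin=date(2020, 3, 1)),
            ]
        )
        assert compute_ced(hist).ced_mSv == 60.0

    def test_window_reported_is_the_maximizing_one(self):
        hist = history_from_days([(0, 10.0), (10, 30.0), (3000, 5.0)])
        res = compute_ced(hist)
        assert res.ced_mSv == 40.0
        assert res.window[1] == date(2021, 1, 11)
        assert res.contributing_exam_count == 2

    def test_nuclear_only_history_raises(self):
        hist = PatientHistory(
            [make_ct(modality=Modality.NUCLEAR, protocol=Protocol.NUCLEAR_MED, dose=5)]
        )
        with pytest.raises(EmptyHistoryError):
            compute_ced(hist)

    def test_fixture_entry_2_reproduces_printed_total(self, expanded_histories):
        res = compute_ced(expanded_histories[1])
        assert res.ced_mSv == pytest.approx(223.0, abs=1e-9)

    @given(
        st.lists(
            st.tuples(st.integers(0, 4000), st.floats(0.01, 50)),
            min_size=1,
            max_size=50,
        ),
        st.integers(1, 6),
    )
    def test_matches_exhaustive_window_oracle(self, rows, window_years):
        hist = history_from_days(rows)
        res = compute_ced(hist, window_years=window_years)
        assert res.ced_mSv == pytest.approx(
            brute_force_ced(hist, window_years), rel=1e-12
        )


class TestShortlist:
    def test_fixture_counts_at_standard_thresholds(self, expanded_histories):
        assert len(shortlist_patients(expanded_histories, 100)) == 22
        top7 = shortlist_patients(expanded_histories, 150)
        assert len(top7) == 7
        assert [r.patient_id for r in top7] == [f"T2-{i:02d}" for i in range(1, 8)]

    def test_threshold_zero_returns_everyone_sorted(self, expanded_histories):
        res = shortlist_patients(expanded_histories, 0)
        assert len(res) == 22
        assert all(a.ced_mSv >= b.ced_mSv for a, b in zip(res, res[1:]))

    @given(st.floats(0, 300), st.floats(0, 300))
    def test_raising_threshold_never_enlarges_shortlist(
        self, t1, t2
    ):
        lo, hi = sorted([t1, t2])
        hists = [
            history_from_days([(0, 120.0)], pid="A"),
            history_from_days([(0, 80.0), (30, 90.0)], pid="B"),
            history_from_days([(0, 5.0)], pid="C"),
        ]
        assert len(shortlist_patients(hists, hi)) <= len(
            shortlist_patients(hists, lo)
        )

    def test_ced_additive_for_co_windowed_histories(self):
        a = history_from_days([(0, 10.0), (5, 20.0)])
        b = history_from_days([(2, 7.0), (9, 3.0)])
        merged = PatientHistory(a.exams + b.exams)
        assert compute_ced(merged).ced_mSv == pytest.approx(
            compute_ced(a).ced_mSv + compute_ced(b).ced_mSv
        )


class TestInterval:
    @pytest.mark.parametrize(
        "days,expected", [([0, 2, 4], 2.0), ([0, 1, 5], 2.5)]
    )
    def test_mean_gap(self, days, expected):
        hist = history_from_days([(d, 1.0) for d in days])
        assert average_study_interval(hist) == expected

    def test_fixture_entry_7_interval(self, expanded_histories):
        # 33 exams constructed at the printed 1.2-day average spacing
        assert round(average_study_interval(expanded_histories[6]), 1) == 1.2


class TestRecurrence:
    def test_three_cts_one_patient(self):
        recs = [make_ct(day=d, dose=1) for d in (0, 10, 20)]
        period = (date(2021, 1, 1), date(2021, 12, 31))
        assert recurrent_ct_rate(recs, period) == (2, 3, pytest.approx(2 / 3))

    def test_all_patients_distinct_means_no_recurrence(self):
        recs = [make_ct(pid=f"P{i}", day=i) for i in range(5)]
        period = (date(2021, 1, 1), date(2021, 12, 31))
        assert recurrent_ct_rate(recs, period)[0] == 0

    def test_out_of_period_and_non_ct_records_ignored(self):
        period = (date(2021, 1, 1), date(2021, 12, 31))
        recs = [
            make_ct(day=0),
            make_ct(day=5, modality=Modality.RADIOGRAPH, protocol=Protocol.XRAY),
            make_ct(day=400),  # outside period
        ]
        assert recurrent_ct_rate(recs, period) == (0, 1, 0.0)

    def test_no_cts_raises(self):
        period = (date(2021, 1, 1), date(2021, 12, 31))
        with pytest.raises(UndefinedRateError):
            recurrent_ct_rate([], period)


class TestAgeBands:
    def test_bands_partition_15_to_90(self):
        for age in range(15, 91):
            band = DEFAULT_SCHEME.band_for(age)
            assert band.lo <= age <= band.hi
        assert len(DEFAULT_SCHEME.bands) == 8

    @pytest.mark.parametrize("age,lo", [(70, 61), (71, 71), (20, 15), (21, 21)])
    def test_boundaries(self, age, lo):
        assert DEFAULT_SCHEME.band_for(age).lo == lo

    def test_fixture_range_uses_upper_bound(self, fixture_entries):
        # 79-81-year-old lands in 81-90; 69-70-year-old in 61-70
        assert assign_age_group(fixture_entries[12].patient).label == "81-90"
        assert assign_age_group(fixture_entries[4].patient).label == "61-70"

    def test_birth_date_patient_uses_reference_date(self):
        p = Patient(patient_id="X", sex=Sex.M, birth_date=date(1980, 6, 15))
        assert assign_age_group(p, reference_date=date(2021, 6, 14)).label == "31-40"
        assert assign_age_group(p, reference_date=date(2021, 6, 15)).label == "41-50"

    def test_out_of_scheme_age(self):
        p = Patient(patient_id="X", sex=Sex.F, age_range=(93, 95))
        with pytest.raises(OutOfSchemeError):
            assign_age_group(p)
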