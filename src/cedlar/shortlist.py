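"""Cumulative effective dose over a rolling window, threshold shortlisting,
study-interval and recurrence statistics, and age-band assignment.

CED is computed as the maximum, over windows of a fixed number of calendar
years anchored at each exam date, of the summed effective doses of the
patient's non-nuclear-medicine exams falling inside the window.  Windows
are half-open ``(anchor - years, anchor]``: an exam exactly at the window
start is excluded, so adjacent windows never double-count an event.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from datetime import date
from itertools import accumulate
from typing import Iterable, Sequence

from .errors import (
    EmptyHistoryError,
    OutOfSchemeError,
    UndefinedIntervalError,
    UndefinedRateError,
)
from .records import ExamRecord, Modality, Patient, PatientHistory

__all__ = [
    "AgeBand",
    "AgeGroupScheme",
    "DEFAULT_SCHEME",
    "CedResult",
    "compute_ced",
    "shortlist_patients",
    "average_study_interval",
    "mark_recurrent",
    "recurrent_ct_rate",
    "age_in_years",
    "assign_age_group",
]


@dataclass(frozen=True, order=True)
class AgeBand:
    lo: int
    hi: int

    @property
    def label(self) -> str:
        return f"{self.lo}-{self.hi}"

    def __contains__(self, age: int) -> bool:
        return self.lo <= age <= self.hi


@dataclass(frozen=True)
class AgeGroupScheme:
    """Ordered, non-overlapping integer age bands covering 15-90 years."""

    bands: tuple[AgeBand, ...]

    def __post_init__(self):
        for a, b in zip(self.bands, self.bands[1:]):
            if b.lo != a.hi + 1:
                raise ValueError(f"bands not contiguous: {a.label}, {b.label}")

    def band_for(self, age: int | float) -> AgeBand:
        age = int(age)
        for band in self.bands:
            if age in band:
                return band
        raise OutOfSchemeError(
            f"age {age} outside scheme {self.bands[0].lo}-{self.bands[-1].hi}"
        )


#: The ten-year grouping used for every stratified summary.
DEFAULT_SCHEME = AgeGroupScheme(
    bands=(
        AgeBand(15, 20),
        AgeBand(21, 30),
        AgeBand(31, 40),
        AgeBand(41, 50),
        AgeBand(51, 60),
        AgeBand(61, 70),
        AgeBand(71, 80),
        AgeBand(81, 90),
    )
)


@dataclass(frozen=True)
class CedResult:
    patient_id: str
    ced_mSv: float
    window: tuple[date, date]
    contributing_exam_count: int


def _years_before(d: date, years: int) -> date:
    try:
        return d.replace(year=d.year - years)
    except ValueError:  # Feb 29 in a non-leap target year
        return d.replace(year=d.year - years, day=28)


def compute_ced(history: PatientHistory, window_years: int = 5) -> CedResult:
    """Maximum windowed cumulative effective dose for one patient.

    Nuclear-medicine events are excluded before summation.  The reported
    window is the maximising one; ties break toward the earliest window
    start.  Raises EmptyHistoryError when no irradiating event remains.
    """
    if window_years <= 0:
        raise ValueError("window_years must be positive")
    exams = [e for e in history.exams if e.modality is not Modality.NUCLEAR]
    if not exams:
        raise EmptyHistoryError(
            f"patient {history.patient_id!r}: no non-nuclear irradiating events"
        )
    dates = [e.study_date for e in exams]
    prefix = [0.0, *accumulate(e.effective_dose_mSv for e in exams)]

    best_sum = -1.0
    best: tuple[date, date, int] | None = None
    for j, anchor in enumerate(dates):
        start = _years_before(anchor, window_years)
        left = bisect_right(dates, start)  # first exam with date > start
        total = prefix[j + 1] - prefix[left]
        if total > best_sum:
            best_sum = total
            best = (start, anchor, j + 1 - left)
    assert best is not None
    return CedResult(
        patient_id=history.patient_id,
        ced_mSv=best_sum,
        window=(best[0], best[1]),
        contributing_exam_count=best[2],
    )


def shortlist_patients(
    histories: Iterable[PatientHistory],
    threshold_mSv: float = 100.0,
    window_years: int = 5,
) -> list[CedResult]:
    """Patients whose windowed CED meets the threshold, sorted by
    descending CED.  Histories left empty by the nuclear-medicine
    exclusion are skipped (they cannot exceed any positive threshold)."""
    if threshold_mSv <= 0 and threshold_mSv != 0:
        raise ValueError("threshold_mSv must be non-negative")
    results = []
    for history in histories:
        try:
            res = compute_ced(history, window_years=window_years)
        except EmptyHistoryError:
            continue
        if res.ced_mSv >= threshold_mSv:
            results.append(res)
    return sorted(results, key=lambda r: (-r.ced_mSv, r.patient_id))


def average_study_interval(history: PatientHistory) -> float:
    """Mean gap in days between successive exams:
    (last date - first date) / (n - 1)."""
    if len(history.exams) < 2:
        raise UndefinedIntervalError(
            f"patient {history.patient_id!r}: interval needs >= 2 exams"
        )
    span = (history.exams[-1].study_date - history.exams[0].study_date).days
    return span / (len(history.exams) - 1)


def mark_recurrent(
    records: Sequence[ExamRecord], period: tuple[date, date]
) -> list[bool]:
    """Flag, for each record, whether it is a recurrent CT study.

    A CT study is recurrent when the same patient has at least one earlier
    CT study within the period; equivalently, every in-period CT of a
    patient beyond their first is recurrent.  Same-date CTs are ordered by
    their position in the input stream.  Non-CT and out-of-period records
    are flagged False.
    """
    start, end = period
    if end < start:
        raise ValueError("period end precedes start")
    seen: set[str] = set()
    flags = [False] * len(records)
    order = sorted(
        (
            i
            for i, r in enumerate(records)
            if r.modality is Modality.CT and start <= r.study_date <= end
        ),
        key=lambda i: (records[i].study_date, i),
    )
    for i in order:
        pid = records[i].patient_id
        if pid in seen:
            flags[i] = True
        else:
            seen.add(pid)
    return flags


def recurrent_ct_rate(
    records: Sequence[ExamRecord], period: tuple[date, date]
) -> tuple[int, int, float]:
    """(recurrent CT count, total CT count, recurrent fraction) within a
    reporting period."""
    start, end = period
    flags = mark_recurrent(records, period)
    total = sum(
        1
        for r in records
        if r.modality is Modality.CT and start <= r.study_date <= end
    )
    if total == 0:
        raise UndefinedRateError("no CT studies in period")
    recurrent = sum(flags)
    return recurrent, total, recurrent / total


def age_in_years(birth_date: date, on: date) -> int:
    """Completed years of age on a reference date."""
    years = on.year - birth_date.year
    if (on.month, on.day) < (birth_date.month, birth_date.day):
        years -= 1
    return years


def assign_age_group(
    patient: Patient,
    reference_date: date | None = None,
    scheme: AgeGroupScheme = DEFAULT_SCHEME,
) -> AgeBand:
    """Age band of a patient at the reference (most recent exam) date.

    Patients whose age is stored as a printed range use the upper end of
    the range — the assignment that reproduces all published band
    placements, including the 79-81-year-old in band 81-90.
    """
    if patient.age_range is not None:
        return scheme.band_for(patient.age_range[1])
    if patient.birth_date is None or reference_date is None:
        raise ValueError("need birth_date and reference_date, or an age_range")
    return scheme.band_for(age_in_years(patient.birth_date, reference_date))
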