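"""Grouped descriptive statistics and report-table builders.

All stratified summaries report median, SD (n-1 denominator), IQR
(25th-75th percentile by linear interpolation between order statistics)
and min-max, grouped by sex and ten-year age band.  The median of an
even-sized sample is the mean of the two central order statistics.
Empty strata are emitted as explicit not-available rows rather than
dropped, mirroring registry-report practice.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .lar import CancerSite, LARResult
from .records import ExamRecord, Modality, Patient, Sex
from .shortlist import (
    DEFAULT_SCHEME,
    AgeBand,
    AgeGroupScheme,
    CedResult,
    age_in_years,
    assign_age_group,
    mark_recurrent,
)

__all__ = [
    "SummaryStats",
    "CohortSummary",
    "summarize",
    "group_ced_summary",
    "build_exam_mix_table",
    "build_lar_site_table",
    "build_lar_total_table",
]


@dataclass(frozen=True)
class SummaryStats:
    n: int
    median: float
    sd: float | None  # undefined (None) for a single observation
    q25: float
    q75: float
    min: float
    max: float


def summarize(values: Sequence[float]) -> SummaryStats:
    """Median / SD / IQR / range of a non-empty sample."""
    if len(values) == 0:
        raise ValueError("cannot summarize an empty sample")
    arr = np.asarray(values, dtype=float)
    return SummaryStats(
        n=arr.size,
        median=float(np.median(arr)),
        sd=float(np.std(arr, ddof=1)) if arr.size > 1 else None,
        q25=float(np.percentile(arr, 25)),
        q75=float(np.percentile(arr, 75)),
        min=float(arr.min()),
        max=float(arr.max()),
    )


@dataclass(frozen=True)
class CohortSummary:
    """Summary of one quantity in one (sex, age band) stratum.

    ``stats`` is None for an empty (not-available) stratum.  ``percent``
    is the stratum's share of patients within its sex, rounded to the
    nearest whole percent as in registry reports.
    """

    sex: Sex
    band: AgeBand
    quantity: str
    stats: SummaryStats | None
    percent: float | None

    @property
    def available(self) -> bool:
        return self.stats is not None


def group_ced_summary(
    shortlisted: Iterable[tuple[Patient, float]],
    scheme: AgeGroupScheme = DEFAULT_SCHEME,
    reference_dates: Mapping[str, date] | None = None,
    quantity: str = "CED mSv",
) -> dict[tuple[Sex, AgeBand], CohortSummary]:
    """Per-(sex, band) summaries of a per-patient quantity.

    ``shortlisted`` pairs each patient with their value (typically the
    windowed CED in mSv).  Every band of the scheme is present for both
    sexes; empty strata carry stats=None.
    """
    values: dict[tuple[Sex, AgeBand], list[float]] = {}
    sex_totals: dict[Sex, int] = {Sex.M: 0, Sex.F: 0}
    for patient, value in shortlisted:
        ref = (reference_dates or {}).get(patient.patient_id)
        band = assign_age_group(patient, reference_date=ref, scheme=scheme)
        values.setdefault((patient.sex, band), []).append(value)
        sex_totals[patient.sex] += 1

    out: dict[tuple[Sex, AgeBand], CohortSummary] = {}
    for sex in (Sex.M, Sex.F):
        for band in scheme.bands:
            vals = values.get((sex, band))
            if vals:
                stats = summarize(vals)
                pct = round(100.0 * len(vals) / sex_totals[sex])
            else:
                stats, pct = None, (0.0 if sex_totals[sex] else None)
            out[(sex, band)] = CohortSummary(
                sex=sex, band=band, quantity=quantity, stats=stats, percent=pct
            )
    return out


def build_exam_mix_table(
    records: Sequence[ExamRecord],
    period: tuple[date, date],
    patients: Mapping[str, Patient] | None = None,
) -> pd.DataFrame:
    """Per-protocol CT study counts, percentage shares (one decimal),
    sex split, age summary and recurrent counts for a reporting period.

    Recurrent studies (every in-period CT of a patient beyond their
    first) are attributed to the protocol of the recurrent study, so the
    per-protocol recurrent counts partition the overall recurrent count.
    Sex and age columns require a patient lookup and are NA without one.
    """
    start, end = period
    flags = mark_recurrent(records, period)
    in_period = [
        (r, f)
        for r, f in zip(records, flags)
        if r.modality is Modality.CT and start <= r.study_date <= end
    ]
    total = len(in_period)

    rows = []
    protocols = sorted(
        {r.protocol for r, _ in in_period}, key=lambda p: p.value
    )
    for protocol in protocols:
        sub = [(r, f) for r, f in in_period if r.protocol is protocol]
        n = len(sub)
        n_male = n_female = None
        ages: list[int] = []
        if patients is not None:
            n_male = sum(
                1 for r, _ in sub if patients[r.patient_id].sex is Sex.M
            )
            n_female = n - n_male
            for r, _ in sub:
                p = patients[r.patient_id]
                if p.birth_date is not None:
                    ages.append(age_in_years(p.birth_date, r.study_date))
                elif p.age_range is not None:
                    ages.append(p.age_range[1])
        age_stats = summarize(ages) if ages else None
        rows.append(
            {
                "protocol": protocol.value,
                "n_studies": n,
                "percent": round(100.0 * n / total, 1) if total else 0.0,
                "n_male": n_male,
                "n_female": n_female,
                "age_median": age_stats.median if age_stats else None,
                "age_sd": age_stats.sd if age_stats else None,
                "age_min": age_stats.min if age_stats else None,
                "age_max": age_stats.max if age_stats else None,
                "n_recurrent": sum(1 for _, f in sub if f),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "protocol", "n_studies", "percent", "n_male", "n_female",
            "age_median", "age_sd", "age_min", "age_max", "n_recurrent",
        ],
    )
    df = df.sort_values("n_studies", ascending=False, kind="stable")
    return df.reset_index(drop=True)


def _band_rows(
    profiles: Sequence[tuple[Sex, AgeBand, LARResult, LARResult]],
    scheme: AgeGroupScheme,
):
    grouped: dict[tuple[Sex, AgeBand], list[tuple[LARResult, LARResult]]] = {}
    for sex, band, inc, mort in profiles:
        grouped.setdefault((sex, band), []).append((inc, mort))
    for sex in (Sex.M, Sex.F):
        for band in scheme.bands:
            yield sex, band, grouped.get((sex, band), [])


def build_lar_site_table(
    profiles: Sequence[tuple[Sex, AgeBand, LARResult, LARResult]],
    kind: str = "incidence",
    scheme: AgeGroupScheme = DEFAULT_SCHEME,
) -> pd.DataFrame:
    """Per-(sex, band) median and IQR of per-site LAR, per 100 patients.

    Single-member strata echo the member's value (median = q25 = q75);
    empty strata are NA rows.
    """
    if kind not in ("incidence", "mortality"):
        raise ValueError(f"kind must be incidence/mortality, got {kind!r}")
    idx = 0 if kind == "incidence" else 1
    rows = []
    for sex, band, members in _band_rows(profiles, scheme):
        row: dict[str, object] = {"sex": sex.value, "band": band.label,
                                  "n": len(members)}
        for site in CancerSite:
            vals = [m[idx].per_100.get(site) for m in members]
            vals = [v for v in vals if v is not None]
            if vals:
                s = summarize(vals)
                row[f"{site.value}_median"] = s.median
                row[f"{site.value}_q25"] = s.q25
                row[f"{site.value}_q75"] = s.q75
            else:
                row[f"{site.value}_median"] = None
                row[f"{site.value}_q25"] = None
                row[f"{site.value}_q75"] = None
        rows.append(row)
    return pd.DataFrame(rows)


def build_lar_total_table(
    profiles: Sequence[tuple[Sex, AgeBand, LARResult, LARResult]],
    scheme: AgeGroupScheme = DEFAULT_SCHEME,
) -> pd.DataFrame:
    """Per-(sex, band) median and min-max of total LAR of incidence and
    mortality, per 100 patients."""
    rows = []
    for sex, band, members in _band_rows(profiles, scheme):
        row: dict[str, object] = {"sex": sex.value, "band": band.label,
                                  "n": len(members)}
        for label, idx in (("incidence", 0), ("mortality", 1)):
            vals = [m[idx].total_per_100 for m in members]
            if vals:
                s = summarize(vals)
                row[f"{label}_median"] = s.median
                row[f"{label}_min"] = s.min
                row[f"{label}_max"] = s.max
            else:
                row[f"{label}_median"] = None
                row[f"{label}_min"] = None
                row[f"{label}_max"] = None
        rows.append(row)
    return pd.DataFrame(rows)
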