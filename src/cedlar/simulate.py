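"""Synthetic dose-registry generation with known ground truth.

Two generators are provided:

* :func:`simulate_registry` draws a stochastic registry from a
  :class:`SimulationConfig`: a per-patient recurrence process
  (zero-truncated negative binomial with an explicit high-recurrence
  subpopulation, giving the overdispersion needed to produce both a
  ~5 % recurrent-study rate and a small tail of patients with ten or
  more CTs), a categorical CT protocol mix, right-skewed (log-normal)
  per-exam effective doses per protocol, and an adult age/sex structure.
  The per-patient true CED is returned alongside the records.

* :func:`registry_from_exam_mix` deterministically reconstructs a
  registry matching a printed exam-mix table exactly: per-protocol study
  counts, sex splits and recurrent-study counts are reproduced by
  construction (each recurrent study is a second CT of a patient who
  already has one in the period).

All randomness flows through one explicitly seeded generator; identical
seeds give bit-identical registries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import stats

from .errors import UnsupportedOracleError
from .records import (
    ExamRecord,
    Modality,
    Patient,
    PatientHistory,
    Protocol,
    Sex,
    histories_from_records,
    load_table1_exam_mix,
)
from .shortlist import _years_before, shortlist_patients

__all__ = [
    "DoseModel",
    "RecurrenceModel",
    "SimulationConfig",
    "SimulatedRegistry",
    "default_config",
    "simulate_registry",
    "simulate_shortlist_experiment",
    "registry_from_exam_mix",
    "ExperimentResult",
]


class DoseModel(BaseModel):
    """Log-normal per-exam effective dose: median (mSv) and geometric SD.

    gsd = 1 degenerates to a point mass at the median.
    """

    model_config = ConfigDict(frozen=True)

    median_mSv: float = Field(gt=0)
    gsd: float = Field(ge=1.0)


class RecurrenceModel(BaseModel):
    """Per-patient CT count model.

    Baseline counts follow a zero-truncated negative binomial with the
    given mean and dispersion; a fraction of patients instead draw from a
    high-recurrence component with a larger mean.  ``fixed_count``
    overrides the whole model with a constant (used for degenerate
    oracle configurations).
    """

    model_config = ConfigDict(frozen=True)

    mean: float = Field(default=1.15, gt=0)
    dispersion: float = Field(default=0.3, gt=0)
    high_fraction: float = Field(default=0.005, ge=0.0, lt=1.0)
    high_mean: float = Field(default=8.0, gt=0)
    fixed_count: int | None = Field(default=None, ge=1)


class SimulationConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    n_patients: int = Field(gt=0)
    period: tuple[date, date] = (date(2021, 1, 1), date(2021, 12, 31))
    protocol_mix: dict[str, float]
    dose_models: dict[str, DoseModel]
    recurrence: RecurrenceModel = RecurrenceModel()
    male_fraction: float = Field(default=0.679, ge=0.0, le=1.0)
    age_mean: float = Field(default=48.0, gt=0)
    age_sd: float = Field(default=18.0, gt=0)
    age_min: int = Field(default=18, ge=18)
    age_max: int = Field(default=90, le=90)
    xray_rate: float = Field(default=0.5, ge=0.0)
    xray_dose: DoseModel = DoseModel(median_mSv=0.02, gsd=2.0)
    window_years: int = Field(default=5, ge=1)
    seed: int = 0

    @model_validator(mode="after")
    def _validate(self) -> "SimulationConfig":
        start, end = self.period
        if end < start:
            raise ValueError("period: end precedes start")
        if abs(sum(self.protocol_mix.values()) - 1.0) > 1e-9:
            raise ValueError("protocol_mix: probabilities must sum to 1")
        for name in self.protocol_mix:
            Protocol(name)  # raises on unknown code
            if name not in self.dose_models:
                raise ValueError(f"dose_models: missing entry for {name!r}")
        if self.age_min > self.age_max:
            raise ValueError("age_min exceeds age_max")
        return self


#: Study-year protocol shares (from the printed 4406-study exam mix) and
#: plausible per-protocol effective-dose medians for a trauma-centre CT
#: service.  Assumed, not measured: the source reports no per-exam dose
#: distributions.
_DEFAULT_DOSE_MODELS = {
    "ABD_PELVIS_C": DoseModel(median_mSv=14.0, gsd=1.5),
    "POLYTRAUMA": DoseModel(median_mSv=20.0, gsd=1.5),
    "KUB": DoseModel(median_mSv=7.0, gsd=1.5),
    "BRAIN_STROKE_CTA": DoseModel(median_mSv=9.0, gsd=1.5),
    "CHEST_ABD_PELVIS_C": DoseModel(median_mSv=18.0, gsd=1.5),
    "TRIPHASIC_LIVER": DoseModel(median_mSv=25.0, gsd=1.5),
    "ABD_ANGIO": DoseModel(median_mSv=20.0, gsd=1.5),
}


def default_config(n_patients: int = 4000, seed: int = 0) -> SimulationConfig:
    """Configuration emulating the study year's registry structure."""
    mix_df = load_table1_exam_mix()
    total = int(mix_df["n_studies"].sum())
    mix = {
        str(r.protocol): r.n_studies / total for r in mix_df.itertuples()
    }
    return SimulationConfig(
        n_patients=n_patients,
        protocol_mix=mix,
        dose_models=dict(_DEFAULT_DOSE_MODELS),
        seed=seed,
    )


@dataclass(frozen=True)
class SimulatedRegistry:
    records: list[ExamRecord]
    patients: dict[str, Patient]
    truth: pd.DataFrame  # patient_id, true_ced_mSv, n_ct, n_xray

    def histories(self) -> list[PatientHistory]:
        return histories_from_records(self.records, self.patients)


def _draw_ct_counts(
    rng: np.random.Generator, n: int, model: RecurrenceModel
) -> np.ndarray:
    if model.fixed_count is not None:
        return np.full(n, model.fixed_count, dtype=int)
    means = np.where(
        rng.random(n) < model.high_fraction, model.high_mean, model.mean
    )
    r = model.dispersion
    p = r / (r + means)
    counts = rng.negative_binomial(r, p)
    zero = counts == 0  # zero-truncation by resampling
    while zero.any():
        counts[zero] = rng.negative_binomial(r, p[zero])
        zero = counts == 0
    return counts.astype(int)


def simulate_registry(
    config: SimulationConfig, seed: int | None = None
) -> SimulatedRegistry:
    """Draw one registry.  ``seed`` overrides ``config.seed``.

    Each patient's exams fall inside one episode shorter than the CED
    window, so the true CED equals the sum of the patient's generated
    doses by construction.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    start, end = config.period
    period_days = (end - start).days
    window_days = (
        start + timedelta(days=1)
        - _years_before(start + timedelta(days=1), config.window_years)
    ).days

    protocols = list(config.protocol_mix)
    probs = np.array([config.protocol_mix[p] for p in protocols])
    sigmas = {p: math.log(config.dose_models[p].gsd) for p in protocols}
    mus = {p: math.log(config.dose_models[p].median_mSv) for p in protocols}

    n = config.n_patients
    sexes = np.where(rng.random(n) < config.male_fraction, "M", "F")
    ages = np.clip(
        np.rint(rng.normal(config.age_mean, config.age_sd, n)),
        config.age_min,
        config.age_max,
    ).astype(int)
    ct_counts = _draw_ct_counts(rng, n, config.recurrence)
    xray_counts = (
        rng.poisson(config.xray_rate * ct_counts)
        if config.xray_rate > 0
        else np.zeros(n, dtype=int)
    )

    records: list[ExamRecord] = []
    patients: dict[str, Patient] = {}
    truth_rows = []
    for i in range(n):
        pid = f"P{i:05d}"
        k = int(ct_counts[i])
        nx = int(xray_counts[i])
        first_off = int(rng.integers(0, period_days + 1))
        max_span = min(window_days - 1, period_days - first_off)
        if k > 1:
            gaps = rng.integers(1, 31, size=k - 1)
            if gaps.sum() > max_span:  # keep the episode inside one window
                gaps = np.maximum(
                    1, (gaps * (max_span / max(1, gaps.sum()))).astype(int)
                ) if max_span >= k - 1 else np.zeros(k - 1, dtype=int)
            offsets = np.concatenate([[0], np.cumsum(gaps)])
        else:
            offsets = np.array([0])
        span = int(offsets[-1])

        episode_start = start + timedelta(days=first_off)
        birth = _years_before(episode_start, int(ages[i])) - timedelta(days=30)
        sex = Sex(sexes[i])
        patients[pid] = Patient(patient_id=pid, sex=sex, birth_date=birth)

        chosen = rng.choice(len(protocols), size=k, p=probs)
        total_dose = 0.0
        for j in range(k):
            proto = protocols[int(chosen[j])]
            dose = float(
                rng.lognormal(mean=mus[proto], sigma=sigmas[proto])
            )
            total_dose += dose
            records.append(
                ExamRecord(
                    patient_id=pid,
                    study_date=episode_start + timedelta(days=int(offsets[j])),
                    modality=Modality.CT,
                    protocol=Protocol(proto),
                    effective_dose_mSv=dose,
                )
            )
        if nx:
            x_offsets = rng.integers(0, max(span, 1) + 1, size=nx)
            x_doses = rng.lognormal(
                mean=math.log(config.xray_dose.median_mSv),
                sigma=math.log(config.xray_dose.gsd),
                size=nx,
            )
            for off, dose in zip(x_offsets, x_doses):
                total_dose += float(dose)
                records.append(
                    ExamRecord(
                        patient_id=pid,
                        study_date=episode_start + timedelta(days=int(off)),
                        modality=Modality.RADIOGRAPH,
                        protocol=Protocol.XRAY,
                        effective_dose_mSv=float(dose),
                    )
                )
        truth_rows.append(
            {"patient_id": pid, "true_ced_mSv": total_dose, "n_ct": k, "n_xray": nx}
        )
    truth = pd.DataFrame(truth_rows)
    return SimulatedRegistry(records=records, patients=patients, truth=truth)


@dataclass(frozen=True)
class ExperimentResult:
    observed_fraction: float
    expected_fraction: float
    n_patients: int


def _analytic_exceedance(config: SimulationConfig, threshold: float) -> float:
    """Closed-form P(CED >= threshold) for supported configurations."""
    if config.xray_rate != 0:
        raise UnsupportedOracleError(
            "closed form requires xray_rate = 0 (X-ray doses are random)"
        )
    k = config.recurrence.fixed_count
    if k is None:
        raise UnsupportedOracleError(
            "closed form requires a fixed per-patient exam count"
        )
    models = [
        (w, config.dose_models[p]) for p, w in config.protocol_mix.items()
    ]
    if all(m.gsd == 1.0 for _, m in models):
        medians = {m.median_mSv for _, m in models}
        if len(medians) == 1:
            return 1.0 if k * medians.pop() >= threshold else 0.0
        if k == 1:
            return sum(
                w for w, m in models if m.median_mSv >= threshold
            )
        raise UnsupportedOracleError(
            "fixed-dose mixtures need k = 1 or a single dose value"
        )
    if k == 1:
        return float(
            sum(
                w
                * stats.lognorm.sf(
                    threshold, s=math.log(m.gsd), scale=m.median_mSv
                )
                for w, m in models
            )
        )
    raise UnsupportedOracleError(
        "log-normal dose models support the closed form only for k = 1"
    )


def simulate_shortlist_experiment(
    config: SimulationConfig,
    threshold_mSv: float,
    seed: int | None = None,
) -> ExperimentResult:
    """Simulate a registry, run the shortlisting pipeline, and return the
    observed CED-exceedance fraction next to its analytic expectation."""
    expected = _analytic_exceedance(config, threshold_mSv)
    registry = simulate_registry(config, seed=seed)
    selected = shortlist_patients(
        registry.histories(),
        threshold_mSv=threshold_mSv,
        window_years=config.window_years,
    )
    return ExperimentResult(
        observed_fraction=len(selected) / config.n_patients,
        expected_fraction=expected,
        n_patients=config.n_patients,
    )


def registry_from_exam_mix(
    mix: pd.DataFrame | None = None,
    period: tuple[date, date] = (date(2021, 1, 1), date(2021, 12, 31)),
    seed: int = 0,
) -> tuple[list[ExamRecord], dict[str, Patient]]:
    """Deterministically build a registry matching an exam-mix table.

    For each protocol row with n studies, s_M/s_F per sex and r recurrent
    studies, r patients receive two CTs (the second is recurrent by the
    first-study rule) and the rest receive one, with sexes allocated so
    the per-sex study counts match exactly.  Dates, ages and doses are
    drawn from the seeded generator; the count structure is exact by
    construction.
    """
    if mix is None:
        mix = load_table1_exam_mix()
    rng = np.random.default_rng(seed)
    start, end = period
    period_days = (end - start).days

    records: list[ExamRecord] = []
    patients: dict[str, Patient] = {}
    for row in mix.itertuples(index=False):
        protocol = Protocol(row.protocol)
        n, m_studies, f_studies = int(row.n_studies), int(row.n_male), int(row.n_female)
        r = int(row.n_recurrent)
        if m_studies + f_studies != n:
            raise ValueError(f"{protocol.value}: sex split does not sum to total")
        doubled_m = min(r, m_studies // 2)
        doubled_f = r - doubled_m
        if 2 * doubled_f > f_studies:
            raise ValueError(f"{protocol.value}: cannot place recurrent studies")
        singles_m = m_studies - 2 * doubled_m
        singles_f = f_studies - 2 * doubled_f

        plan = (
            [(Sex.M, 2)] * doubled_m
            + [(Sex.F, 2)] * doubled_f
            + [(Sex.M, 1)] * singles_m
            + [(Sex.F, 1)] * singles_f
        )
        dose_model = _DEFAULT_DOSE_MODELS.get(
            protocol.value, DoseModel(median_mSv=10.0, gsd=1.5)
        )
        for i, (sex, n_exams) in enumerate(plan):
            pid = f"{protocol.value}-{i:04d}"
            age = int(
                np.clip(
                    round(rng.normal(row.age_median, row.age_sd)),
                    row.age_min,
                    row.age_max,
                )
            )
            first_off = int(rng.integers(0, period_days - 60))
            first_date = start + timedelta(days=first_off)
            birth = _years_before(first_date, age) - timedelta(days=30)
            patients[pid] = Patient(patient_id=pid, sex=sex, birth_date=birth)
            dates = [first_date]
            if n_exams == 2:
                gap = int(rng.integers(1, 60))
                dates.append(min(first_date + timedelta(days=gap), end))
            for d in dates:
                records.append(
                    ExamRecord(
                        patient_id=pid,
                        study_date=d,
                        modality=Modality.CT,
                        protocol=protocol,
                        effective_dose_mSv=float(
                            rng.lognormal(
                                mean=math.log(dose_model.median_mSv),
                                sigma=math.log(dose_model.gsd),
                            )
                        ),
                    )
                )
    return records, patients
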