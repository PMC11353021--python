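# Methods

## Problem and model

`cedlar` analyses radiology dose-registry extracts to identify patients
whose **cumulative effective dose (CED)** from recurrent imaging —
chiefly repeated CT — reaches 100 mSv within a five-year span, and to
attach a rough **lifetime attributable risk (LAR)** of cancer incidence
and mortality to each such patient via the precomputed BEIR VII Phase 2
risk tables.

The unit of data is the irradiating event: `(patient, date, modality,
CT protocol, effective dose in mSv, optional DLP in mGy·cm)`.  Three
quantities are derived per patient:

1. **CED** — the maximum, over windows of `window_years` (default 5)
   calendar years anchored at each exam date, of the summed effective
   doses of the patient's non-nuclear-medicine exams inside the window.
   Windows are half-open `(anchor − years, anchor]`, so an exam exactly
   at a window start is excluded and adjacent windows never double-count.
   Anchoring at exam dates makes the sliding maximum exact and finite;
   ties resolve to the earliest window.  Nuclear-medicine events are
   retained in storage but never summed (internal dosimetry is a
   different quantity).

2. **Cumulative organ dose** — per-exam organ absorbed doses (mGy) from
   a coefficient table keyed by `(protocol, sex)`, summed over the
   patient's CT exams.  The table is declarative and pluggable: the
   shipped default is a per-exam table with plausible body-region
   magnitudes (in-beam abdominal organs in the tens of mGy per
   abdominal exam, sub-mGy out-of-beam); these defaults are stated
   assumptions, not measurements, and a site deploying the package
   should substitute coefficients for its own scanners (mode `per_dlp`
   supports mGy-per-mGy·cm scaling when DLP is recorded).  Effective
   dose is the tissue-weighted sum `E = Σ_T w_T·H_T`; both ICRP-103
   (default) and ICRP-60 weight sets ship, with remainder-tissue weights
   apportioned in small equal shares to the represented remainder organs
   (kidneys, brain, uterus, prostate) so the represented total stays ≤ 1.

3. **LAR** — for each of nine dose-mapped cancer sites (bladder, breast,
   colon, liver, lung, stomach, thyroid, uterus, prostate), risk =
   interpolated coefficient × scaled cumulative organ dose.
   Coefficients come from transcriptions of BEIR VII tables 12D-1
   (incidence) and 12D-2 (mortality): cases per 100,000 persons per
   0.1 Gy, gridded on age at exposure {0, 5, 10, 15, 20, 30, 40, 50,
   60, 70, 80} by sex and site.  Ages between grid points interpolate
   linearly; ages above 80 clamp to the age-80 value (the cohort reaches
   81; extrapolating past the published grid is unjustified).  One age
   per patient is used — age at the most recent exam (for patients whose
   age is known only as a printed range, its upper bound; this is the
   assignment that uniquely reproduces every published band placement).
   Thyroid mortality is not tabulated in 12D-2 and is carried as zero.
   Leukemia (red bone marrow) is outside the table pathway and out of
   scope.

### Dose-scaling conventions

BEIR VII coefficients are defined per 0.1 Gy = 100 mGy (`canonical`,
the default: risk = coefficient × dose/100).  Back-calculating the
published risk tables this package is designed to reproduce shows their
values are larger by almost exactly a factor of ten (e.g. a female colon
risk of 1.41 per 100 patients at 222.48 mGy and age ≈ 59 implies a
coefficient of ~63 per 100,000 per **10 mGy** — the BEIR VII per-0.1-Gy
magnitude shifted one decade).  The engine therefore treats the scaling
as data: the `paper_implied` convention (risk = coefficient × dose/10)
reproduces publication-style magnitudes and logs a warning naming the
discrepancy.  Because of this unresolved factor, printed LAR tables are
checked by property (interpolant boundedness, homogeneity in dose,
mortality ≤ incidence, total = Σ sites) plus the back-calculated worked
case, not cell-by-cell.

## Descriptive statistics

Stratified summaries use median, SD (n−1), IQR (25th–75th percentile,
linear interpolation between order statistics), and min–max, grouped by
sex and ten-year age band (15–20, 21–30, …, 81–90).  The median of an
even-sized sample is the mean of the two central order statistics — the
rule that uniquely reproduces the published band medians 185.75, 119.20,
180.55 and 161.40 from the underlying patient values.  The published
quartile rule is unstated, so IQR cells are treated as plausibility
checks only.  Empty strata are emitted as explicit NA rows.  A CT study
is **recurrent** when the same patient has an earlier CT within the
reporting period (every in-period CT beyond a patient's first); the
period rate is recurrent/total studies.

## Packaged fixtures

Three reference tables ship as CSV: the 22-patient shortlist (sex, age
range, CED, mean study interval, exam counts, history), the seven-protocol
exam mix of the 4406-study year (counts, sex split, age summary,
recurrent counts), and the per-(sex, band) cumulative organ doses for the
nine sites.  Values are stored verbatim, including two internal
inconsistencies of the source: one patient's exam total exceeds CT +
X-ray counts by one (an interventional procedure), and the printed
maximum CED (231.7 mSv) exceeds the value the narrative calls the highest
registered (223.0 mSv).

`expand_fixture_history` reconstructs a per-exam history from printed
totals: X-ray/interventional exams get a nominal 0.02 mSv each (general
radiology contributes < 1 % of CED in this setting), CT exams share the
remainder equally so per-exam doses sum to the printed CED exactly, and
dates spread evenly over `round(interval × (n−1))` days.  With
day-granularity calendar dates the mean gap reproduces the printed
interval at its printed 0.1-day precision (exact fractional-day
reproduction is impossible on integer dates).

## Synthetic cohort generator

`simulate_registry` emulates the structure of a one-year trauma-centre
registry:

- **Protocol mix** — categorical over the seven CT protocols, defaulting
  to the published shares (32.6 % abdomen/pelvis + contrast, 23.6 %
  polytrauma, …).
- **Per-exam effective dose** — log-normal per protocol (right-skewed,
  strictly positive; the standard dose-registry model).  Default medians
  7–25 mSv with geometric SD 1.5 are plausible for the exam types; the
  source reports no per-exam distributions, so these are assumptions.
- **Recurrence** — per-patient CT counts from a zero-truncated negative
  binomial (mean 1.15, dispersion 0.3) plus a 0.5 % high-recurrence
  subpopulation (mean 8): the overdispersion needed to produce both a
  ~5 % recurrent-study rate and a small tail of patients with ten or
  more CTs.  `fixed_count` collapses the model to a constant for
  analytic-oracle configurations.
- **Demographics** — sex Bernoulli (male fraction 0.679, the published
  study-level split); age from a clipped normal (mean 48, SD 18,
  bounded 18–90).
- **X-rays** — Poisson-attached low-dose events (median 0.02 mSv).

Each patient's exams fall in one episode shorter than the CED window, so
the true CED equals the sum of generated doses by construction and the
generator can emit exact ground truth.  All draws flow through one
seeded `numpy` generator; identical seeds give bit-identical registries.
`simulate_shortlist_experiment` pairs the simulated exceedance fraction
with a closed-form expectation, available for fixed-dose/fixed-count
configs (an indicator) and single-exam log-normal mixtures (mixture of
log-normal upper tails); other configs raise `UnsupportedOracleError`
rather than return an approximate oracle.

`registry_from_exam_mix` is the deterministic counterpart: it rebuilds a
registry matching a printed exam-mix table exactly (per-protocol totals,
sex splits, and recurrent counts, the latter realised as second CTs of
already-imaged patients), drawing only dates, ages and doses at random.

What the generator does **not** emulate: diagnosis-driven correlated
protocol sequences, inter-episode returns spanning multiple years,
facility effects, and pediatric patients.  Tests passing on synthetic
registries therefore validate the pipeline arithmetic and selection
logic, not the clinical realism of any particular dose distribution.

## Numerical choices and limitations

- Dates are ISO-8601 calendar dates; intervals are exact integer-day
  differences divided by (n−1).
- CED uses prefix sums with a bisect per anchor (O(n log n)); the test
  oracle is an independent O(n²) enumeration.
- Shortlist ordering: descending CED, patient id as tie-break.
- Unknown CT protocol strings coerce to OTHER with a warning; unknown
  modality strings are rejected outright (loud failure in a dose-safety
  context).
- CSV floats are written via `repr` and read with round-trip precision,
  so write→read is bit-exact.
- Problem sizes in the test suite (200 random histories for the
  windowing oracle, 10,000 patients × 20 seeds for exceedance coverage,
  2,000 patients for protocol-share checks) were chosen to give stable
  3-standard-error verdicts at interactive runtimes.
- The LAR pathway reports point estimates only; BEIR VII's full
  ERR/EAR machinery, DDREF and survival-table integration, and
  uncertainty intervals are out of scope, as are DICOM RDSR parsing and
  PACS connectivity.
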