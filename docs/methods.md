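# Methods

## Scope and data model

`ehrqc` operates on an OMOP-lite dialect: person, visit_occurrence,
drug_exposure, measurement, condition_occurrence, death, concept,
concept_ancestor, and a site metadata table, exchanged as CSV (RFC-4180,
ISO-8601 dates) or Parquet with identical schema; `dialect.json` documents
the schema machine-readably. Three conventions run through everything:

* **Day resolution.** All dates are calendar days; input timestamps are
  truncated. Visit-end and death timestamps are rarely both available in
  practice, so finer resolution would be spurious precision.
* **Closed intervals.** A one-day exposure has start == end and counts one
  exposure day; era length is `end − start + 1`.
* **Flag, never drop at load.** `validate_bundle` reports invariant
  violations (reversed intervals, missing demographics, duplicate deaths,
  orphan references, …) per table/rule/site but mutates nothing; each
  analysis stage applies its own documented drop rules. Missing values are
  encoded by absence (NaN/NaT), never sentinels.

## Interval merging: two deliberately different gap conventions

Both macrovisit and era construction merge sorted closed intervals, but the
default semantics differ, and the difference is substantive:

* **Macrovisits** merge when the next visit starts on or before
  `current end + merge_gap_days` (default 0): only overlapping or
  day-sharing visits are one care episode; inpatient visits on consecutive
  days remain distinct encounters.
* **Drug eras** merge when the *uncovered gap* is ≤ `gap_days` (default 0):
  exposures on consecutive days are one continuous course (no day without
  drug between them). This is what makes five consecutive single-day rows
  one 5-day era.

Both conventions conserve the union of covered days, which the test suite
checks against brute-force day-set oracles. The stock 30-day outpatient
persistence window is available (`gap_days=30`) but off by default: it
over-merges short inpatient courses.

Era cleaning order: (1) drop reversed rows (end < start) with a logged
count — they are erroneous entries, and in the multi-day documentation
paradigm they duplicate already-covered days; (2) open intervals become
single-day exposures; (3) identical (person, start, end) rows deduplicate —
this also collapses the common "bounded one-day row plus unbounded row
sharing the start date" pattern with no special-casing; (4) merge. The
construction is idempotent and order-invariant in the input rows.

## Cohort rules

Inclusion: non-missing age and sex; index date ≥ 2020-01-01 (earlier
positives are implausible) and within the study window (default 2020-03-01
to 2021-09-01); age ≥ 18 at index (index year − birth year; day of birth is
not in the dialect); a first macrovisit starting within ±14 days of the
index date (the index-to-admission window is not externally specified; it
is configurable and recorded in the run log); stay ≥ 2 days. Every rule
outcome is a boolean column, and the attrition table applies the rules
sequentially, so cohort size is monotone non-increasing down the table.

## Site screening

Rules (a)/(b) use the *population* SD over all profiled sites, computed
once before any exclusion; iterative re-screening is not performed. When
all sites are identical the SD is zero and no site is excluded. "Temporal
variance" is operationalized as the variance across pandemic months
(calendar month of macrovisit start) of a site's monthly missing fraction,
averaged over variables — the screen is pooled over variables rather than
per-variable, a documented choice where the procedure is genuinely open.
Clustering uses Euclidean distance and average linkage on completeness
vectors (configurable); cutting at k = 2, the retained cluster is the one
with the higher mean completeness. Cluster membership is written as an
artifact but is not an exclusion rule by default: with near-homogeneous
sites a forced two-way cut is arbitrary. The completeness matrix and the
patient-level missingness table are exact complements when both use the
whole-visit window (%missing = 100 − completeness), which is tested.

## Continuity

Months of history use a 30.4375-day month (average Gregorian month;
configurable). A patient with a prior visit but < 1 month of history falls
in the 1–23-month group with months = 0 — presence of *any* prior record is
the qualitatively different state. "Earliest recorded visit" uses
strictly-before semantics relative to the macrovisit start, and visits
before the lookback floor (default 2018-01-01) are invisible, so history is
right-capped at 24 months by construction. Comorbidity indicators are
any-code-before-admission; no washout or visit-density requirement is
applied. The binary SMD uses the pooled-variance formula; degenerate
zero-variance comparisons return 0. Kruskal–Wallis and chi-square p-values
come from scipy; cells below a configurable threshold (default 20) are
suppressed in rendered tables.

## Outcomes

The ±1-day in-hospital mortality tolerance is symmetric and configurable;
day-resolution recording makes one-day skew in either direction expected.
The 28-day horizon is anchored at the macrovisit start (the anchor is not
externally specified; it is a documented, configurable choice). Deaths with
any subsequent visit are classified as data errors (billing artifacts) and
excluded from the offset histogram. Acute-event calls work on days-with-code
within the stay: codes on every day → carried-forward history; first code
before treatment start → pre-treatment exclusion; otherwise any code on/after
treatment start → acute event. Lab-confirmation enrichment (e.g. troponin
for MI) is a hook left to concept-set configuration, off by default.
Survival modeling, competing-risk analysis and external mortality linkage
are out of scope; the module emits the cleaned columns such analyses would
consume.

## Synthetic generator

The generator's defaults are the study conditions the pipeline is meant to
face, not dials to tune per test:

* per-variable capture probabilities default to the observed non-missing
  fractions in a hospitalized-COVID population (e.g. temperature 0.876,
  creatinine 0.428, IL-6 0.0005), with per-site overrides and per-month
  multipliers for temporal missingness;
* value models are quartile-matched log-normals (or normals for vitals)
  around typical medians, e.g. creatinine median 0.94 (IQR 0.73–1.40);
* history groups none / 1–23 mo / 24+ mo with weights 0.288 / 0.225 /
  0.487; comorbidity, prior-medication, ventilation and mortality
  prevalences are conditional on history group with the characteristic
  discontinuity gradient (e.g. hypertension 0.45 → 0.59 → 0.74);
* treatment courses are 5 days (80 %) or 10 days (20 %), initiated within
  2 days of admission, documented under per-day-duplicated or multi-day
  paradigms with configurable reversed/open-row probabilities;
* a fraction (default 0.55) of courses is truncated to a single documented
  day labelled "Inferred from claim". The expected number of truncations is
  allocated so one designated site carries a target share (default 73 %) up
  to its capacity — with equal-size sites the designated site may hold fewer
  treated patients than the target share implies, in which case the surplus
  spreads over the other sites and the overall fraction is preserved
  exactly;
* death dates are offset from the visit end by a planted distribution
  concentrated at 0 with a heavier late tail, and a small fraction of
  deaths gains a post-death "billing artifact" visit;
* discharge disposition is populated only at OMOP-CDM sites, emulating
  source models that lack the field.

Everything derives from `SimConfig.seed` via per-site `SeedSequence`
spawns, so a config fully determines the bundle (tested byte-for-byte).

What the generator does *not* emulate: clinically coherent disease
trajectories, realistic coded vocabularies beyond a toy concept table,
free-text data, cross-site patient linkage, or informative (MNAR)
missingness mechanisms tied to severity. Passing parameter-recovery tests
therefore demonstrates that the pipeline recovers what was planted under
known mechanisms — not that it would be unbiased under real-world
informative missingness. One deliberate artificiality: patients with no
prior visits still carry comorbidity codes dated before admission, so that
planted prevalences in the no-history group are recoverable by the
baseline-covariate stage; in real data those comorbidities would be
invisible, which is precisely the discontinuity bias the continuity module
measures.

## Problem sizes and numerical choices

The test suite exercises oracle equivalences on 1000 random dirty
exposure-row sets and 500 random visit sets, and parameter recovery on 2
sites × 2000 patients (completeness within ±2 %, history-group proportions
within ±2 %, single-day-claim fraction within ±3 %) plus a 20-site × 250
design with 3 pathological sites recovered exactly. These sizes make the
binomial standard errors comfortably smaller than the stated tolerances
while keeping the default suite under a minute of simulation time. CSV
artifacts are written with fixed sorting and `%.6g` float formatting so
reruns are byte-identical. Ties in clustering and merging are broken by
stable sorts on (person, start, end, id).

## Known limitations

* The macrovisit heuristic is a documented simplification (merge
  overlapping/abutting inpatient+ED intervals); production macrovisit
  algorithms use richer visit metadata.
* COVID phenotype derivation is out of scope: index dates are an input.
* The concept vocabulary is a toy; real RxNorm/SNOMED hierarchies are much
  deeper, but era construction only needs the descendant closure.
* Imputation/weighting for residual missingness, EHR-continuity prediction
  models, and privacy-preserving record linkage are explicitly not
  implemented; the pipeline produces the cleaned inputs those methods need.
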