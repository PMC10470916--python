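# Methods

## The quality measures

**Field validation.** A certificate field is `missing` when empty or
whitespace-only, `unexpected` when present but invalid, `valid` otherwise.
Categorical topics (place of occurrence, certifier, sex, marital status)
validate against editable allowed-code sets shipped as
`src/vitalqc/data/field_dictionary.json`, mirroring SIM/MIS codification
conventions (the "ignored" codes, e.g. sex = 0, belong to the predefined
list and therefore count as valid). Date topics validate layout
(`DDMMYYYY`) plus full calendar validity including leap years, for any
year — no cross-field ordering checks (fields are validated
independently). A certificate is fully correct iff all seven topics are
valid; municipal quality is

```
pct_correct = 100 × (# fully correct certificates) / (# certificates)
```

and the label is **poor** iff `pct_correct < threshold` with threshold
80% by default — exactly 80% is good. The threshold sits at the national
median of the emulated system, which is what makes the dichotomy
informative.

**Garbage coding.** ICD-10 codes are canonicalized (trim, uppercase, drop
dot; must match letter + 2 digits + optional digit/letter) and classified
against an ordered interval list; a 3-character interval contains any code
sharing a stem in range, a 4-character interval contains 4-character codes
literally in range, and the first matching entry wins. The shipped default
list (`src/vitalqc/data/garbage_codes.json`) is a small documented subset
covering the canonical examples of the four garbage types plus ICD-10
Chapter XVIII; production analyses should supply a complete list as JSON
with the same structure. The municipal garbage percentage uses records
with a *classifiable* cause as denominator; empty or malformed causes are
counted separately (`n_unclassifiable`) so the cause-quality measure stays
orthogonal to the field-quality measure. Garbage subtypes (1–4) are
carried in verdicts but all aggregation uses the binary verdict only.

**Correlation.** Spearman's ρ is computed as Pearson correlation of
mid-ranks (average ranks on ties). Stratification uses quartiles of the
socioeconomic index with cut points at p25/p50/p75 and the rule
`≤ p25 → Q1`, `(p25, p50] → Q2`, `(p50, p75] → Q3`, else `Q4`; a stratum
with fewer than three members or constant values reports NaN. No p-values
or confidence intervals are produced anywhere: the municipalities are the
whole population under study, not a sample.

## Predictive modelling

Eleven features: population, education, poverty, wealth, income,
deprivation (socioeconomic dimensions, with education and deprivation
oriented so higher = better conditions; readers ingesting raw
GeoSES-oriented files can set `raw_geoses_orientation` to apply the ×−1
flip), physicians and hospital beds per 1,000, % facilities serving the
universal health system, % facilities with emergency departments, and the
2010-style death rate per 1,000. The composite index is reserved for
stratification and is not a feature.

**Splitting.** Municipalities are packed whole-region into
train/validation/test at target fractions 0.70/0.15/0.15 by seeded
randomized greedy packing (largest region first into the most deficient
set; equal-size regions in seeded-shuffle order). With ≥ 30 regions the
achieved fractions land within ~5 points of target. The 5-fold CV folds
use the same packing. The validation set exists for interim monitoring;
reported numbers come from the test set.

**Grid search.** Families: logistic regression, SGD linear classifier and
SVM inside a standardization pipeline; decision tree, random forest and
gradient boosting on raw inputs. Grids are small and documented in
`default_model_space()` (regularization on a log grid, tree depth
{5, 10, None}, forest size {300, 1000} × depth {10, None}, boosting
{100, 300} trees) and fully overridable. Scoring is mean out-of-fold ROC
AUC; ties break to the earlier grid point; the winner is refit on the
whole training set. Standardization statistics are always estimated inside
the pipeline, i.e. on the fitting portion only. Learner internals come
from scikit-learn; splitting, CV orchestration, selection and all metrics
are implemented and tested in this package.

**Metrics.** ROC AUC uses the rank (Mann–Whitney) formulation — the
probability that a random positive outranks a random negative, half
credit for ties — with curves by threshold sweep; PR AUC is average
precision (step-wise integral of precision over recall increments).
Confusion rates at a fixed threshold (default 0.5; probability exactly at
the threshold predicts positive) are reported class-conditionally.

**Attribution.** Feature contributions are interventional Shapley values
estimated by seeded permutation sampling against a background sample
(training set, seeded subsample of ≤ 100 rows by default): features enter
in random order and each is credited with the change in mean predicted
probability when switched from background to instance values. Because
each permutation telescopes from the background mean to the instance
prediction, additivity (`base + Σ attributions = predicted probability`)
holds exactly for any number of permutations; more permutations only
stabilize the split of credit among correlated features (default 8). A
feature's direction summary is the sign of the rank correlation between
its values and its attributions.

**Residuals.** `observed label − predicted probability ∈ [−1, 1]`.
With the default symmetric cutoff 0.5, residual ≥ 0.5 flags
`worse_than_expected` (observed poor despite a context predicting good)
and ≤ −0.5 `better_than_expected`. Both counts are reported; the cutoff
is a reporting choice, exposed in configuration.

## The synthetic universe

Defaults describe the emulated national system: 5,570 municipalities in
450 health regions, certificates pooled over 2010–2017 (2010-style
covariates; any quality drift across years is deliberately unmodelled).
A standard-normal *disadvantage* factor per municipality — half of its
variance shared within the health region — drives all socioeconomic
dimensions (poverty, deprivation, education, income, wealth load on it
with noise; pairwise rank correlations ≥ 0.5), the composite index
(`tanh` of its negative), and weaker loadings on population, physicians,
beds, % SUS facilities and death rate. Marginals are skewed census-like:
lognormal population (median 11,000), lognormal-type income/wealth/
physician rates, ~30% of municipalities with zero hospital beds, % SUS
clipped with mass at 100.

The hidden flaw propensity is logistic in the standardized features,
`q = σ(Σ c_f z_f + ε)`, with signs: positive (quality-worsening) for
poverty, deprivation, population, % SUS; negative for education, income,
wealth, physicians, beds, death rate. Coefficient magnitudes are scaled so
the linear predictor's signal has sd ≈ 0.4 against noise sd 0.5: this
keeps the logistic in its informative range even when the signal is
deliberately amplified (the `signal_scale` knob used in recovery tests),
and yields default-condition discrimination (test ROC AUC ≈ 0.71–0.77
under the shipped model space) in the realistic "acceptable" band rather
than a trivially separable world.

Record counts are Poisson around
`population × death_rate/1000 × n_years` (re-drawn until ≥ 1, so
percentage denominators are positive; median ≈ 300 certificates per
municipality). Each topic is flawed independently with probability
`2 × base_rate × q`, split evenly between missing and an unexpected token
(configurable in principle via the generator's pools); per-topic base
rates (certifier 9.2%, marital status 8.3%, date of registration 1%,
others ≤ 0.4%) concentrate the flaw mass where real systems show it and
put the median municipality near the 80% threshold (~40–46% poor).
Generated valid dates use days 1–28 so validity never depends on the
month; the validator itself handles the full calendar. Unexpected dates
are calendar-invalid `3213YYYY` strings (day 32, month 13).

Garbage causes are drawn with municipal probability
`0.25 × (1 + m_Q (q − 0.5)) + ε`, clipped to [0.01, 0.95], where the
multiplier `m_Q = (4.5, 1.4, 0.8, 0.1)` for socioeconomic quartiles
Q1→Q4 and ε is N(0, 0.05²) municipal noise. The strongly graded
multipliers are what make the stratified flaw–garbage correlation decay
monotonically from Q1 to Q4: with a logistic latent, milder gradients are
masked in the lowest quartile, where sigmoid saturation compresses the
rank information in both measures. The base rate 0.25 is a realistic
garbage share for a middle-income system of the emulated era. About 0.5%
of causes are missing, exercising the classifiable-cause denominator.

**What the generator does not emulate** — and hence what passing tests do
not certify about real data: decedent-level covariates (age, sex and
circumstance effects on certification), temporal drift, geographic
adjacency beyond abstract regions, real municipality codes, realistic
ICD-10 cause-of-death profiles (causes are drawn from small fixed pools),
and correlated multi-topic failure modes (topics fail independently given
the latent). Recovery results on synthetic data demonstrate that the
pipeline's machinery is correct, not that any particular real-world
association holds.

## Numerical and design notes

* Determinism: one `numpy` Generator seeded from the config seed per
  generation stage; identical config + seed ⇒ byte-identical output.
  The pipeline re-run with the same inputs and seed reproduces its model
  report bit-for-bit.
* Problem sizes in the shipped tests: the generative-recovery study uses
  2,000 municipalities in 160 regions (~1.2 M certificates) with the
  quality signal tripled and a compact two-family grid — sizes chosen to
  make recovery assertions sharp while keeping the suite quick to run.
* The flaw-probability link `min(1, 2 × base × q)` is linear in the
  latent over the realized range; clipping only binds under extreme
  configurations.
* Degenerate inputs fail loudly rather than defaulting: empty record sets
  (undefined summaries), single-class metric inputs, strata under three
  members (NaN with the stratum reported), constant sequences in rank
  correlation, municipalities absent from the municipality table.
* `quartile_assign` on heavily tied indices can collapse strata; it warns
  and preserves the partition property.
* The 80%-threshold semantics (exactly 80 ⇒ good) follow the operational
  definition attached to the quality classification; whether date fields
  outside the study window should count as unexpected is an open
  modelling question — the default accepts any calendar-valid date.
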