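# Methods

This note documents the statistical machinery the package implements, the
assumptions of the synthetic-data generator, and the numerical conventions
and design choices made where the underlying methodology leaves them open.

## Two-phase design and weighted estimation

The target design screens a population of pregnant women with a binary
two-item screen at the booking appointment, then administers the
gold-standard diagnostic interview to all screen-positives and a random
1-in-k sample of screen-negatives (k switchable mid-study, e.g. 1:4 then
1:6). The 1-in-k selection is implemented as independent Bernoulli(1/k)
draws per enrolment position rather than systematic every-kth selection:
both are "random selection", and the Bernoulli form is exchangeable and
simplest to reason about.

Design weights use **realized interviewed counts**, `w_h = N_h / n_h`, not
the nominal 1/k inclusion probabilities. Consent non-response is thereby
absorbed into the weight. This reproduces exactly the weights a study
publishes from its flow chart (e.g. 906/287 and 9057/258), and it makes the
Horvitz–Thompson identity `n_h · w_h = N_h` exact. The cost is a subtle
one: conditional on a *fixed* population, the estimator targets the
consenting subpopulation; unbiasedness for the full population requires
consent to be non-informative (MCAR), which holds for the generator by
construction and is the standard assumption when non-response is folded
into design weights.

All accuracy measures come from the weighted 2×2 table (cells are sums of
weights). Bayes consistency — PPV = Se·π/(Se·π + (1−Sp)(1−π)) with π the
weighted prevalence — holds on the weighted table as an algebraic identity
and is asserted in tests to 1e-12. Empty *disease* margins raise a typed
error (Se/Sp undefined, and silent NaNs propagate); an empty *test* margin
only leaves the corresponding predictive value NaN, so a cut-point table
can still report the degenerate rows Se = 1/Sp = 0 and Se = 0/Sp = 1 at
extreme cut-offs. Records on which a test rule is unevaluable (missing help
answer, missing score) are excluded from that rule's table and counted.

Confidence intervals are percentile bootstrap (default B = 1000),
resampling records with replacement **within each screening stratum** with
stratum sizes fixed at the observed counts and each record's weight riding
along. The percentile interval was chosen as the simplest defensible
resampling interval for weighted ratio estimators; no continuity
corrections or exact intervals are attempted. Replicates on which the
estimator is undefined are tolerated up to 1%, then the bootstrap aborts
with the failure count.

Report rounding is half-away-from-zero, 2 dp for proportions and 1 dp for
likelihood ratios, matching the usual printed precision of such studies.
A note on one published table this package's arithmetic illuminates: the
weighted cells 410/597/496/8460 for the either-positive screen against
depression give Sp = 0.9447 and LR+ = 7.4; values of 0.95 and 8.2 sometimes
quoted alongside them are not consistent with those cells (they likely fold
in unpublished nonresponse weighting), and the package always reports the
weight-consistent values.

## Score threshold convention

A "cut-off 12/13" on the 0–30 score means negative ≤ 12, positive ≥ 13;
`TestDefinition.parse("epds:13")` therefore tests `total ≥ 13`. Cut-point
tables flag an "optimal" row by Youden's J = Se + Sp − 1 (the most common
transparent criterion) but always return the full table so any alternative
criterion can be applied.

## Covariate-adjusted ROC regression

The ROC model is the parametric distribution-free binormal ROC-GLM

    ROC_Z(t) = Φ(α₀ + α₁ Φ⁻¹(t) + β′Z),

in which covariates shift the case distribution (and hence the ROC) while
the control score distribution is left unadjusted. Estimation follows
Pepe's placement-value approach: each case's placement value is the
design-weighted proportion of controls scoring at or above her; binary
indicators U_it = 1[PV_i ≤ t] over a grid of false-positive rates t are
regressed on {Φ⁻¹(t), Z} with a probit link and case design weights. Each
case contributes one row per grid point, so the parameter covariance is a
sandwich clustered on case; covariate groups (e.g. a 5-level ethnicity
factor) are tested with a Wald χ² on their coefficient block.

Numerical conventions:

- **Ties.** The ordinal 0–30 score guarantees score ties; case–control
  ties get half weight (mid-rank). This makes the trapezoid AUC of the
  weighted empirical ROC *exactly* equal to the weighted pairwise
  concordance probability, an identity the tests verify by exhaustive
  enumeration, and it keeps the placement values of controls against their
  own distribution mean-0.5 exactly.
- **Grid.** Default t-grid 0.01…0.99 step 0.01; coarser grids are
  statistically valid (the estimator is consistent for any fixed grid) and
  are used in simulation-heavy tests for speed.
- **Diagnostics.** A rank-deficient design matrix raises an error naming
  the columns; a fitted α₁ ≤ 0 (a downward-sloping ROC, impossible under
  the model) sets a warning flag rather than failing, since it can occur by
  chance in tiny samples.
- Covariate-specific AUC = Φ((α₀ + β′Z)/√(1 + α₁²)) is computed from the
  fitted parameters; at the reference covariate level on model-generated
  data it agrees with the empirical weighted AUC within sampling error.

Under the generator below with controls N(0,1) and cases
N(μ₁ + shift, σ₁), the truth is α₀ = μ₁/σ₁, α₁ = 1/σ₁ and β = shift/σ₁;
`config_from_roc_params` inverts this map so recovery tests can dial in
(α₀, α₁, β) directly. Parameter recovery is tested on the *latent*
(continuous) score: discretisation to 0–30 introduces ties that lower the
AUC slightly and would conflate discretisation bias with estimator bias.

## Missing data

Two mechanisms are handled separately, mirroring how such studies treat
them:

**Item-level missingness** (questionnaire items): a *single* round of
predictive mean matching. For each item, an OLS of the item on the mean of
the record's other observed items plus age (predictors that are defined for
every non-excluded record regardless of its missingness pattern) is fitted
on the records observed for that item; each missing cell receives the value
of one of the k = 5 donors nearest in predicted mean, drawn uniformly
(ties broken by record order, then the seed). Imputed values therefore
always belong to the item's observed value set, and observed cells are
never altered. Records with more than 30% of items missing are excluded
from score-based analyses, never imputed. Single imputation is deliberate —
one round, no chained equations, no multiple-imputation pooling.

**Module-level missingness** (whole gold-standard modules declined): a
logistic response model of the module-observed indicator on the
(post-imputation) questionnaire total score, ethnicity and employment — the
covariates that drive missingness in the generator and in the motivating
study. The analysis weight is `design_weight / fitted response
probability`; probabilities below a floor of 0.02 are clipped (weight
capped) and counted, a standard IPW variance guard. Module-missing records
drop out of that module's analyses. Perfect separation raises an error
suggesting category collapsing. When missingness is absent the combined
weight reduces exactly to the design weight, and under MCAR module
missingness IPW and complete-case estimates agree within Monte-Carlo
tolerance — both are tested.

A structural point the tests exploit: in the generator, screen status and
the score are conditionally independent given diagnosis, so score-driven
module missingness leaves the *screen's* complete-case sensitivity
unbiased; it is the *score-threshold* test whose complete-case sensitivity
is biased and whose IPW correction is measurable. The bias-reduction
property is therefore exercised with the score-threshold rule under a
deliberately strong MAR scenario (response intercept 2.5, total-score
coefficient −0.15, ~77% module completion), chosen so the missingness bias
dominates sampling noise and the comparison is informative.

## Synthetic-cohort generator

The generator is first-class, tested code; its defaults reproduce the
structure of the motivating study population:

| parameter | default | rationale |
|---|---|---|
| n_screen | 10,000 | screened population size |
| depression / anxiety / any-disorder prevalence | 0.11 / 0.15 / 0.27 | study-scale prevalences |
| screen sens / spec (vs depression) | 0.41 / 0.95 | observed operating characteristics; give ~9% screen-positive |
| latent case mean μ₁, SD σ₁ | 1.735, 1.0 | binormal AUC ≈ 0.89 for the score |
| consent rate | 0.35 | realized participation scale |
| age effect on case latent mean | −0.35/decade | score less discriminating with age |
| interpreter effect | +0.5 | face-to-face administration aids disclosure |
| item missingness | MCAR, p = 0.005 | small item-level losses |
| module response model | logistic(4.5 − 0.06·total + ethnicity + employment) | ~96% completion, MAR via the IPW predictors |

Mechanics: diagnoses are independent Bernoulli components plus a residual
"other disorder" component solved so the union matches the configured
any-disorder prevalence (components below the union raise a configuration
error). Screen answers are drawn with the configured sensitivity against
the reference diagnosis; a positive screen is split across
(both questions / q1 only / q2 only) with configurable pattern
probabilities, and the stratum equals "positive" iff either answer is yes.
The help question exists only for screen-positives, with separate
endorsement probabilities for cases and non-cases (defaults 0.18 / 0.02,
making the either-plus-help rule far less sensitive, as observed in
practice). The ordinal score is a fixed monotone discretisation of the
latent value, `clip(round(7 + 4·latent), 0, 30)`: the control median is 7
and the oversampled high-scoring stratum pulls the observed IQR toward the
4–13 range seen in real data. The total is spread across the 10 items
(each 0–3) by a base level plus a randomly allocated remainder.

All draws come from one seeded NumPy `Generator` in a fixed column order;
identical (config, seed) gives byte-identical cohorts across platforms.
(Column-ordered vectorised draws give the same determinism guarantee as
record-by-record drawing at a fraction of the cost.)

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: dependence among disorders beyond the
any-disorder union, item-level psychometric structure (all items share one
latent), informative consent, covariate-dependent screen error rates, and
any drift of the screen's meaning between administration and interview.
Covariate distributions (uniform age 16–45, configurable multinomials) are
conventions, not estimates of any population.

## Design and power planning

`expected_yield` is closed-form: with screen positivity
P(+) = πSe + (1−π)(1−Sp) and Bayes-inverted stratum case rates, the
expected diseased interviewees are `n₊·P(D|+) + n₋·P(D|−)`. Phase-two
interview counts can be given directly as planned targets (protocols fix
round numbers like 400 + 200 and quote the implied fractions only
approximately — the published "185 expected cases" follows from the planned
counts, while the rounded fractions 0.54/0.06 would give 184); otherwise
they derive from the sampling fractions. Both the unrounded and rounded
values are reported.

`simulate_ci_width` draws whole replicate studies hierarchically (binomial
frame composition, binomial selection, hypergeometric disease counts among
interviewees, binomial index-test outcomes — distributionally identical to
per-woman simulation and much faster), computes weighted Se/Sp and their
stratified-bootstrap percentile CIs, and reports mean widths with
Monte-Carlo standard errors. Replicates with degenerate yields are dropped
and counted; more than 5% dropped is an error.

`simulate_power` implements the "conservative, cases-only" comparison: the
index test is drawn on the expected case count at its assumed sensitivity
and tested against the comparator value with an exact two-sided binomial
test (rejection region precomputed once per configuration). The exact test
is slightly conservative by discreteness (size 0.045 at n = 185 against
0.65). A two-sample independent-proportions variant is provided; it is
weaker, as the comparator's sampling uncertainty costs power. All simulated
quantities carry Monte-Carlo standard errors and are reproducible given the
seed.

## Problem sizes used in the test suite

Simulation-heavy checks run at sizes chosen to make their Monte-Carlo
bands meaningful while keeping the default suite quick: screen calibration
at n = 50,000; design-unbiasedness over 200 replicate two-phase studies of
8,000 women; ROC-GLM recovery over 100 replicates at ~1,000 cases /
1,000 controls (grid step 0.02); Wald-test calibration over 400 null
simulations (~525 cases each, grid step 0.05); IPW bias reduction over 200
replicates of 5,000 women; bootstrap coverage over 300 replicate studies.
The whole suite runs in about two minutes on one CPU.

## Known limitations

- The percentile bootstrap under-covers slightly in small strata; the
  coverage test asserts a deliberately loose 90–99% band.
- IPW assumes the response model is correctly specified (MAR given total
  score, ethnicity, employment); no doubly robust estimator is provided.
- ROC comparison between correlated markers (DeLong), partial AUC, and
  Neyman-optimal two-phase allocation are out of scope.
- The ROC-GLM sandwich treats the control empirical distribution as fixed
  when computing placement values; a clustered bootstrap switch exists for
  when that approximation is doubtful, but is off by default.
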