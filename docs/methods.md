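# Methods

This note records the scientific and numerical choices behind the package:
what is modelled, what the defaults mean, and what the tests do and do not
establish.

## The measurement model

In the Who-Said-What paradigm, categorization strength for a binary cue is
read out of memory errors. Correct recalls are ignored: a correct match can
come from memory, category inference, or luck, so it carries no information
about grouping. For each participant and cue *c*, every error is
*within-category* (chosen face shares *c* with the true speaker) or
*between-category* (it does not); binary cues partition the alternatives,
so `within + between = n_errors` holds exactly for every cue. The
proportional categorization score is

    score_c = (within_c − between_c) / n_errors  ∈ [−1, 1].

Scores for different cues are computed on the same error pool and are *not*
mutually exclusive. The score is undefined when `n_errors = 0`; such
participants are flagged and excluded from every participant-level
aggregate and model fit (never imputed 0), which naturally yields analysis
n below recruitment n. No base-rate correction is applied; instead the
analytic chance level is reported alongside.

### Exact chance levels (balanced factorial of k binary cues)

- Overlap: every face has exactly one all-differing complement among the
  `2^k − 1` alternatives, so two distinct faces share ≥ 1 cue with
  probability `1 − 1/(2^k − 1)` — 6/7 ≈ 85.7% for k = 3. The closed form
  is verified against exhaustive pair enumeration at construction.
- Score: under uniform error choice a cue has `s = 2^(k−1) − 1` same-level
  and `d = 2^(k−1)` different-level alternatives, so
  `E[score_c] = (s − d)/(2^k − 1)` = −1/7 for k = 3. Both are exact
  rationals (`fractions.Fraction`) in the API.

Chance-level tests: participant-level overlap proportions get a one-sample
t against the baseline plus Cohen's d; pooled trial-level counts get an
exact binomial test, one-sided ("greater") by default because the question
is elevation above chance (two-sided available by flag). If every
participant's overlap proportion is identical (ceiling), the t is reported
as NaN rather than failing the whole analysis.

## Cue-interdependence regression

The scar score is regressed by OLS on the race score, sex score, and their
product, on **uncentered** scores. Uncentered fitting is deliberate: the
moderator probe values the field reports (mean ± 1 SD of the raw sex
score) and the conditional slopes `b1 + b3·v` are then directly
interpretable on the raw score scale, and the slope at the moderator mean
equals the value implied by the uncentered coefficients.

Simple-slope standard errors use the delta method on the coefficient
covariance, `SE(v)² = Var(b1) + v²·Var(b3) + 2v·Cov(b1, b3)`, with t on
the residual df. Two algebraic identities follow and are tested to machine
precision: `slope(v) = b1 + b3·v` exactly, and every slope contrast
`b3(v_b − v_a)` has |t| equal to the interaction's t. Nested models are
compared with `ΔF = ((R²_f − R²_r)/q) / ((1 − R²_f)/df_resid_f)`;
comparing a model with itself returns ΔF = 0, p = 1. Covariates join on
`participant_id`, categorical covariates are dummy-coded against the modal
category, and incomplete rows are deleted listwise with logged counts.
P-values are two-sided throughout.

The OLS core is a small shared normal-equations kernel with a
condition-number rank check (cond > 1e12 on the scaled cross-product
raises a fit error). It is deliberately the *same* kernel for the primary
fit and every null replicate, so observed and null statistics cannot drift
apart; an independent `(XᵀX)⁻¹Xᵀy` brute force and statsmodels serve as
cross-check oracles in the test suite only.

## Constrained resampling null

Because all cue scores divide the same finite error pool, they are
mechanically interdependent — e.g. a run of same-sex errors necessarily
depresses the other cues' scores. To ask whether regression structure
exceeds this artifact, the null simulation holds each participant's
correct trials and error positions fixed and redraws only each error's
chosen face, uniformly over the `2^k − 1` alternatives — preserving every
zero-sum constraint while destroying cue-based encoding. Scores and the
regression are recomputed per replicate through the same kernels as the
primary analysis (5000 replicates by default; replicate r uses the
counter-derived stream `[seed, r]`, so results are independent of
execution order).

Conventions, stated in the output metadata:

- tail probabilities are add-one corrected, `p = (1 + #extreme)/(1 + R)`,
  never zero; "extreme" is `|x| ≥ |obs|` for coefficients (magnitude mode,
  default; signed mode by flag) and `x ≥ obs` for R²;
- quantiles are order statistics with linear interpolation (type-7);
- replicates with a failed fit are excluded and counted; more than 1% of
  them (configurable) aborts the run.

Two testable signatures of the artifact: replicate score vectors show
negative cross-cue correlation even under pure uniform guessing, and the
null R² distribution shifts upward as error pools shrink (fewer errors →
noisier scores → more apparent structure).

## Synthetic cohort generator

The generator is a stand-in for real WSW data with known ground truth.
Participant i has accuracy `a_i` (probability a trial is answered
correctly) and latent weights `w_i` (one per cue, log-odds units); on an
error the chosen face follows the cue-match softmax
`P(f) ∝ exp(Σ_c w_ic · match_c(f, true))`. This is the minimal
exponential-family choice model that nests uniform guessing (w = 0) and
produces graded within-category confusion; a weight of ln 2 doubles the
relative odds of same-category alternatives, and w → ∞ confines errors to
the same category.

Defaults (overridable via `GeneratorConfig` / YAML):

- 500 participants × 24 trials over the 8-face design (3 statements per
  face, pairing randomized by seed);
- accuracy ~ Beta(6, 4): mean 0.6, i.e. ≈ 10 errors of 24 — a realistic
  online-sample error rate for this task;
- weight means (1.0, 0.15, −0.15) for (sex, race, scar) with unit
  variances and zero covariances: strong sex encoding, weak race encoding,
  weak contrastive scar encoding. These defaults qualitatively mirror the
  cue hierarchy the paradigm typically finds (sex ≫ race > scar), not any
  particular dataset's values;
- accuracy and weights independent across participants; correlation is
  available only through the config because no joint model is assumed.

Reproducibility: latents are drawn from stream `[seed, 0]`; participant
p's recall from `[seed, 1, p]`, so any participant can be regenerated
independently.

Known gaps between generator and real data — and hence what passing tests
show: the generator has no encoding-phase attention structure, no
statement semantics or sentiment, no face idiosyncrasies (one face per
design cell, as in the paradigm), no accuracy–weight correlation, and
error probability is constant across a participant's trials. Tests
against it therefore validate the *pipeline* (scoring, inference, null
calibration, parameter recovery), not any empirical claim about human
categorization.

### Calibration facts used by the tests

- With w = 0, mean cue scores converge to −1/7 and participant-mean
  overlap to 6/7 (tested as means over 12 independent 500-participant
  cohorts, which puts the Monte-Carlo SE near 0.004 — a single cohort's
  SE of ≈ 0.015 would confound the check).
- With w_sex = 10, errors are confined to the 3 same-sex alternatives, of
  which exactly one shares race and one shares scar, so race and scar
  means converge to −1/3 — the conditional-choice trade-off in its purest
  form.
- Rank recovery: with accuracy ~ Beta(5, 5) and weights ~ N(0, I), the
  population Spearman correlation between a participant's planted `w_c`
  and observed `score_c` is ≈ 0.80 per cue. The recovery test uses one
  8000-participant cohort so that the estimate's sampling error (≈ 0.004)
  is small relative to the quantity; with ≈ 12 errors per participant the
  score is a noisy readout, which is what bounds recovery, not cohort
  size.
- Null calibration: under w = 0 the observed cohort is exchangeable with
  its own null replicates, so observed R² falls inside the null's central
  95% in ≈ 95% of cohorts (tested over 100 cohorts × 500 replicates).
  The "structured" scenario — strong heterogeneous sex weights with
  moderate race weights, means (2.0, 0.5, 0.0) — puts observed R² far
  beyond the null's 99.9% quantile, because between-participant weight
  heterogeneity couples the cue scores in a way uniform resampling cannot.

Problem sizes throughout the suite (cohorts of 200–8000 participants,
nulls of 150–5000 replicates) were chosen so each check's Monte-Carlo
error is small against the effect it measures.

## Design choices where the design was open

- Face ids are 0-based integers in binary-counting order over the cue
  order (first cue = most significant bit): deterministic,
  file-layout-independent keys. Level→code mappings are explicit in the
  `Cue` definition and the faces CSV.
- The statement–face pairing is randomized per cohort by seed; no canonical
  pairing is assumed.
- `feature_overlap_probability` refuses the closed form on non-factorial
  sets and falls back to enumeration only; unbalanced face tables are
  rejected at the I/O boundary with an explicit message.
- The null simulation resamples only error-trial *choices*; which trials
  were errors is treated as fixed design, matching the zero-sum-constraint
  logic of the resampling scheme.
- Cohen's d is reported signed (d = (m − μ0)/s), including for negative
  score means.

## Limitations

- Participant-level scores discard trial-level cue-competition structure;
  a conditional-logit trial model is out of scope here.
- The regression assumes homoskedastic errors; participants with very few
  errors have noisier scores, which the null simulation captures but the
  primary OLS does not reweight.
- Exact rational baselines and the closed-form overlap require the
  balanced full factorial; only pair enumeration is offered otherwise.
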