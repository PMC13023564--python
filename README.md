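# wsw-categorization

Analysis tools for the **Who-Said-What (WSW) memory-confusion paradigm**, a
standard method in social cognition for measuring *spontaneous* social
categorization. Participants study a small set of faces — here a balanced
2×2×2 factorial varying **sex**, **race**, and **facial anomaly (scar)** —
each paired with short first-person statements, then face a surprise recall
task: which face said each statement? Recall *errors* carry the signal: if
someone misattributes a statement to a face sharing the true speaker's sex,
sex apparently organized their memory.

The package is aimed at researchers running or reanalyzing WSW studies, and
provides:

- **Design baselines** (`wsw.design`): the factorial face set with exact
  combinatorial chance levels. For k fully crossed binary cues, two distinct
  faces share at least one cue with probability `1 − 1/(2^k − 1)` (= 6/7 for
  the 8-face design), and the expected per-cue categorization score under
  uniform error choice is `(s − d)/(2^k − 1)` with `s = 2^(k−1) − 1`,
  `d = 2^(k−1)` (= −1/7).
- **Scoring** (`wsw.scoring`): for each participant and cue *c*, the
  proportional categorization score over that participant's errors,

  ```
  score_c = (within_c − between_c) / total errors ∈ [−1, 1],
  ```

  where an error is *within-category* when the chosen face shares cue *c*
  with the true speaker. Scores for different cues are computed
  independently (an error can be within-category for several cues), are
  undefined for zero-error participants (flagged, never imputed), and are
  reported against the analytic −1/7 chance level rather than base-rate
  corrected. One-sample t-tests, Cohen's d, and feature-overlap analyses
  (participant-level t and trial-level exact binomial against the 6/7
  baseline) are included.
- **Cue-interdependence regression** (`wsw.inference`): a
  statsmodels-style model/results pair. `CueRegressionModel(scores).fit()`
  estimates, by OLS on uncentered scores,

  ```
  scar_i = b0 + b1·race_i + b2·sex_i + b3·race_i·sex_i + e_i
  ```

  and the results object gives coefficient tables, **simple slopes**
  `b1 + b3·v` with delta-method standard errors at moderator levels
  mean ± 1 SD, slope contrasts, covariate models, and nested-model ΔF/ΔR²
  comparisons.
- **Constrained resampling null** (`wsw.nullsim`): because all cue scores
  are computed from one finite error pool per participant, they are
  mechanically interdependent. The null simulation keeps every correct
  trial and every error *position* fixed and redraws only the chosen face
  on each error, uniformly over the 7 alternatives; scores and the
  regression are then recomputed with the *same code path* as the primary
  analysis (5000 replicates by default), yielding empirical null
  distributions for R² and each coefficient, order-statistic quantiles,
  and add-one-corrected tail probabilities.
- **Synthetic cohorts** (`wsw.simulate`): a generative stand-in for real
  data with known ground truth. Each participant has an accuracy
  (probability a trial is answered correctly) and one latent weight per
  cue; error choices follow a cue-match softmax,
  `P(choose f) ∝ exp(Σ_c w_c · match_c(f, true))`, which nests uniform
  guessing at `w = 0`. Defaults: 500 participants × 24 trials, accuracy
  ~ Beta(6, 4), weight means (1.0, 0.15, −0.15) for (sex, race, scar) —
  a strong sex cue, weak race cue, and weak contrastive scar cue.

## Worked example

```python
import wsw

face_set = wsw.default_face_set()                      # sex × race × scar, 8 faces
trials, latents = wsw.simulate_cohort(wsw.GeneratorConfig(seed=11))

scores = wsw.categorization_scores(trials, face_set)
print(wsw.overlap_statistics(trials, face_set))
res = wsw.fit_interaction_model(scores)
print(res.summary())
null = wsw.run_null_simulation(trials, face_set,
                               wsw.NullSimConfig(n_replicates=5000, seed=11))
print(null)
```

prints (exactly, for this seed):

```
participant-level overlap: M = 90.8% (SD = 12.7%), t(497) = 8.91, p = 9.31e-18, d = 0.40; trial-level: 4561 of 5030 (90.7%) vs 85.7% (exact binomial, greater, p = 1.38e-26)

OLS: scar score ~ race + sex + race:sex
n = 498, R^2 = 0.247, F(3, 494) = 54.12, p = 2.91e-30

           Estimate     SE        t      p
Intercept   -0.2624 0.0226 -11.6312 0.0000
race        -0.3109 0.0427  -7.2763 0.0000
sex         -0.2671 0.0393  -6.7984 0.0000
race:sex    -0.3349 0.0684  -4.8980 0.0000

Constrained null: 5000 replicates (seed 11, 0 failed fits)
  r2: observed = 0.247, null 99.9% quantile = 0.182, p = 0.0002
  b_Intercept: observed = -0.262, null 99.9% quantile = -0.156, p = 0.0016
  b_race: observed = -0.311, null 99.9% quantile = -0.075, p = 0.08838
  b_sex: observed = -0.267, null 99.9% quantile = -0.072, p = 0.2833
  b_race:sex: observed = -0.335, null 99.9% quantile = 0.215, p = 0.2456
```

Reading it: errors overlap the true speaker's features well above the 6/7
chance level, so responding is not random guessing. Two of 500 simulated
participants made no errors and are excluded (n = 498). Scar-based
categorization falls as race- and sex-based categorization rise (negative
`race` and `sex` coefficients, negative interaction), and the model's R²
of 0.247 lies far beyond anything the shared-error-pool artifact alone
produces (null 99.9% quantile 0.182, add-one p = 1/5001) — the regression
captures genuine cue-driven structure planted by the generator, while the
individual coefficient draws show how much mechanical trade-off the null
itself can produce.

The same pipeline is scriptable from the shell:

```sh
wsw sim --seed 11 --out run/
wsw score --trials run/trials.csv --faces run/faces.csv --out run/
wsw analyze --scores run/scores.csv --out run/
wsw nullsim --trials run/trials.csv --faces run/faces.csv --reps 5000 --seed 11 --out run/
wsw report --seed 11 --out run/report   # everything, plus figures
```

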