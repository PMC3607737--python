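# Methods

This note documents the statistical models implemented in `oksmap`, the
choices made where the design was genuinely open, and what the synthetic
data can and cannot establish.

## Tariff engine

An EQ-5D-3L state is a 5-tuple of levels (1 = no, 2 = some, 3 = severe
problems) on mobility, self-care, usual activities, pain/discomfort and
anxiety/depression; there are 3⁵ = 243 states. An additive tariff values a
state as

```
U = full_health
    - any_problem · 1[any level > 1]
    - Σ_d dec_d(level_d)
    - n3 · 1[any level = 3]
```

with `dec_d(1) = 0`. The packaged UK time-trade-off constants are
`any_problem = 0.081`, per-domain level-2/level-3 decrements
(MO 0.069/0.314, SC 0.104/0.214, UA 0.036/0.094, PD 0.123/0.386,
AD 0.071/0.236) and `n3 = 0.269`. They are validated on load (all
decrements non-negative, level-3 ≥ level-2 per domain) and by the test
suite against the known anchors: full health values to exactly 1, the
worst state 33333 to −0.594, and 11121 to 0.796. Tariffs are pluggable via
a long-format CSV (`tariff_name, term, value`), so non-UK value sets can be
added without code changes; only the UK set ships validated, because no
authoritative in-repo anchor exists for the others.

`enumerate_states()` orders states lexicographically with
anxiety/depression varying fastest (11111, 11112, …, 33333). The
expected-value enumeration and the state→class partition rely on this
fixed order.

The outcome classification used by the three-part model is: `perfect`
(all level 1), `n3` (any level 3 — the states carrying the N3 decrement),
`mild_moderate` (the remaining 31 states). Utilities rescale to [0, 1] by
`(U − U_min)/(U_max − U_min)` — `(U + 0.594)/1.594` for the UK set — for
the fractional-logit model.

## OKS coding

Items follow one canonical order everywhere (design vectors, the packaged
coefficient file, reports): pain, washing/drying, transport, walking time,
standing, limping, kneeling, night pain, work, instability, shopping,
stairs. The `dummies48` coding gives each item four indicators for levels
0–3 with level 4 (no problems) as reference; `scores12` uses the raw 0–4
item scores as numeric regressors; `total1` the 0–48 sum. The three
codings are nested linear spans (each score is affine in its item's
dummies, the total affine in the scores), which is why in-sample OLS error
is monotone across them — a property the tests assert.

Only complete questionnaires are analysed; `complete_case_filter` drops
records missing any OKS item (or, when observed EQ-5D is required, any
domain) and reports counts by reason. No half-scale or imputation rule is
implemented: mapping models fitted to imputed items would blur the
item-level coefficients that are the point of the dummies coding.

## Response mapping and the expected-value method

One model per EQ-5D domain predicts P(L1), P(L2), P(L3) from the OKS
design:

* **multinomial logit** with level 1 as base: with linear predictors η₂,
  η₃, `P(L1) = 1/(1+e^{η₂}+e^{η₃})`, etc. The packaged published model has
  this form — per domain, two 49-vectors (48 dummies + intercept) for the
  L2-vs-L1 and L3-vs-L1 contrasts, 490 coefficients in total. The file
  carries a SHA-256 checksum and five anchor coefficients are re-verified
  on every load. Coefficients are transcribed at their printed three-decimal
  precision, so predictions approximate the authors' full-precision model.
* **ordered logit** (proportional odds), estimation-only:
  `P(level ≤ k) = logistic(θ_k − xβ)` with two increasing thresholds.
  No published ordinal coefficients exist, so this link has no packaged
  model.

A predicted utility is the expectation of the tariff under the implied
distribution over the 243 states, treating domains as independent given
the covariates — consistent with fitting each domain separately. Two
implementations are kept deliberately:

* *enumeration* (reference): Σ over 243 states of the product probability
  times the state utility;
* *decomposition* (fast path): because the tariff is additive,
  `E[U] = full_health − any_problem·(1 − Π_d P(L1_d))
  − Σ_d [P(L2_d)·dec_d(2) + P(L3_d)·dec_d(3)]
  − n3·(1 − Π_d (1 − P(L3_d)))`.

They are algebraically identical; the tests require agreement to 1e-10 on
1,000 random distribution sets. A Monte Carlo valuation (mean tariff value
over sampled states) converges to the expected value at the usual n^(−1/2)
rate and exists as a diagnostic and teaching device. The
highest-probability assignment (per-domain argmax, ties broken toward the
healthier level so the rule is deterministic) is retained only because it
is the naive alternative one must *not* use for valuation: it
systematically under-predicts severe problems.

## Direct and composite specifications

Eight specifications share one interface (`fit_mapping(data, spec_id,
coding)`) and one prediction contract (a utility per questionnaire):

| spec | outcome | prediction rule |
|---|---|---|
| `ols` | utility | linear predictor, capped at 1 from above (no lower cap) |
| `glm_gamma` | disutility 1−U | gamma family, identity link by default; `1 − μ̂` |
| `glm_log_gaussian` | disutility | Gaussian family, log link; `1 − exp(xβ)` |
| `fractional_logit` | (U+0.594)/1.594 | quasi-likelihood binomial/logit; `1.594·p̂ − 0.594`, strictly inside the tariff range |
| `two_part` | ceiling + conditional | `P + (1−P)·U`, logistic ceiling model plus OLS below the ceiling |
| `three_part` | class + two conditionals | `P₁ + P_N3·U_N3 + (1−P₁−P_N3)·U_mm`, multinomial class model plus per-class OLS |
| `rm_ordinal` / `rm_multinomial` | domain levels | expected-value method over the fitted distributions |

Open choices resolved here:

* **Gamma link.** The model-comparison table of the source literature
  labels the gamma GLM with an identity link while the accompanying text
  describes log links; both are implemented and selectable
  (`glm_gamma_link`), with identity as the default to match the tabulated
  comparison.
* **Gamma zeros.** Gamma responses must be positive but perfect health has
  disutility 0. Default policy shifts exact zeros by ε = 1e-6 with a
  warning; a `drop` policy excludes perfect-health records instead. The
  shift is the minimal intervention that lets the family fit without
  changing the estimand materially.
* **No inner truncation.** The conditional OLS parts of the composite
  models are combined untruncated; only the standalone OLS specification
  caps predictions at 1. Whether the original analyses truncated the
  inner parts is unstated; combining raw conditional means keeps the
  convex-combination algebra exact.
* **Level merging.** The logistic/multinomial first parts of the composite
  models are prone to perfect separation on sparse item levels. By default
  the two-part model merges washing/drying levels 0 and 1, and the
  three-part model additionally merges work levels 0 and 1 — the merges the
  original estimation needed. `merge_map` overrides or disables this;
  merges never touch the continuous parts. Separation that survives the
  merge is detected (non-finite standard errors or |coef| > 15) and
  reported as a warning rather than silently dropped.
* **Degenerate subsets.** Within a conditional subset an item level may be
  absent, or an item may never sit at its reference level (making its
  dummies sum to the intercept). Subset models prune such columns by
  pivoted QR and record the dropped names; the standalone OLS instead
  raises an informative rank-deficiency error naming the columns, since on
  the full sample that indicates a data problem the user should see.

Estimation is maximum likelihood via statsmodels (OLS/GLM/Logit/MNLogit/
OrderedModel). L-BFGS is the primary optimizer for the categorical models
— Newton steps can silently diverge under quasi-separation — with a Newton
fallback and an explicit error if both diverge. Cluster-robust standard
errors grouping repeated questionnaires within patients are available via
`cluster_col` (point estimates unaffected).

## Evaluation

Accuracy is MSE (selection criterion), MAE (secondary) and the signed mean
residual. Validation splits sample *patients*, not questionnaires, so all
records of a patient land on one side; splits are reproducible by seed.
`compare_models` fits every requested specification on the estimation
partition, scores both partitions, and ranks by validation MSE with ties
broken by MAE and then parsimony (fewest parts); a failing specification
is recorded with its reason and does not abort the comparison.
Diagnostics report the mean residual below/at-or-above observed utility
0.5 (ceiling and floor effects show up as opposite signs — predictions
compress toward the middle), MSE by decade bands of total OKS (0–10 …
41–48; the band edges are a convention, configurable), and the
range/SD of predictions versus observations. Calibration tables compare
observed level proportions with mean predicted probabilities per domain
(5 × 3); chi-squared testing of those proportions is deliberately not
reproduced — the table is descriptive.

## Synthetic cohorts

The generator is a one-factor latent-trait model:

* patient i has a latent knee-health trait `θ_i ~ N(0, icc)`; a
  questionnaire adds `N(0, 1 − icc)` noise, so the questionnaire-level
  latent is standard normal marginally and questionnaires from one patient
  correlate with intraclass correlation `icc` (default 0.75);
* surgery shifts the latent mean by `μ_post`, solved so the expected
  post-operative total OKS equals 33.79;
* item j adds `N(0, σ_item²)` noise (default σ_item = 0.6) and is scored by
  four strictly increasing thresholds: score = number of thresholds below
  the item latent. Per item, the threshold location and spacing are solved
  (closed-form Gaussian moments, least squares) so the pre-operative item
  mean and SD match the published pre-operative summaries of the national
  knee-replacement cohort (e.g. pain 0.55 (0.66), washing/drying 2.79
  (1.03)); the twelve calibrated items then reproduce the pre-operative
  total of 18.59 by construction;
* EQ-5D levels are drawn per domain, by default from the packaged
  published model given the simulated OKS dummies (`published_model`
  mode). This makes the generating coefficients known, so coefficient
  recovery and specification ranking can be tested against a ground truth.
  The alternative `latent_thresholds` mode instead thresholds the same
  latent trait per domain, calibrated to the published pre-operative
  level-2/level-3 proportions, and is useful when the response-mapping
  model must *not* be the truth (e.g. to show misspecification effects).

Presets: `preop_like` and `postop_like` give one questionnaire per patient
in the corresponding phase; `mixed` gives every patient a pre-operative
questionnaire plus one or two post-operative follow-ups (70/30). At
n = 10,000 patients the presets reproduce mean total OKS 18.6/33.8 within
±1 and mean UK utility 0.39/0.70 within ±0.05 (asserted in the acceptance
tests), and post-operative utilities are multimodal: a ceiling mass at 1,
a mild-problem plateau around 0.6–0.8, and a severe (N3) tail — the
signature the N3 decrement imprints on real utility distributions.

What the generator does **not** emulate: multidimensional symptom
structure (a single factor drives all items, so the synthetic total-OKS SD
is somewhat larger than the published 7.95 because items are more strongly
inter-correlated than in real data); phase-specific item-level means after
surgery (a single latent shift matches the post-operative total, not each
item); dataset- or era-specific coefficient differences; informative
missingness (`inject_missingness` is completely at random). Consequently,
passing tests show that the estimation and evaluation machinery is
correct under a plausible data-generating process — not that the packaged
model is accurate for any particular real population.

Because EQ-5D responses are simulated independently across questionnaires
given the OKS design, plain maximum-likelihood standard errors are the
correct yardstick in the parameter-recovery test; cluster-robust errors
remain available for real repeated-measures data.

## Numerical conventions

* Probabilities from softmax/logistic transforms are computed with
  max-subtraction to avoid overflow; domain distributions must sum to 1
  within 1e-9 on input and the enumeration/decomposition identity is
  enforced at 1e-10.
* All randomness flows through `numpy.random.default_rng(seed)`; every
  stochastic CLI subcommand requires an explicit seed, and identical seeds
  give byte-identical simulation output.
* Serialized fits are versioned JSON containing parameter vectors and
  feature names, so predictions are reproducible without pickling model
  objects.
* Problem sizes in the test suite (cohorts of roughly 400–10,000 patients,
  a 20,000-questionnaire recovery experiment) were chosen so the full
  suite runs in a few minutes on one CPU while leaving the stochastic
  assertions comfortable margins.

## Known limitations

* Predictions carry no uncertainty intervals; the machinery estimates
  standard errors for coefficients, not for predicted utilities.
* The packaged model is transcribed at printed precision; residual
  rounding is negligible relative to coefficient standard errors but makes
  bit-exact replication of the authors' predictions impossible.
* Only the three-level EQ-5D is supported: no EQ-5D-5L, crosswalks, or
  visual-analogue scoring.
* Published model coefficients contain level orderings that contradict the
  OKS's implicit item ordering (documented in the source literature);
  utilities predicted from the packaged model are therefore not guaranteed
  monotone in single-item improvements, and the tests deliberately do not
  assert such monotonicity.
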