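# oksmap

Map Oxford Knee Score (OKS) questionnaires to EQ-5D-3L responses and
utilities.

Many knee-replacement trials and registries collect the OKS — a validated
12-item questionnaire, each item scored 4 (no problems) down to 0 (severe
problems), summed to a 0–48 total — but no generic preference-based
instrument. Cost-utility analysis, however, needs *utilities*: valuations of
health on a scale where 1 is full health and 0 is death, the input to
quality-adjusted life-years. `oksmap` implements the machinery for
*mapping* (cross-walking) OKS onto the EQ-5D-3L, whose five domains
(mobility, self-care, usual activities, pain/discomfort,
anxiety/depression) at three levels each define 243 health states valued by
a published tariff. It is aimed at health economists and outcomes
researchers who need EQ-5D utilities for studies that only administered the
OKS, and at methodologists comparing mapping-model specifications.

## What is inside

* **Tariff engine** (`oksmap.tariff`) — EQ-5D-3L states, enumeration of all
  243 of them, and additive value sets with the any-problem constant and the
  N3 decrement (applied once when any domain is at level 3). The UK
  time-trade-off set ships packaged and validated (range −0.594 to 1);
  other tariffs plug in via a constants CSV.
* **OKS instrument** (`oksmap.oks`) — validation, 0–48 scoring, the
  48-indicator design coding (one dummy per item per level 0–3, level 4 as
  reference), and complete-case filtering.
* **Response mapping** (`oksmap.response_mapping`) — one multinomial (or
  ordered) logit per EQ-5D domain predicting the level probabilities from
  the OKS dummies, plus the published fitted multinomial model packaged as
  data with checksum and anchor verification. Predicted distributions are
  valued by the *expected-value method*:

  utility<sub>i</sub> = Σ<sub>s∈243 states</sub> Π<sub>d</sub> P(level<sub>d</sub>(s) | x<sub>i</sub>) · U(s)

  computed both by explicit enumeration and by an algebraically identical
  closed-form decomposition over the additive tariff terms. A Monte Carlo
  valuation and the (biased, diagnostic-only) highest-probability
  assignment are also provided.
* **Direct models** (`oksmap.direct_models`) — the competing
  specifications: OLS on utility (predictions capped at 1), gamma and
  log-link Gaussian GLMs on disutility 1 − U, a fractional logit on
  utility rescaled to [0, 1] via (U + 0.594)/1.594, and the composite
  models:

  * two-part: `U* = P(U=1) + (1 − P(U=1)) · E[U | U<1]`
  * three-part: `U* = P(U=1) + P(N3) · E[U | N3] + (1 − P(U=1) − P(N3)) · E[U | mild/moderate]`

  where the three-part classes come from a multinomial model over
  {perfect health, severe problems on ≥1 domain (N3), mild/moderate}.
* **Evaluation** (`oksmap.evaluation`) — MSE/MAE scoring, patient-level
  validation splits (all questionnaires of a patient travel together),
  an eight-way specification comparison ranked by validation MSE, and
  residual/calibration diagnostics.
* **Synthetic cohorts** (`oksmap.synthetic`) — a latent-trait generator
  reproducing the published pre-/post-operative summary statistics
  (mean total OKS ≈ 18.6 pre-operatively and ≈ 33.8 post-operatively,
  mean UK utility ≈ 0.39 and ≈ 0.70), within-patient clustering, and
  EQ-5D responses drawn from the packaged model so that estimation code
  can be tested against a known truth.

## Worked example

Predict EQ-5D for one questionnaire (item scores in the canonical order
pain, washing, transport, walking, standing, limping, kneeling, night pain,
work, instability, shopping, stairs):

```python
import pandas as pd
import oksmap as om
from oksmap.oks import ITEM_COLUMNS, dummy_design

uk = om.load_tariff()                  # UK time-trade-off value set
model = om.load_published_model()      # packaged multinomial response mapping

scores = [1, 3, 2, 2, 1, 1, 0, 2, 1, 2, 2, 2]   # total OKS = 19
data = pd.DataFrame([scores], columns=list(ITEM_COLUMNS))
dists = model.predict_distributions(dummy_design(data).to_numpy())
print(om.expected_utility(dists, uk))  # [0.5549...]
```

The predicted level distributions behind that number:

```
mobility             P(L1)=0.014  P(L2)=0.986  P(L3)=0.001
self_care            P(L1)=0.745  P(L2)=0.253  P(L3)=0.002
usual_activities     P(L1)=0.019  P(L2)=0.899  P(L3)=0.083
pain_discomfort      P(L1)=0.003  P(L2)=0.905  P(L3)=0.092
anxiety_depression   P(L1)=0.598  P(L2)=0.383  P(L3)=0.020
```

So this patient almost certainly has some mobility, activity and pain
problems, probably no self-care problems, and an expected utility of 0.555
— the probability-weighted tariff value over all 243 states, which is what
should enter a QALY calculation (not the utility of the single most likely
state, 0.691 for modal state 21221, which is biased against severe
outcomes).

The same flow from the shell:

```bash
oksmap simulate --preset mixed --n-patients 200 --seed 1 --out cohort.csv
oksmap predict  --in cohort.csv --out predictions.csv
oksmap evaluate --in cohort.csv --out report.json
# [oksmap 0.1.0] evaluate published response mapping: MSE=0.0231 MAE=0.1001
oksmap compare  --in cohort.csv --seed 1 --out comparison.csv
```

`fit` estimates any of the eight specifications
(`--spec {ols,glm_gamma,glm_log_gaussian,fractional_logit,two_part,three_part,rm_ordinal,rm_multinomial}`,
`--coding {dummies48,scores12,total1}`) and writes a portable JSON fit that
`predict` and `evaluate` accept.

Note that the packaged coefficients are transcribed at their printed
precision (three decimals), so predictions approximate the authors'
full-precision model.

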