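# stabcox

Bootstrap stability selection for L1-penalized Cox regression, built for a
recurring question in digital-health research: **which baseline
characteristics predict dropout from a multi-session online intervention?**

The motivating setting is a 6-session anonymous online program for women
with eating disorder symptoms. Roughly half of such cohorts terminate
early, attrition is spread over the sessions, and with ~90 dropout events
against 14 candidate predictors (events per variable ≈ 6.5, well under the
conventional minimum of 10) an ordinary Cox regression is unstable. The
package implements the penalized-bootstrap workflow that handles this
regime, end to end:

1. **Eligibility screening** — the trial's inclusion/exclusion rules
   (female gender, weekly compensatory symptoms, 15 < BMI < 30, CES-D < 35,
   and the psychosis/dissociation/substance/psychotherapy exclusions) with
   machine-readable reason codes.
2. **Cohort model** — one row per participant: 14 baseline covariates
   (four EDE-Q subscales, BMI, three 28-day behaviour frequencies, four
   URICA stage-of-change subscales, HSCL-25 depression, age), the session
   of dropout (1–6), and an event indicator; censoring only at session 6.
3. **Attrition curves** — discrete-grid Kaplan–Meier life tables with
   Greenwood variance and log(−log) 95% bands, plus median-split
   stratified curves.
4. **Penalized Cox core** — Breslow partial likelihood (normalized by n),
   Newton–Raphson MLE, cyclic coordinate-descent LASSO, warm-started
   penalty paths, K-fold cross-validation of λ by the
   Verweij–van Houwelingen deviance.
5. **Bootstrap stability selection** — the headline procedure: B
   pseudosamples drawn with replacement, each re-standardized, CV-tuned
   and LASSO-fitted; a covariate is *identified* as a predictor when it is
   selected in more than 50% of pseudosamples **and** its bootstrap 95% CI
   excludes zero.
6. **Synthetic cohort generator** — no individual-level data from the
   motivating study are available, so the generator reproduces its study
   conditions: published covariate means/SDs/ranges (moment-matched
   bounded normals, zero-inflated behaviour counts), a discrete-time
   proportional-hazards dropout process, and a baseline hazard calibrated
   to 50.8% overall attrition.

## The model

For participant *i* with standardized covariates *x<sub>i</sub>* and
linear predictor η<sub>i</sub> = x<sub>i</sub><sup>T</sup>β, dropout at
session *j* occurs with probability

&nbsp;&nbsp;p<sub>ij</sub> = 1 − (1 − h<sub>j</sub>)<sup>exp(η<sub>i</sub>)</sup>,

a grouped-time proportional-hazards law. Estimation minimizes the
per-n Breslow negative log partial likelihood with an L1 penalty,

&nbsp;&nbsp;−ℓ(β)/n + λ‖β‖₁,

by coordinate descent on an iteratively reweighted quadratic
approximation; λ is chosen per sample by K-fold cross-validated partial
likelihood deviance. Stability selection repeats the whole tuning-and-
fitting pipeline on every bootstrap pseudosample.

## Worked example

```python
import stabcox as sc

cfg = sc.default_config(effect=0.4)          # study-condition generator
cohort = sc.generate_cohort(cfg, seed=7)

epv, below = cohort.events_per_variable()
print(f"n={len(cohort)}  events={cohort.n_events}  "
      f"dropout={cohort.dropout_rate():.1%}  EPV={epv:.1f} (below 10: {below})")

lt = sc.fit_km(cohort.event_times, cohort.events)
print(lt.table[["session", "at_risk", "events", "survival",
                "ci_low", "ci_high"]].round(3).to_string(index=False))

res = sc.bootstrap_lasso(cohort, B=200, K=10, seed=11)
print(res.summary())
```

prints

```
n=179  events=88  dropout=49.2%  EPV=6.3 (below 10: True)
 session  at_risk  events  survival  ci_low  ci_high
       1      179      26     0.855   0.794    0.899
       2      153      20     0.743   0.672    0.801
       3      133      10     0.687   0.614    0.750
       4      123      12     0.620   0.545    0.687
       5      111      10     0.564   0.488    0.633
       6      101      10     0.508   0.433    0.579
Bootstrap stability selection (L1-penalized Cox)
  pseudosamples B=200, CV folds K=10, rule='min', seed=11, redraws=0
  identification: selection frequency > 50% and 95% percentile CI excluding 0

covariate                  lasso    mean     sd   ci_low  ci_high       p   freq  identified
--------------------------------------------------------------------------------------------
binge_28d                  0.343   0.407  0.096    0.242    0.617   0.005   1.00  yes
vomit_28d                  0.270   0.305  0.091    0.151    0.475   0.005   1.00  yes
hscl_depression            0.226   0.267  0.112    0.027    0.477    0.05   0.97  yes
edeq_shape_concerns        0.138   0.173  0.124    0.000    0.444    0.21   0.90  no
urica_contemplation       -0.063  -0.125  0.095   -0.329    0.000    0.37   0.81  no
...
```

Reading the table: half the cohort dropped out (26 of 179 already at
session 1); the life table tracks the proportion remaining with its 95%
band. In the stability report, binge-eating frequency, vomiting frequency
and depression were selected in essentially every pseudosample with
bootstrap CIs bounded away from zero, so they are flagged as dropout
predictors. Shape concerns — a true predictor in this simulation — was
selected in 90% of pseudosamples, but its percentile CI touches zero, so
the conjunction rule (deliberately conservative) withholds the flag at
this B. Coefficients are log hazard ratios per SD of the covariate:
0.34 for binge eating means one SD more frequent binge eating multiplies
the per-session dropout hazard by e^0.34 ≈ 1.41.

The same pipeline is scriptable from the shell:

```sh
stabcox simulate --n 179 --seed 7 --out cohort.csv
stabcox describe cohort.csv --out table1.csv
stabcox curves cohort.csv --stratify edeq_shape_concerns --out km.csv
stabcox bootstrap cohort.csv --b 1000 --k 50 --seed 11 --out stability
stabcox run --seed 7 --out results/   # everything, with a manifest
```

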