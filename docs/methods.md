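# Methods

This note documents the statistical model, the numerical choices, and the
scope of the synthetic-data defaults. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Outcome model and event-time encoding

Dropout is patient-initiated non-completion: a participant who finished
session *j*−1 but not session *j* has `event_time = j`, `event = 1`;
completers of all 6 sessions are censored at session 6 (`event = 0`).
The data model permits `event_time = 1` (dropout before the first
session's completion) for generality, since commencement definitions vary
between recruitment and analysis descriptions.

Event times live on a 6-point grid, so ties are massive by construction.
The partial likelihood uses the **Breslow** approximation (one shared
risk-set denominator per session), the convention of the penalized-Cox
literature; subjects censored at a session remain in that session's risk
set (events counted before censoring — this matters at session 6, where
completers are censored and dropouts can also occur).

The negative log partial likelihood is **normalized by n**. This makes
the penalty weight λ comparable between the full sample and bootstrap
pseudosamples of equal size, and makes solutions invariant to duplicating
every record (tested).

## Penalized estimation

* **Unpenalized MLE**: Newton–Raphson on the full Hessian with
  step-halving; convergence when the largest coefficient update is below
  1e−8. A monotone partial likelihood (risk-set separation) is flagged —
  not raised — when any |β| exceeds 20 on the standardized scale.
* **LASSO**: cyclic coordinate descent on the iteratively reweighted
  quadratic (diagonal-Hessian) approximation with soft-threshold updates,
  warm starts along a log-spaced penalty path from λ_max (the sup-norm of
  the null gradient) downward. A step-halving line search on the outer
  update keeps the penalized objective nonincreasing. Final fits converge
  at 1e−7 on the largest update; CV fold fits run at 1e−5, a level at
  which the CV curve is insensitive (the selected λ is refitted at 1e−7).
  KKT subgradient conditions are verified to 1e−6 in the test suite, and
  solutions match R `glmnet` (family="cox", standardize=FALSE) to ~1e−5
  on frozen oracle instances.
* Covariates are standardized to mean 0, sample SD 1 (n−1 denominator)
  before fitting, because the L1 penalty is not scale-invariant;
  coefficients are reported per SD, with native-scale conversions
  available. All 14 covariates carry equal penalty weight.

## Cross-validation of λ

With K as large as 50 on n ≈ 179, held-out folds are too small for their
own partial likelihood (risk sets of size 1–4, folds without events).
The CV deviance therefore uses the **Verweij–van Houwelingen difference
form**: fold k contributes 2·[negPL_full(β₋ₖ) − negPL₋ₖ(β₋ₖ)] with
unnormalized log partial likelihoods, which is well defined for any fold
size. Folds are event-stratified by default (sizes and per-fold event
counts each differ by at most 1); a fold whose removal leaves training
data without events is skipped and recorded.

Selection rules: `"min"` (default) takes the λ minimizing the CV
deviance, ties toward the smaller λ; `"1se"` the largest λ within one
standard error of the minimum; `"path_min"` the literal smallest λ on the
path. The published description of this procedure ("the smallest lambda
was then chosen") is ambiguous between the first and last readings; the
default follows the CV-optimal reading, since selecting the smallest path
value would make the CV step inert, and the literal reading remains
available for sensitivity analysis.

## Bootstrap stability selection

Defaults follow the study conditions: **B = 1000** pseudosamples,
**K = 50** folds (tests and worked examples use B = 200, K = 10 — about
8 s per run instead of ~7 min — which leaves aggregate behaviour
qualitatively unchanged). Each pseudosample of size n is drawn with
replacement, re-standardized internally, path-built, CV-tuned and fitted;
its coefficients are mapped back to the full-sample standardized scale by
the SD ratio so estimates are comparable across pseudosamples. Degenerate
pseudosamples (< 2 events, or a constant covariate) are redrawn so B is
exact. The bootstrap path uses 50 log-spaced λ values down to
λ_max·0.05; the standalone `lambda_path` default is 100 values down to
λ_max·0.01.

Aggregation keeps zero coefficients in the mean/SD/CI computations by
default (`include_zeros=False` is available for sensitivity analysis).
The **identification rule** is the conjunction: selection frequency
> 50% AND the 95% bootstrap CI excludes zero.

Two CI readings are implemented, and the choice matters:

* `ci_method="percentile"` (default): the empirical percentile interval
  of the raw estimates. With zeros included it excludes zero only when
  the selection frequency exceeds 97.5%, so the conjunction is strictly
  conservative — a predictor must be selected essentially always to be
  flagged. On null cohorts (no true effects) this rule identifies
  nothing across seeds in the test suite.
* `ci_method="mean"`: the normal-theory CI of the bootstrap mean,
  mean ± z·SD/√B. This reproduces the arithmetic of published
  mean/SD/CI triples for this procedure, but its width shrinks with B,
  so at large B it flags any covariate whose chance association with the
  realized sample is consistently signed; it is offered for comparison
  with published tables, not as an identification default.

The per-covariate p-value is a two-sided bootstrap sign test,
2·min(#{est ≤ 0}, #{est ≥ 0})/B, floored at 1/B — the source analyses
print p-values without defining the test, so this definition is the
package's own.

## Attrition curves

Product-limit estimation on the session grid with Greenwood variance and
95% bands on the log(−log) scale (stabler than plain Wald near survival
0 or 1, and guaranteed inside [0, 1]); the band collapses to the point
estimate where no events have occurred. Median-split stratification
sends values ≤ the sample median (midpoint of central order statistics
for even n) to the "low" stratum; the split is undefined for constant
covariates.

## Synthetic cohort generator

The generator defines the study conditions under which the pipeline is
exercised; its defaults are fixed, not tuning knobs.

* **Marginals**: the published baseline table (mean, SD, min, max for all
  14 covariates; e.g. age 27.54 (8.02) on [18, 59], shape concerns
  4.17 (1.29) on [0.5, 6]). Draws come from bounded normals whose latent
  parameters are **moment-matched** so the observed mean and SD hit the
  targets despite bounding — naive truncation of N(27.54, 8.02²) to
  [18, 59] would shift the age mean upward by more than 2 SEM at
  n = 179. Continuous covariates use exact inverse-CDF truncated
  normals. The three 28-day behaviour counts print SDs above the maximum
  any truncated normal on [0, 28] can reach, so they use **censored**
  (clipped) normals instead: the atom at 0 emulates the zero inflation
  of real behaviour-frequency data (about half the cohort reports zero
  vomiting episodes), and counts are rounded to integers.
* **Correlation**: identity by default (the source reports no covariate
  correlations); a user-supplied correlation couples the latent normals
  through a Gaussian copula (slightly attenuated on the bounded scale).
  This default matters: with orthogonal covariates, a null covariate's
  chance association with dropout (|r| ≈ 0.1 at n = 179) is absorbed by
  nothing and keeps bootstrap selection frequencies of some null
  covariates above 50%; in real data, strongly correlated symptom scales
  absorb such associations. Conclusions about the identification rule's
  specificity under identity correlation are therefore conservative.
* **Dropout process**: per-session probability 1 − (1 − h_j)^exp(η) with
  η = x·β on the within-sample standardized scale; β defaults to 0.3 on
  the four predictors the motivating analysis identified (shape concerns,
  vomiting, binge eating, depression) and 0 elsewhere — a scale-free
  config value, not an estimate. The constant baseline hazard h is
  calibrated so expected overall dropout is 50.8%: closed-form
  1 − (1 − 0.508)^(1/6) ≈ 0.1115 when β = 0, otherwise Monte-Carlo
  bisection (50 000 subjects, common random numbers, tolerance 0.002).
  Whether the published "approximately 10% per session" means 10% of the
  initial or of the remaining sample is ambiguous (8.5% vs 11.2%);
  calibration targets the overall 50.8% and leaves that reading open.
* **Not emulated**: item-level questionnaire responses, longitudinal
  post-treatment measures, covariate correlations (by default), informative
  censoring, and time-varying effects. Passing tests on synthetic cohorts
  therefore validate the estimation machinery and the procedure's
  operating characteristics under a known truth — not distributional
  claims about any real cohort.

## Reproducibility

Every stochastic stage takes an explicit seed; the pipeline derives
generator, fold and bootstrap sub-seeds from one master seed via named
`SeedSequence` streams, and writes a manifest with parameters and SHA-256
checksums of every output. Re-running a manifest's configuration
reproduces its outputs byte for byte (tested).

## Known limitations

* The identification rule's sensitivity at desk-scale B: with the
  conservative percentile reading, a true predictor needs > 97.5%
  selection frequency to be flagged, so moderate effects (≈ 0.4 per SD at
  n = 179) are identified in roughly half of replicate cohorts at
  B = 200, while null cohorts essentially never produce false flags. The
  rule trades recall for specificity by design.
* Breslow (not Efron) tie handling; with six sessions and ~90 events the
  approximation is coarse but standard for penalized fits, and it is the
  convention the cross-validated oracle (`glmnet`) uses.
* The unpenalized Newton fit reports, but does not resolve, monotone
  likelihood; no Firth correction is implemented.
* No elastic-net mixing, stratified baselines, time-varying covariates,
  or competing risks.
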