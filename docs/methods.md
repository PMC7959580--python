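# Methods

This note documents the generative model, the estimators, the numerical
choices behind them, and what the synthetic-data tests do and do not
establish about real behavioral data.

## Generative observer

Each simulated subject is an equal-variance Gaussian signal-detection
observer. On a trial with square difference Δ (a positive integer; the
comparison grid holds 200 + Δ of 400 positions, the reference 200) and the
larger stimulus on side s ∈ {left, right}, decision evidence is

    e ~ Normal(s·Δ/σ_p, 1),   s = +1 for right, −1 for left,

and the response is the sign of e. The lapse-free psychometric is then
exactly Φ(Δ/σ_p), passing through 0.5 at Δ = 0, which is the identifying
assumption the calibration fit relies on. Additional mechanisms:

- **Lapses** (`lapse`, default 0): a stimulus-independent uniform guess,
  giving accuracy `lapse/2 + (1−lapse)·Φ(Δ/σ_p)`.
- **Misses** (`miss_rate`, default 0.02): an independent Bernoulli
  no-response event. The human study excluded a few percent of trials for
  misses and RT outliers; 2% reproduces that order of magnitude.
- **Confidence**: meta-level evidence m = |e| + Normal(0, σ_m), cut by five
  fixed increasing criteria into ratings 1–6. With σ_m = 0 the confidence
  data are exactly as diagnostic as the decisions (M-ratio 1, the SDT-ideal
  observer); increasing σ_m degrades meta-d′ and AUROC2 without touching
  type-1 accuracy, which is what makes it the single dial for
  metacognitive efficiency. The default σ_m = 0.5 yields M-ratio ≈ 0.78 at
  d′ ≈ 1.5, in the range typically reported for healthy adults.
- **Response times**: log RT = a − b·|e| + Normal(0, s_rt), exponentiated
  and clipped to [200 ms, deadline]. The defaults a = 6.94, b = 0.22,
  s_rt = 0.25 are calibrated so the easy/difficult condition means come out
  near 823/878 ms, matching the published condition means of the paradigm
  (≈6% RT difference); the 200-ms floor keeps log RT finite and
  sub-deadline RTs physiological.
- **End-of-block choices**: P(choose A) = logistic((c̄_A − c̄_B)/τ), where
  c̄ is the block's mean ratings-scale confidence per task. The paradigm
  only measures these choices; a softmax over accumulated local confidence
  is our modelling choice of how they are produced, with temperature τ
  (default 0.5) controlling SPE sensitivity. A task with no responded
  trials in a block (possible only with misses) contributes the scale
  midpoint 3.5, i.e. no information.

Cohorts draw per-subject parameters from ranges around these defaults
(σ_p ∈ [9, 16], σ_m ∈ [0.2, 0.8], τ ∈ [0.3, 0.8], …); all randomness flows
from one `numpy` generator per subject, seeded as `[cohort_seed, index]`.

## Psychometric calibration

`fit_psychometric` maximizes the Bernoulli likelihood of accuracy under
`P(correct|Δ) = λ/2 + (1−λ)Φ(Δ/σ_f)` with Nelder-Mead over log σ_f,
multistarted from six log-spaced scales to avoid local optima. The lapse is
fixed at 0 by default — the calibration procedure we emulate did not
describe a lapse term — with an optional free lapse ≤ 0.1 (logit-bounded)
for robustness work. All-correct or all-error data leave σ_f unidentified;
the fit is returned pinned at a bound with `converged=False` rather than
raising. Inversion is closed-form, `Δ = σ_f·Φ⁻¹((p−λ/2)/(1−λ))`; extracted
levels are rounded to integers because stimuli are discrete square counts,
forced ≥ 1 and strictly ordered (a collision bumps the easy level up by
one). At the study's 200-trial calibration size the fitted σ_f has a
median relative error under 15% (measured in the test suite), which
translates into a 2–3 percentage-point spread in realized accuracy at the
extracted levels — visible in the acceptance computation, which therefore
averages 16 independent calibration loops.

## Meta-d′ and AUROC2

Ratings are tabulated into the standard 2K response-conditional count
vectors per stimulus class (K = 6), padded by 1/(2K) in every cell — the
common zero-count remedy that keeps z-scores and likelihoods finite; raw
counts are preserved alongside. Type-1 d′ and c come from
rating-collapsed hit/false-alarm rates.

`fit_metad` maximizes the multinomial likelihood of the
response-conditional rating counts under a meta-level Gaussian observer
with sensitivity meta-d′ whose type-1 criterion is held at the scaled
position c·(meta-d′/d′) — the dominant convention for this estimator. Free
parameters are meta-d′ and 2(K−1) type-2 criteria, kept ordered by
optimizing over log-increments outward from the scaled criterion
(L-BFGS-B, three deterministic starts). The tests verify the optimizer
against a profile-likelihood grid over meta-d′ (step 0.01) with an
independently coded likelihood, recovery of M-ratio = 1 ± 0.05 for a
σ_m = 0 observer at 10⁵ trials, and |bias| < 0.15 at the study's 200-trial
session size. The small negative bias of the estimate comes mostly from
cell padding.

AUROC2 sweeps the K−1 confidence thresholds over cumulative rating
distributions conditional on correct vs incorrect, with endpoints (0,0)
and (1,1) and trapezoidal integration; ties are absorbed by the cumulative
distributions (no random tie-breaking). All-correct or all-error input has
no type-2 ROC and returns NaN, which propagates through the per-condition
average as a flagged missing value. Both indices are computed per
difficulty level — SDT assumes constant stimulus strength — and averaged.

The 2×2 Accuracy × Difficulty ANOVA on trial-level confidence is
regression-formulated (statsmodels OLS + type-II table) so unbalanced
cells are handled; zero-variance confidence returns F = 0, p = 1 for every
effect rather than 0/0.

## Ordinal confidence model and transfer

The latent confidence model is a proportional-odds cumulative-link
regression, `P(rating ≤ k|x) = F(θ_k − x·β)`, fitted per subject on the
metacognition session by BFGS over (θ₁, log-increments of θ₂…θ₅, β), with
deterministic initialization from the empirical cumulative link-quantiles
and β = 0. The logit link is the default (probit behind a flag). Features
are difficulty (signed square-difference magnitude, larger = easier),
accuracy, log RT, and the product of the two z-scored components as the
interaction; z-scoring is always computed within the subject/session slice
being scored, so transferred coefficients are applied to comparably scaled
inputs (a switch allows reusing the fitting session's scaling instead).
Constant columns — e.g. accuracy in an all-correct slice — cannot be
z-scored and are dropped with a warning. Rating categories never observed
collapse onto their neighbour (duplicated cutpoints, flagged, zero
predicted mass). Complete separation is caught by a ridge (10⁻⁴) refit
with `converged=False`. The implementation agrees with statsmodels'
`OrderedModel` to 10⁻³ on shared problems (cross-checked in the tests) but
is kept in-package for the collapse/ridge/deterministic-init behavior the
pipeline relies on.

Predicted confidence on the unrated main session is the expected rating
`Σ_k k·P(rating = k|x)`, a continuous value in [1, 6] (the modal category
is available as an alternative). Candidate regressor sets — the default
grid is {acc}, {rt}, {diff}, their pairs, the triple, and the triple plus
interaction — are compared by deviance summed over subjects.

A note on what transfer can achieve: with σ_m > 0 a large share of rating
variance is meta-noise that no function of (difficulty, accuracy, RT) can
explain. Under the default observer the in-sample best linear predictor of
the true ratings tops out at r ≈ 0.5 on main-session data; the transferred
ordinal model reaches ≈99% of that ceiling, which is the property the test
suite asserts (transfer ≥ 90% of the in-test oracle ceiling) rather than
an absolute correlation.

## Global-SPE analyses

Exclusions drop missed trials and responded trials with |z(log RT)| > 3,
where the z-score uses each subject's responded-trial mean and SD computed
once (no re-iteration after removal; the criterion is scale-invariant, so
milliseconds are fine). Each main-session trial is labelled higher- or
lower-SPE according to whether its task was chosen at the end of its
block.

Choice frequencies: the easy-task choice frequency (identically, the SPE
sensitivity — the brain–behavior covariate of the original design) and the
best-performed-task frequency, the latter excluding accuracy-tied blocks
from its denominator with the tie count reported. Blocks are classed by
the realized easy-minus-difficult accuracy difference as positive / null /
negative — exact ties form the null class — and the easy-choice frequency
is split by class; group tests are one-sample t against 0.5 and paired t
between classes, with subjects lacking a class excluded from that test and
the n reported.

Task-choice logistic regressions code the outcome as "chose the
first-cued task" on first-minus-second signed difference predictors
(z-scored within subject), which makes coefficients sign-interpretable and
symmetric under task relabelling; the difficulty/accuracy model adds their
product. Single-predictor choice models (predicted confidence, accuracy,
log RT differences) are compared on deviance summed over subjects. The
logistic MLE is a small in-package helper (BFGS on the stable
log1p-exp likelihood) with a ridge (10⁻⁴) fallback under separation,
flagged per subject; it agrees with the brute-force −2Σ log p to 10⁻⁶.

The JZS Bayes factor for one-sample t tests uses the default Cauchy prior
(scale √2/2) on the standardized effect and evaluates the H₁ marginal by
adaptive quadrature over the inverse-gamma mixing variable; the tests
check it against a dense fixed-grid integral to 1%.

## Pipeline reproducibility and problem sizes

`run_pipeline` runs simulate → calibrate → re-simulate main/metacognition
at the extracted levels → metacognition metrics → confidence model →
transfer → SPE analyses, per subject, then the group stage. Reports are
JSON with sorted keys and a config digest (output location excluded), so
the same (config, seed) reproduces byte-identical artifacts; a single
subject yields a valid report with group tests flagged absent. Stage
failures abort with the stage name after persisting partial outputs.

Simulation sizes in the tests mirror the study (200-trial calibration and
metacognition sessions, 32×12 main sessions); replicate counts (e.g. 100
for the monotonicity of M-ratio/AUROC2 in σ_m, 40-subject cohorts for the
end-to-end signatures, 16 observers in the acceptance computation) were
chosen to keep Monte-Carlo error comfortably below the asserted margins.

## Limitations

The simulator is a stand-in for human subjects, not a model of them: it
has no sequential dependencies (no confidence leak, fatigue, or
post-error slowing), its confidence criteria are fixed within subject, the
miss process is independent of difficulty, and the softmax choice rule is
one hypothesis about how block choices arise — the paradigm it emulates
only measures them. Passing tests therefore establish that the estimators
recover known generative quantities and that the pipeline's qualitative
signatures (easy-task preference, confidence–SPE coupling, the deviance
ordering of choice models) follow from a confidence-driven chooser; they
do not validate those signatures in real data. Hierarchical (partial
pooling) estimation of meta-d′ and of the ordinal model is out of scope;
group summaries are means of per-subject point estimates.
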