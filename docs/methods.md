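# Methods

## Data model

A drug's record is its annual spontaneous ADR report counts on a
consecutive calendar-year grid. Counts are opaque annual totals as
exported by public dashboards; record-level deduplication is reduced to
summing duplicate (drug, year) rows, and interior year gaps are
zero-filled so the cumulative curve Y(t) is defined on a regular annual
grid. All fitting uses the 1-based time index t = 1..n (years since the
first observed year); the convention is applied uniformly by every fitter
so parameters such as α and t₀ are comparable across drugs.

## Error model and estimation

Errors are modelled as additive, homoscedastic Gaussian noise on the
cumulative scale — the assumption implicit in ordinary least-squares
curve fitting and Q–Q residual diagnostics. This is knowingly
approximate: cumulative counts are a running sum, so their residuals are
autocorrelated (see Limitations).

Family parameterizations and fitting routes:

* **linear** Y = a + b·t: closed-form OLS (statsmodels); t-based
  standard errors and 95% CIs with n − 2 df.
* **exponential** Y = α·e^(β·t): the default route regresses ln Y on t
  by OLS, giving β̂ and ln α̂. It is deterministic and *exactly*
  scale-invariant in β, which is why it is the default for the Detriment
  Index. Fit statistics are computed on the original count scale from
  Y − α̂·e^(β̂·t). Leading zero cumulative values are dropped (with a
  warning) before the log regression. An NLS route (least squares on the
  original scale, initialized from the log-linear solution) is available
  and is used internally by pattern classification (below).
* **saturation** Y = Y₀ + θ₁·t/(θ₂ + t) (shifted Michaelis–Menten, the
  baseline Y₀ absorbing a non-zero series start): scipy
  `least_squares`, initialized at Y₀ ← Y(1), θ₁ ← Y(n) − Y(1), θ₂ ←
  time at half-rise. θ̂₂ ≤ 0 or θ̂₁ < 0 flags the fit invalid rather
  than raising.
* **logistic** Y = L/(1 + e^(−k(t − t₀))), L a free third parameter:
  initialized at L ← 1.05·max Y, t₀ ← first time Y > L/2, k ← slope of
  the logit-linearised regression ln(Y/(L−Y)) on t. k̂ ≤ 0 flags the
  fit invalid.

Nonlinear solvers run with a 500-evaluation cap and 10⁻¹⁰ relative
tolerance on the cost; all starting rules are deterministic, so every fit
is bit-reproducible. Uncertainty for NLS parameters is asymptotic
(Jacobian-based covariance, t-quantile Wald intervals, n − p df);
bootstrap intervals are out of scope.

## Fit statistics

RSS = Σ(obs − fit)², RMSE = √(RSS/n), R² = 1 − RSS/TSS, and the
Gaussian profile-likelihood criteria

    AIC = n·ln(RSS/n) + 2p,     BIC = n·ln(RSS/n) + p·ln(n),

so BIC − AIC = p·(ln n − 2) identically. A fit whose RMSE is at
floating-point noise level relative to the data scale (RMSE ≤ 10⁻⁸ ·
max(1, max|Y|)) is treated as perfect: AIC/BIC take a −inf sentinel and
the fit carries a `perfect_fit` flag. A literal RSS = 0 test would be
meaningless under finite-precision OLS/NLS, which returns residuals of
order 10⁻¹⁴ on exact data.

## Pattern classification

All four families are fitted and the label is the family with minimal
AIC among valid fits. Two rules temper AIC's appetite for parameters:
if the top two candidates are within ΔAIC < 2 the family with fewer
parameters wins, and any remaining tie falls to the fixed precedence
linear < exponential < saturation < logistic. Multiple perfect fits
(−inf AIC, e.g. on a flat series) are treated as tied and resolved the
same way. For selection, the exponential family is fitted by NLS:
AIC values are only comparable when every family sits at its
least-squares optimum on the same scale, and the log-linear route
minimizes error in log space. Invalid fits (non-convergence, θ₂ ≤ 0,
k ≤ 0) exclude a family without failing the drug; with no valid fit the
label is `undetermined`. Labels are descriptive — no significance test
against β = 0 is attached.

## The Detriment Index

The Detriment Index is β itself, estimated by the log-linear route, with
a flat-series convention β = 0 (returned without fitting, avoiding
log(0) on all-zero curves). Ranking sorts ascending in β, ties sharing
the minimum rank: rank 1 = slowest accumulation = most favourable
profile. Because the log-linear β̂ is an OLS slope in log space,
multiplying a series by any positive constant shifts only the intercept:
the ranking is exactly invariant to per-drug rescaling, the property
that makes cross-drug comparison meaningful.

An experimental composite — β × (trapezoidal AUC of Y over t)/(n·max Y)
— is exposed behind an explicit flag for users who want accumulation
speed weighted by curve shape. The normalised AUC factor lies in (0, 1]
and is itself scale-invariant. The composite is exploratory, has no
published reference formula, and is never used for default ranking.

Exposure normalisation divides each annual count by that year's exposure
units (doses sold or a proxy) before cumulation, turning counts into
per-use rates; constant exposure leaves β unchanged, and downstream
fitting is mechanically identical.

## Simulator

The simulator inverts the four families: a deterministic curve F(t) plus
one of two noise models. `poisson_increments` (default for count data)
draws annual increments Poisson with mean ΔF(t), keeping series integer
and non-decreasing; `gaussian_cumulative` adds iid N(0, sd) on the
cumulative scale, clipped monotone, matching the fitters' error model.
An optional spike adds user-set mass to one annual increment, emulating
stimulated reporting after publicity or regulatory action (no canonical
magnitude exists, so none is defaulted). All randomness derives from the
spec's single seed.

What the generator does **not** emulate: under-reporting and reporting
delays, case-level duplication, term-level coding changes, exposure
drift, or drug–drug-interaction confounding. Passing recovery and
classification tests therefore demonstrate correctness of the estimation
machinery under the stated noise models, not robustness to the full
messiness of spontaneous-reporting data.

Study sizes: the validation suite uses 200 replicates per family at
n = 25 years for classification accuracy and 100–500 replicates for β
recovery at n = 30 — large enough that Monte-Carlo error is well below
the effects measured, small enough to keep the whole suite at about a
minute.

## Numerical and design choices

* AIC/BIC convention fixed to the n·ln(RSS/n) form; it is the one
  consistent with the published case-study statistics this package's
  fixtures derive from.
* Mid-range simulation defaults (linear a=50, b=120; exponential α=40,
  β=0.15; saturation Y₀=100, θ₁=4000, θ₂=3; logistic L=5000, k=0.6,
  t₀=10; n=25) give curves of realistic dashboard magnitude (10²–10⁴
  cumulative reports) with all shape features inside the observation
  window.
* Classification accuracy bounds were frozen from a one-time oracle
  pre-run (seed 20260923, 200 replicates/family): saturation and
  sigmoidal ≥ 0.90 observed at 1.00; linear and exponential bounds 0.60,
  observed 0.67 and 0.705 (see Limitations for why those two are lower).

## Limitations

* **Autocorrelated residuals.** Cumulative-count noise is a random walk,
  not iid; diagnostics report the lag-1 autocorrelation but the fits do
  not model it. Consequences: Wald CIs for β under-cover badly (about
  20–25% empirical coverage at nominal 95% in the Poisson recovery
  study) — β̂ itself remains nearly unbiased; and AIC comparisons are
  optimistic toward richer families.
* **Nested-family leakage.** Saturation-MM contains linear as a limit
  (θ₂ → ∞) and logistic contains exponential (t₀ → ∞). Under
  random-walk noise the nesting family's extra parameter beats the AIC
  penalty in roughly 30% of draws, so linear and exponential curves are
  mislabelled as their superset family at that rate. The leakage
  fraction is scale-free — amplifying counts 100-fold does not reduce
  it — so it is a property of AIC selection on cumulative curves, not of
  any parameter regime. Labels for those two families should be read
  jointly with ΔAIC.
* β compares *relative* accumulation speed; it says nothing about
  absolute burden, severity, or causality, and spontaneous-reporting
  biases (stimulated reporting, secular reporting trends) propagate into
  it unless exposure-normalised.
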