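# Methods

## Model and estimators

The package targets the Cox proportional hazards model
λ(t|X) = λ₀(t) exp(βᵀX) for right-censored observations
(Y_i, Δ_i, X_i), i = 1…n, with Y_i = min(T_i, C_i), Δ_i = I(T_i ≤ C_i), and
T_i ⫫ C_i given X_i. Estimation minimizes the weighted negative log partial
likelihood

ℓ_ω(β) = −(1/n) Σ_i ω_i Δ_i [βᵀX_i − log S_i(β)],

with risk sets {j : Y_j ≥ Y_i} in the Breslow convention (tied times share a
risk set; simulated times are continuous, so ties are measure-zero there,
but real data need the rule). Two forms of the risk-set sum S_i are
implemented:

- **weighted** (default): S_i = Σ_j ω_j I(Y_j ≥ Y_i) exp(βᵀX_j). Since
  E[ω_j] = 1, this is conditionally unbiased for the full-data sum, and the
  fit touches only the ω-positive subjects — the computational point of the
  method (O(r log r) per Newton step instead of O(n log n)).
- **full**: the unweighted sum over all n subjects. This keeps the outer
  sum subsampled but needs the whole dataset in every risk set; it is
  provided for comparison and for weight vectors that are not subsample
  indicators.

With ω ≡ 1 both coincide with the ordinary full-data objective.

**Subsampling.** δ_i ~ Bernoulli(π_n) i.i.d. with π_n = r/n selects an
expected r subjects; disturbances η_i are i.i.d. nonnegative with mean
1/π_n, either Geometric(π_n) on the support {1, 2, …} (number of trials —
the {0, 1, …} variant would have mean (1−π_n)/π_n, not 1/π_n) with variance
(1−π_n)/π_n², or Gamma(shape 1/π_n, scale 1) with variance 1/π_n. The fit
weights are ω_i = η_i δ_i, so E[ω_i] = 1 and
E[ω_i²] = 1 + 1/π_n. Averaging M independent draws yields
β̃_M = M⁻¹ Σ_m β̃_m; the per-replicate fits and weight realizations are kept
on the aggregate for diagnostics.

**Why this works at reduced n.** The estimator's variance is approximately
I⁻¹ (1 + 1/π_n)/n = I⁻¹ (1/n + 1/r), dominated by 1/r when r ≪ n. The
replication studies therefore run at n = 10⁵ rather than 10⁶ with
essentially unchanged dispersion; the package's documented desk scales are
n = 10⁵ / 200 replications for the study harness and n = 2·10⁴ for the test
suite's internal tables.

## Variance estimation

No closed-form variance is exposed by the weighting scheme itself, so the
package uses a score-residual sandwich Σ̂ = H̃⁻¹ Ĝ H̃⁻¹ with

- H̃ the per-unit-weight information: the objective's Hessian at β̃ rescaled
  by n/Σω. Normalizing by weight mass rather than row count makes H̃
  invariant to splitting a subject into duplicates with shared weight, and
  since Ĝ is normalized by (Σω)⁻², the rescalings cancel: the sandwich is
  identical to the row-count-normalized version.
- Ĝ = (Σω)⁻² Σ_i ω_i² Û_i Û_iᵀ, where Û_i is the Cox score residual:
  Δ_i (X_i − X̄(Y_i)) − exp(βᵀX_i) Σ_{events k: Y_k ≤ Y_i} ω_k (X_i − X̄(Y_k))/S_k,
  with X̄(t) the risk-weighted mean covariate. The ω² weighting captures the
  perturbation noise: E[ω²] = 1 + 1/π_n makes Σ̂ scale like 1/r, matching
  the estimator's actual dispersion, and at ω ≡ 1 the whole construction
  reduces to the standard robust covariance of the full-data fit.

The construction is validated empirically: the test suite checks that
nominal-95% Wald intervals cover at ~0.95 across the standard designs and
that the mean estimated SE tracks the empirical SD of the estimates within
20%.

Wald intervals use normal critical values (subsample sizes r ≥ 400 make the
normal/t distinction negligible). For β̃_M the sandwich is evaluated at β̃_M
with the final replicate's weights — conservative, since it ignores the
averaging gain — and the output is labelled accordingly. A
replicate-dispersion estimator (covariance of the M replicate estimates
divided by M) is available as a labelled diagnostic of the
perturbation-noise component only; it is never the default.

## Simulator

- Covariates: p = 5, mean zero, covariance Σ_ij = 0.5^|i−j|. The `normal`
  case is Gaussian; the `t10` case is multivariate t with ν = 10 degrees of
  freedom scaled by √((ν−2)/ν) so its covariance equals Σ exactly (a raw t
  with dispersion Σ has covariance Σ·ν/(ν−2)); it differs from the Gaussian
  case only in tail weight (excess kurtosis 1 per margin).
- Event times: T = −log(V)/(λ₀ exp(β₀ᵀX)), V ~ U(0,1) — inverse-transform
  sampling for a constant baseline hazard λ₀, default 1 (exponential
  baseline, the standard choice in this literature when the baseline is
  otherwise unspecified; exposed as `baseline_rate`).
- Censoring: C ~ Uniform(0, U) independent of T given X. U is resolved by
  calibration: given a Monte-Carlo sample of event times (default 10⁵), the
  expected censoring rate at bound U is mean_i min(T_i/U, 1), a smooth
  decreasing function of U on which Brent root-finding hits the target rate
  (default tolerance 0.005); the bracket is grown geometrically, any target
  in (0, 1) is reachable. The resolved U is recorded in all outputs.
- Defaults: β₀ = (−1, −0.5, 0, 0.5, 1), censoring targets 0.2 and 0.6 as
  the standard scenarios.

What the generator does **not** emulate: covariate-dependent or
non-uniform censoring, time-varying effects, ties in observed times,
model misspecification. Passing tests therefore demonstrate correctness of
the estimator and its inference under a correctly specified proportional
hazards model with independent uniform censoring — not robustness to
violations of those assumptions.

## Replication harness

Each replication draws a fresh dataset, one subsampling estimate (M = 1 by
default — the repeated variant is exposed but the standard tables use single
draws), the sandwich SE, and a 95% interval. Summaries per coefficient:

- **Bias** = mean *absolute* deviation from β₀. For an approximately
  unbiased, normally distributed estimator this is √(2/π) ≈ 0.798 times the
  SSE — a ratio the harness checks as an internal-consistency invariant.
  The signed mean deviation is emitted separately as `signed_bias`.
- **ESE** = mean of the estimated standard errors; **SSE** = sample SD
  (denominator n_reps − 1) of the estimates; **CP** = fraction of intervals
  covering β₀; **MSE** = mean squared Euclidean error over replications.

Failed replications (separation, zero-event subsample, non-convergence) are
excluded and counted; above 5% a warning is recorded in the table metadata.
Tables are written in tidy long format (coefficient, metric, value) with a
`# key=value` metadata header echoing the full resolved configuration;
`ReplicationTable.to_wide()` renders the conventional wide view.

## Numerical choices

- **Optimizer**: Newton with Armijo step-halving (c₁ = 10⁻⁴), zero-vector
  start, gradient max-norm tolerance 10⁻⁸, max 100 iterations, with ridge
  fallback on non-descent directions. Risk-set sums are reverse cumulative
  sums over time-sorted subjects with a global exp-shift for overflow
  safety.
- **Separation**: a monotone partial likelihood (e.g. the event with the
  uniformly smallest covariate) has no finite minimizer; it is detected
  when the iterates leave |β|_∞ ≤ 50 while the gradient is still above
  tolerance, and raised as an error rather than returned as a fit. Note the
  gradient decays exponentially along the monotone direction, so a
  separated fit with a *large* covariate gap can instead stop inside the
  box at a numerically flat point; the bound is configurable.
- **Zero-event subsamples** (possible at small r): redrawn once with the
  advancing RNG stream and logged; a second failure raises. Silent repeated
  redraws would bias small-r studies.
- **Degenerate risk sets**: a non-positive risk-set sum at a
  positive-weight event raises an error naming the event time (reachable
  only through exp underflow in weighted mode, since each event is in its
  own risk set).
- **RNG discipline**: a single seeded `numpy` Generator; within one
  subsample draw all n δ's are drawn before all n η's; repeated-draw
  replicates consume the stream replicate-major; the replication harness
  spawns one child stream for calibration and one per replication. All η's
  are drawn even in weighted mode (rather than only for selected subjects):
  the memory cost is negligible at the package's scales and it makes the
  weighted and full modes consume the stream identically, so a seed
  reproduces the same (δ, η, ω) in both modes. Every run is bit-for-bit
  reproducible from its seed.

## Known limitations

- No baseline hazard estimation, Efron ties, stratification, or
  time-varying covariates.
- The repeated-draw (M > 1) interval is conservative; a variance formula
  exploiting the averaging gain is not implemented.
- Optimal (A-/L-criterion) subsampling probabilities and uniform
  without-replacement subsampling are out of scope, as is distributed
  execution.
- The replicate-dispersion variance omits the data-sampling component by
  construction; it is a diagnostic, not an inferential tool.
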