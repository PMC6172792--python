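# Methods

## Model

Each genomic element contributes one short time series: estimated mean
abundances `y = (y_1, …, y_n)` at time points `t = (t_1, …, t_n)`, together
with fixed per-observation variances `v = (v_1, …, v_n)` produced upstream
(probabilistic transcript quantification, or the beta-binomial posterior
described below). Two Gaussian-process models compete:

* **Time-dependent model** — the latent temporal profile `f(t)` has a
  squared-exponential (RBF) prior,
  `k(t, t') = σ_f² · exp(−(t − t')² / (2ℓ²))`, and observations are
  `y_i = c + f(t_i) + ε_i` with `ε_i ~ N(0, σ_n² + v_i)`. Free
  hyper-parameters: length-scale `ℓ`, signal variance `σ_f²`, global noise
  variance `σ_n²`. The kernel matrix is the plain elementwise sum of the
  RBF, white-noise and fixed-variance components.
* **Null (time-independent) model** — observations are independent around
  a constant, `y_i = c + ε_i`, with the same noise distribution; the only
  free hyper-parameter is `σ_n²`.

Hyper-parameters are estimated by maximizing the log marginal likelihood
`log N(y − c·1 | 0, K)` (Cholesky factorization; analytic gradients
`∂L/∂θ = ½(αᵀ(∂K/∂θ)α − tr(K⁻¹ ∂K/∂θ))` with `α = K⁻¹(y − c·1)`). The
evidence for temporal activity is the natural-log Bayes factor

    ln BF = log ML(time-dependent) − log ML(null),

and elements are ranked by ln BF (descending, ties broken by id). Under
equal prior model probabilities the posterior probability of the
time-dependent model is `BF / (1 + BF)`; ln BF > 3 ("strong evidence",
posterior ≈ 0.953) is the default cut-off, overridable. Bayes factors are
not p-values and no multiple-testing correction is applied.

## The constant mean is profiled, not subtracted

The constant `c` is estimated at its maximum-likelihood value under each
model's own covariance, `c = (1ᵀK⁻¹y) / (1ᵀK⁻¹1)` (the GLS mean; under the
null this is the precision-weighted average with weights `1/(σ_n² + v_i)`).
Because `∂L/∂c = 0` at the profiled value, the envelope theorem keeps the
analytic kernel gradients exact.

This choice matters. Centering by the arithmetic mean — the obvious
alternative — is biased by exactly the observations the fixed variances
mark as unreliable: a few high-variance points drag the sample mean, and
the resulting shared offset error at the low-variance points is a smooth
signal that only the RBF model can absorb. In experiments with spiky
variance patterns this inflated the null false-positive rate severely
(and increasingly with spike size), inverting the very property the method
exists for. Profiling the constant removes the artifact: the constant is
estimated from the points the model actually trusts.

## Bounds

Two lower bounds keep the marginal-likelihood surface well-behaved on
short series and curb over-fitting:

* `ℓ ≥ min_i (t_{i+1} − t_i)` — the minimum sampling distance; the model
  may not postulate fluctuations faster than the sampling can resolve.
* `σ_n² ≥ min_i v_i` by default — the fixed variances act as a floor on
  the global noise variance. The aggregation rule is configurable
  (`noise_bound="mean"` uses the mean of `v`); `min` is the weakest bound
  consistent with treating the fixed variances as a noise floor, and it is
  applied identically to both models so the comparison stays fair. When
  every `v_i = 0` the bound degenerates; a floor of `1e-10 · var(y)`
  (1e-12 for a constant series) avoids an exactly singular covariance.

## Optimization

Parameters are optimized on a log scale relative to their bounds
(`log(ℓ − bound + ε)`, `log σ_f²`, `log(σ_n² − bound + ε)`, `ε = 1e-12`,
values clamped at the bound to absorb the ε slack), which enforces the
constraints smoothly. L-BFGS with analytic gradients runs from three
deterministic starts: `ℓ = span/2`, `σ_f² = var(y)`,
`σ_n² = max(bound, 0.1·var(y))`, with restarts scaling `ℓ` and `σ_f²` by
0.25 and 4. The best optimum over all restarts — including the evaluated
starting points themselves — is reported, with iteration counts and
convergence flags in the diagnostics. Convergence: gradient norm 1e-6 or
200 iterations. Fitting is fully deterministic, so collection runs are
reproducible and order-independent by construction. If a covariance is
numerically indefinite, jitter starting at `1e-8 · mean(diag)` escalates
tenfold up to `1e-2 · mean(diag)` before an error is raised.

`σ_f² = 0` is permitted (the time-dependent model then coincides with the
null — the nesting used by the matched-parameter consistency test); there
is no upper bound on `ℓ`, since long length-scales degrade gracefully
toward the constant model.

## Posterior predictions

Plots and exports use the posterior of the latent function (excluding
observation noise): mean `k_*ᵀK⁻¹(y − c) + c` and variance
`σ_f² − k_*ᵀK⁻¹k_*`, clipped at zero. Far from the data the prediction
reverts to the constant `c` with variance `σ_f²`. Shaded bands are ±2
posterior SD; observation error bars are ±2√v_i.

## Beta-binomial variances for Pool-seq

For pooled-sequencing allele counts, an allele count `x` out of depth `n_d`
updates a conjugate Beta(a, b) prior (uniform `a = b = 1` by default,
configurable) on the allele frequency. The posterior
Beta(x + a, n_d − x + b) supplies mean `(x + a)/(n_d + a + b)` and variance
`mean·(1 − mean)/(n_d + a + b + 1)` as the `(Y, V)` entries, so uneven
coverage translates directly into per-point uncertainty. Zero-depth cells
carry the prior moments and are flagged, never NaN. No overdispersion
beyond the conjugate model is estimated. RNA-seq mean/variance matrices
from probabilistic quantifiers are consumed as-is.

## Synthetic data

The generator emulates the canonical short, irregular design: ten samples
at `t = [0, 5, 10, 20, 40, 80, 160, 320, 640, 1280]` analysed on a
`log(5 + t)` axis (natural log; the transform compresses the geometric
tail so a stationary kernel is reasonable). Dynamic rows are draws from a
zero-mean RBF GP with `ℓ = 1.0`, `σ_f² = 4.0`, `σ_n² = 0.01` plus a
uniform(−2, 2) offset; null rows are the offset alone; both receive
heteroscedastic noise `N(0, σ_n² + v_i)` and the returned `V` holds the
true `v_i`. The fixed-variance regimes are `constant` (`v_i = 0.01`) and
`heteroscedastic` (`v_i = 4.0` — comparable to the signal variance,
mimicking time points with poor quantification — with probability 0.2,
else 0.01). The count generator squashes GP draws through the logistic on
the logit scale of a uniform(0.2, 0.8) base frequency, draws depths from
Poisson(mean 50, clipped to ≥1) and counts from Binomial(depth, freq).
All randomness derives from one integer seed through per-row
`SeedSequence` substreams, so collections are bit-reproducible and a row's
data does not depend on collection size.

What the generator does *not* emulate: biological replicates,
library-size/normalization effects, count overdispersion beyond binomial
sampling, correlation between elements, or non-stationary dynamics.
Passing tests therefore demonstrate the statistical machinery under its
own assumptions, not performance on any particular real data set.

## Problem sizes in the checks

The end-to-end checks run at: 1000 null elements for the type-I rate, 100
dynamic elements for power, 100 replicates of 50 equispaced points for
length-scale recovery, 20 repetitions of 100-element collections (10
dynamic) for the variance-incorporation comparison, and 100 random short
series (n ≤ 12) for the dense-algebra oracle and grid comparisons. These
sizes give stable medians and rates while keeping a full run in the
low minutes on one core.

## Known limitations

* Evidence is a ratio of *maximized* (not integrated) marginal
  likelihoods; with n ≈ 10 observations the ln BF > 3 rule is a calibrated
  convention, not an exact error rate.
* Each element is modelled independently; shared structure across elements
  (co-regulation, linkage) is ignored.
* The RBF kernel assumes stationary, smooth dynamics on the (transformed)
  time axis; the time transform is the user's modelling choice.
* The beta-binomial path assumes independent binomial sampling per time
  point; no pool-size or overdispersion correction.
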