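# Methods

## Model

The α-monotone inverse Weibull law is the distribution of
`T = X · Y^(1/α)` with `X ~ IW(β, σ)` (cdf `exp(−σ x^(−β))`, shape β > 0,
scale σ > 0) and `Y ~ U(0, 1)` independent, α > 0.  Equivalently, T is a
scale mixture: `T | Y=y ~ IW(β, σ y^(β/α))` with uniform mixing.  Closed
forms used throughout:

* density `f(t) = α σ^(−α/β) t^(α−1) γ(α/β+1, σ t^(−β))` with γ the lower
  incomplete gamma function;
* cdf `F(t) = exp(−σ t^(−β)) + (t/α) f(t)`; survival `S = 1 − F`; hazard
  `h = f/S`;
* moments `E[T^r] = σ^(r/β) α/(α+r) Γ(1 − r/β)`, existing iff `r < β` (the
  tail index is β, inherited from the IW factor);
* α-monotonicity: `d/dt log f(t) ≤ (α−1)/t` for all t > 0.

As α → ∞ the uniform factor degenerates at 1 and the law converges to
IW(β, σ); β = 1 and β = 2 give the α-monotone inverse exponential and
inverse Rayleigh submodels; Z = 1/T follows the slash-Weibull relative.

## Numerical evaluation

All density work happens in log space.  The only delicate primitive is
`log γ(a, x)`: it is computed as `lgamma(a) + log P(a, x)` (P the regularized
lower incomplete gamma), and when `P(a, x)` underflows (deep lower tail,
`x ≪ a`, reached for large α/β) it switches to the convergent series
`γ(a,x) = (x^a e^(−x)/a) Σ_k Π_{j≤k} x/(a+j)`, truncated at relative 1e−18.
The cdf adds `exp(−σ t^(−β))` and the log-space second term, clipping to
[0, 1]; t ≤ 0 maps to 0 by convention, while the pdf raises outside the
support except in the masked vectorized form used by the likelihood.

The quantile has no closed form and is found by Brent root-finding on the
cdf.  Because `T ≤ X` pathwise, the closed-form IW quantile at the same
probability is a valid upper bracket; the lower edge is halved geometrically
until it straddles.  The bracket plus machine-precision `rtol` gives
`|F(q) − p| ≤ 1e−10` across the tested parameter range.

Sampling follows the representation exactly: one seeded PCG64 generator
yields a uniform vector p (inverse-transformed through the IW quantile) and
then a uniform vector y, in that fixed order, so a fixed seed reproduces the
sequence bit for bit across platforms.

Structural identities are exposed as numerical oracles rather than assumed:
the scale-mixture quadrature (`mixture_pdf_oracle`, adaptive quadrature at
1e−12 tolerance) independently reconstructs the density; the
α-monotonicity check and the hazard characterization `f′/f = h′/h − h` use
central differences with relative step 1e−5 on log-scale grids, so their
expected residuals are ~1e−6 and ~1e−4 respectively.

## Estimation

* **ML** maximizes `lnL = 2n ln α − n ln β − n(α/β) ln σ + n ln Γ(α/β) +
  (α−1)Σ ln tᵢ + Σ ln P(α/β+1, σ tᵢ^(−β))`.  The public `neg_loglik` codes
  this expression term by term; the optimizer uses an independently coded
  `−Σ log f(tᵢ)` (the two agree to 1e−10, enforced by tests).  The score uses
  the analytic digamma terms, with the inner derivatives of the incomplete
  gamma composition — which have no closed form — taken by central
  differences (relative step 1e−6).
* **MPS** maximizes the mean log spacing `(1/(n+1)) Σ ln[F(t_(i+1)) −
  F(t_(i))]` with `F(t_(0)) ≡ 0`, `F(t_(n+1)) ≡ 1`.  Exact ties (present in
  the Kevlar 49 data: repeated 0.01, 0.02, ...) make spacings vanish; the
  Cheng–Amin correction substitutes the log density at the tied point and is
  on by default (toggleable).  This choice is load-bearing: without it the
  objective is −∞ on the Kevlar 49 data.
* **LS** minimizes `(1/n) Σ [F(t_(i)) − i/(n+1)]²`.

All three criteria are optimized over log-parameters (positivity for free)
by Nelder–Mead with tolerances 1e−9/1e−11 and a polish pass, from a
deterministic multistart: β₀ and σ₀ come from the closed-form IW
probability-plot regression of `ln(−ln F_emp)` on `ln t`, and α₀ ranges over
{0.5, 1, 2, 5} because the likelihood can be nearly flat in α.  Estimates
are kept at full precision and rounded to 4 decimals only for display.

Standard errors come from the observed information `J = −H(lnL)`, a
symmetrized central-difference Hessian on the natural scale (relative step
1e−4); the inverse gives the asymptotic covariance and Wald intervals.  The
baseline IW ML fit profiles out its scale (`σ̂(β) = n/Σ t^(−β)`) and
maximizes the one-dimensional profile in log β.

## Goodness of fit

KS, AD, and CvM are the classical one-sample EDF statistics evaluated at the
fitted cdf and reported without p-values (fitted-parameter statistics are
used for ranking only).  KS uses the two-sided supremum over both step edges
of the right-continuous empirical cdf; AD clips F to [1e−15, 1−1e−15] inside
its logarithms.  AICc = −2lnL + 2k + 2k(k+1)/(n−k−1) and BIC = −2lnL +
k ln n; the comparison table flags BIC gaps above 2.  A genuinely different
KS convention (max |F − i/(n+1)|, a plotting-position form) was evaluated
and rejected: the classical definition is the one consistent with the full
set of reference fits this package reproduces.

## Monte-Carlo estimator study

Eight built-in scenarios fix σ = 1 and take (α, β) in (0.8,0.5), (0.7,0.9),
(1.5,0.8), (0.9,1.7), (2.0,1.5), (1.7,2.5), (1.0,1.0), (2.0,2.0) — spanning
heavy to light tails.  At study scale the sample sizes are 100, 200, 300
with ⌊100000/n⌋ replications.  Within a replicate every method fits the same
sample (paired design, reducing comparison variance), and replicate streams
derive from the master seed through a counter scheme, so results are
bit-reproducible.  Variance uses the divisor-R convention, making
MSE = bias² + variance an exact identity.

Two deliberate design choices:

* **Simulation fits are single local searches started at the truth**, unlike
  the multistart used for data analysis.  The sampling-distribution question
  ("how do the estimators behave around the truth?") is answered by the
  local optimum in the truth's basin; a global multistart would instead
  chase the boundary ridge below whenever it dominates.
* **Non-identified fits are excluded, with reported counts.**  For
  heavy-tail scenarios at n = 100, an appreciable fraction of samples
  (roughly 5–10% in the heaviest scenario) carries no interior likelihood
  maximum: the profile in α increases monotonically toward the IW boundary
  α → ∞, because the sample is indistinguishable from a plain IW sample.
  Any convergent fit of such a sample reports an arbitrary, optimizer-
  dependent α̂.  A fit is therefore flagged non-identified when the fitted
  law lies within empirical-cdf resolution of its own IW limit,
  `sup_t |F_αIW(t; θ̂) − F_IW(t; β̂, σ̂)| < 1/(2√n)` — at that point the data
  cannot see α at all.  The exclusion rate is a property of the model at
  that (scenario, n), not of the optimizer, so it cannot be driven to zero
  by tuning; consumers should read the `kept`/`failed` counts alongside the
  bias/variance/MSE cells.  Conditionally on identification, the α̂
  distribution remains right-skewed at n = 100 in the heaviest scenarios,
  so its conditional bias is positive there.

Default replication counts in the test suite are reduced (tens to a couple
of hundred replicates; 200 for the smoke version of the study cell) to keep
runs fast; `scripts/acceptance.py` and `alphaiw simulate --all` run cells at
the full ⌊100000/n⌋ scale.

## What the synthetic data does and does not emulate

The generator draws exactly from the model (exact inverse-transform for the
IW factor, exact uniform power), so simulation studies here measure
estimator behavior under a correctly specified model with complete,
uncensored, i.i.d. samples.  Real reliability data bring censoring, rounding
ties (the Kevlar 49 values are rounded to two decimals — the MPS tie
correction exists precisely for this), covariates and possible model
misspecification; passing tests say nothing about robustness to those.

## Known limitations

* No censored-data likelihoods; complete samples only.
* No closed-form Hessian: standard errors rest on finite differences and can
  degrade if the fit sits near the non-identified IW ridge (σ̂'s interval on
  the Kevlar 373 data already shows the flat-likelihood width).
* Rival three/four-parameter IW extensions are not implemented; they enter
  comparisons only through the (name, cdf, loglik, k) plugin contract.
* Moments of order r ≥ β do not exist (β < 1 means no finite mean), so
  moment-based diagnostics are unavailable in the heaviest-tail settings.
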