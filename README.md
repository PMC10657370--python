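# alphaiw

**The α-monotone inverse Weibull (αIW) distribution for lifetime data under
stress: evaluation, simulation, estimation, and goodness of fit.**

## The model

The inverse Weibull (Fréchet) law, cdf `F_X(x) = exp(−σ x^(−β))`, is a
standard heavy-tailed model for component lifetimes, but its single shape
parameter often limits its fit. `alphaiw` implements a three-parameter
extension built from the stochastic representation

```
T = X · Y^(1/α),     X ~ IW(β, σ),  Y ~ U(0, 1)  independent,
```

which shortens the baseline lifetime `X` by a random uniform factor — a
natural picture of a component operating under stress, with `α > 0`
controlling how strongly.  The density has the closed incomplete-gamma form

```
f(t) = α σ^(−α/β) t^(α−1) γ(α/β + 1, σ t^(−β)),            t > 0,
F(t) = exp(−σ t^(−β)) + (t/α) f(t),
```

where `γ(a, x)` is the lower incomplete gamma function.  The density is
α-monotone (`d/dt log f(t) ≤ (α−1)/t`), arises equivalently as a scale
mixture of IW laws over a uniform scale factor, contains the α-monotone
inverse exponential (β = 1) and inverse Rayleigh (β = 2) as submodels, and
converges to the plain IW law as `α → ∞`.  The r-th moment is
`σ^(r/β) · α/(α+r) · Γ(1 − r/β)` for `r < β`.

The package provides:

* pdf/cdf/survival/hazard/quantile/moments, exact seeded sampling, and the
  law's structural identities as numerically checkable oracles
  (`alphaiw.distribution`);
* maximum likelihood, maximum product of spacings (with Cheng–Amin tie
  correction), and cdf least-squares estimation, with observed-information
  standard errors (`alphaiw.estimation`);
* KS / Anderson–Darling / Cramér–von Mises statistics, AICc/BIC, and a
  model-comparison table with a plugin contract for externally fitted rivals
  (`alphaiw.gof`);
* a Monte-Carlo estimator study over eight built-in parameter scenarios
  (`alphaiw.simulation`);
* the classical Kevlar 49/epoxy (n=101) and Kevlar 373/epoxy (n=76)
  stress-rupture data sets, embedded and checksum-verified
  (`alphaiw.datasets`);
* an `alphaiw` command-line tool (`fit`, `simulate`, `sample`, `gof`).

## Worked example

Fit the Kevlar 49/epoxy strand data by all three methods and compare with the
inverse-Weibull baseline:

```sh
$ alphaiw fit --dataset kevlar49 --method ml --method mps --method ls
# sample: kevlar49 (n=101)
  model  alpha   beta   sigma    loglik     aicc      bic     ks     ad    cvm  k   n
 aiw-ml 0.6976 2.9919  5.8426  -99.2187 204.6849 212.2828 0.0626 0.4058 0.0563  3 101
aiw-mps 0.6803 2.7262  4.9888  -99.3638      NaN      NaN 0.0564 0.4120 0.0616  3 101
 aiw-ls 0.6536 4.2615 19.5937 -100.8388      NaN      NaN 0.0523 0.4394 0.0436  3 101
  iw-ml    NaN 0.6132  0.4195 -132.4394 269.0013 274.1091 0.1880 6.0910 1.1054  2 101
```

The αIW fit beats the IW baseline on every criterion — the log-likelihood
gain is ~33 points for one extra parameter, and the BIC gap (~62, far above
the conventional significance threshold of 2) says the stress parameter α
earns its keep.  The smaller KS/AD/CvM values mean the fitted cdf tracks the
empirical cdf much more closely.

The same from Python, on the Kevlar 373 data:

```python
from alphaiw import datasets, fit

result = fit(datasets.load("kevlar373").sample, "ml")
print(result.to_json(indent=2))
# {
#   "method": "ml",
#   "alpha": 1.2569213901037255,
#   "beta": 2.818289458734321,
#   "sigma": 13.64924673345424,
#   "loglik": -120.09040238330657,
#   "converged": true,
#   ...
# }
```

`result.standard_errors` and `result.confidence_intervals()` expose the
asymptotic (observed-information) uncertainty of the estimates.

A small Monte-Carlo cell of the estimator study:

```sh
alphaiw simulate --scenario 1 --n 100 --reps 200 --seed 7 --out sim.csv
```

writes the long-format bias/variance/MSE summary per method and parameter,
with non-identified fits (samples carrying no information about α — see
`docs/methods.md`) excluded and counted.

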