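"""Point estimation of the aIW parameters by ML, MPS, and least squares.

Three classical criteria are supported:

ML
    Maximize the log-likelihood

        lnL = 2n ln(alpha) - n ln(beta) - n (alpha/beta) ln(sigma)
              + n ln Gamma(alpha/beta) + (alpha - 1) sum ln t_i
              + sum ln P(alpha/beta + 1, sigma t_i**-beta),

    with P the regularized lower incomplete gamma function (the gamma cdf with
    rate sigma applied to t**-beta).

MPS
    Maximize the mean log spacing (1/(n+1)) sum ln[F(t_(i+1)) - F(t_(i))] with
    the conventions F(t_(0)) = 0 and F(t_(n+1)) = 1.  Tied observations make a
    spacing vanish; the Cheng-Amin correction replaces the log of a tied
    spacing by the log density at the tied point (toggleable).

LS
    Minimize the mean squared deviation of the fitted cdf at the order
    statistics from the plotting positions i/(n+1).

All three criteria are optimized over log-parameters (positivity for free)
with a deterministic multistart: beta and sigma start from a closed-form IW
probability-plot regression, alpha from a small fixed grid, since the
likelihood can be nearly flat in alpha.  Asymptotic standard errors come from
the observed information (negative Hessian of lnL, numerical central
differences).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import optimize
from scipy.special import digamma, gammainc, gammaln

from .distribution import aiw_cdf, aiw_logpdf
from .params import AIWParams, Sample

__all__ = [
    "OptimizerOptions",
    "FitResult",
    "neg_loglik",
    "score",
    "mps_objective",
    "ls_objective",
    "fit",
    "observed_information",
    "standard_errors",
    "iw_regression_start",
]

Method = Literal["ml", "mps", "ls"]


@dataclass
class OptimizerOptions:
    """Controls for the deterministic multistart local optimization."""

    initial: Sequence[float] | Literal["auto"] = "auto"
    alpha_starts: Sequence[float] = (0.5, 1.0, 2.0, 5.0)
    xatol: float = 1e-9
    fatol: float = 1e-11
    max_evals: int = 8000
    polish: bool = True

    def __post_init__(self) -> None:
        if self.xatol <= 0 or self.fatol <= 0:
            raise ValueError("tolerances must be positive")
        if self.max_evals < 1:
            raise ValueError("max_evals must be >= 1")


@dataclass
class FitResult:
    params: AIWParams
    method: str
    objective: float          # lnL for ML; mean log spacing for MPS; LS criterion
    converged: bool
    n_evals: int
    standard_errors: tuple[float, float, float] | None = None
    covariance: np.ndarray | None = None
    message: str = ""

    def confidence_intervals(self, level: float = 0.95):
        """Wald intervals  theta_hat +/- z * se  from the observed information."""
        if self.standard_errors is None:
            raise ValueError("fit carries no standard errors")
        from scipy.stats import norm
        z = norm.ppf(0.5 + level / 2.0)
        est = self.params.as_array()
        se = np.asarray(self.standard_errors)
        return np.column_stack([est - z * se, est + z * se])

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "alpha": self.params.alpha,
            "beta": self.params.beta,
            "sigma": self.params.sigma,
            ("loglik" if self.method == "ml" else "objective"): self.objective,
            "converged": self.converged,
            "n_evals": self.n_evals,
        }
        if self.standard_errors is not None:
            d["se_alpha"], d["se_beta"], d["se_sigma"] = map(float, self.standard_errors)
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


# ---------------------------------------------------------------------------
# objectives


def neg_loglik(params: AIWParams, sample: Sample) -> float:
    """Negative log-likelihood, coded term by term from the lnL expression.

    Deliberately independent of :func:`alphaiw.distribution.aiw_logpdf` (the
    two agree to 1e-10; the unit tests enforce it).  Non-finite evaluations
    return +inf so optimizers can step across bad regions.
    """
    a, b, s = params.alpha, params.beta, params.sigma
    t = sample.values
    n = sample.n
    with np.errstate(divide="ignore"):
        g_terms = np.log(gammainc(a / b + 1.0, s * t ** (-b)))
    lnl = (2.0 * n * math.log(a) - n * math.log(b) - n * (a / b) * math.log(s)
           + n * gammaln(a / b) + (a - 1.0) * np.sum(np.log(t)) + np.sum(g_terms))
    return float(-lnl) if np.isfinite(lnl) else float("inf")


def _robust_nll(log_params: np.ndarray, t: np.ndarray) -> float:
    """Optimizer-facing -lnL over log-parameters, with underflow-safe log
    incomplete gamma (sum of aiw_logpdf)."""
    a, b, s = np.exp(log_params)
    if not np.isfinite(a * b * s) or a > 1e12:
        return float("inf")
    lp = aiw_logpdf(t, AIWParams(a, b, s), strict=False)
    total = np.sum(lp)
    return float(-total) if np.isfinite(total) else float("inf")


def score(params: AIWParams, sample: Sample, rel_step: float = 1e-6) -> np.ndarray:
    """Gradient of lnL in (alpha, beta, sigma).

    The digamma terms are analytic; the inner derivatives of the gamma-cdf
    composition G(t**-beta; alpha/beta + 1, sigma) with respect to each
    parameter have no closed form and are taken by central finite differences
    with a relative step of ``rel_step``.
    """
    a, b, s = params.alpha, params.beta, params.sigma
    t = sample.values
    n = sample.n

    def G(aa: float, bb: float, ss: float) -> np.ndarray:
        return gammainc(aa / bb + 1.0, ss * t ** (-bb))

    g0 = G(a, b, s)

    def dG(idx: int) -> np.ndarray:
        p = [a, b, s]
        h = rel_step * p[idx]
        hi, lo = list(p), list(p)
        hi[idx] += h
        lo[idx] -= h
        return (G(*hi) - G(*lo)) / (2.0 * h)

    d_alpha = (2.0 * n / a - (n / b) * math.log(s) + (n / b) * digamma(a / b)
               + np.sum(np.log(t)) + np.sum(dG(0) / g0))
    d_beta = (n * a / b ** 2 * math.log(s) - n / b - n * a / b ** 2 * digamma(a / b)
              + np.sum(dG(1) / g0))
    d_sigma = -n * a / (b * s) + np.sum(dG(2) / g0)
    return np.array([d_alpha, d_beta, d_sigma])


def mps_objective(params: AIWParams, sample: Sample, *,
                  tie_correction: bool = True) -> float:
    """Mean log spacing of the fitted cdf at the order statistics (maximize).

    Spacings use F(t_(0)) = 0 and F(t_(n+1)) = 1.  Exactly tied observations
    produce zero spacings; with ``tie_correction`` the log of each tied
    spacing is replaced by the log density at the tied point (Cheng-Amin),
    otherwise the objective is -inf in the presence of ties.
    """
    if sample.n < 2:
        raise ValueError("MPS needs at least 2 observations")
    ts = sample.sorted_values
    F = np.concatenate([[0.0], np.atleast_1d(aiw_cdf(ts, params)), [1.0]])
    d = np.diff(F)
    tied = np.concatenate([np.diff(ts) == 0.0, [False]])  # spacing i+1 vs i for i>=1
    tied = np.concatenate([[False], tied])                # align with d (n+1 spacings)
    with np.errstate(divide="ignore"):
        logs = np.log(d)
    if tie_correction and np.any(tied):
        logs[tied] = aiw_logpdf(np.concatenate([ts, [ts[-1]]])[tied], params,
                                strict=False)
    if not np.all(np.isfinite(logs)):
        return float("-inf")
    return float(np.mean(logs))


def ls_objective(params: AIWParams, sample: Sample) -> float:
    """Mean squared deviation of F(t_(i)) from plotting positions i/(n+1)
    (minimize)."""
    ts = sample.sorted_values
    n = sample.n
    F = np.atleast_1d(aiw_cdf(ts, params))
    pp = np.arange(1, n + 1) / (n + 1.0)
    return float(np.mean((F - pp) ** 2))


# ---------------------------------------------------------------------------
# fitting


def iw_regression_start(sample: Sample) -> tuple[float, float]:
    """Closed-form IW start (beta0, sigma0) from the probability-plot
    regression of ln(-ln F_emp) on ln t with F_emp = i/(n+1)."""
    ts = sample.sorted_values
    n = sample.n
    F = np.arange(1, n + 1) / (n + 1.0)
    slope, intercept = np.polyfit(np.log(ts), np.log(-np.log(F)), 1)
    beta0 = max(-slope, 1e-2)
    sigma0 = max(np.exp(intercept), 1e-6)
    return float(beta0), float(sigma0)


def _objective_for(method: Method, sample: Sample):
    t = sample.values
    if method == "ml":
        return lambda lp: _robust_nll(lp, t)
    if method == "mps":
        def f(lp):
            a, b, s = np.exp(lp)
            if not np.isfinite(a * b * s) or a > 1e12:
                return float("inf")
            v = mps_objective(AIWParams(a, b, s), sample)
            return -v if np.isfinite(v) else float("inf")
        return f
    if method == "ls":
        def f(lp):
            a, b, s = np.exp(lp)
            if not np.isfinite(a * b * s) or a > 1e12:
                return float("inf")
            return ls_objective(AIWParams(a, b, s), sample)
        return f
    raise ValueError(f"unknown method {method!r}")


_MIN_N = {"ml": 3, "mps": 2, "ls": 1}


def fit(sample: Sample, method: Method = "ml",
        options: OptimizerOptions | None = None, *,
        compute_se: bool | None = None) -> FitResult:
    """Fit the aIW distribution to a sample by ML, MPS, or LS.

    Runs a Nelder-Mead simplex over log-parameters from each multistart point
    and keeps the best optimum; for ML a derivative-free polish pass is run
    from the winner.  Re-running with identical inputs is bit-reproducible
    (the procedure is fully deterministic).
    """
    method = method.lower()  # type: ignore[assignment]
    if method not in _MIN_N:
        raise ValueError(f"method must be one of {tuple(_MIN_N)}, got {method!r}")
    if sample.n < _MIN_N[method]:
        raise ValueError(f"{method} fit needs at least {_MIN_N[method]} observations")
    opts = options or OptimizerOptions()
    objective = _objective_for(method, sample)

    if isinstance(opts.initial, str) and opts.initial == "auto":
        beta0, sigma0 = iw_regression_start(sample)
        starts = [np.log([a0, beta0, sigma0]) for a0 in opts.alpha_starts]
    else:
        init = np.asarray(opts.initial, dtype=float)
        if init.shape != (3,) or np.any(init <= 0):
            raise ValueError("initial values must be three positive reals")
        starts = [np.log(init)]

    best = None
    n_evals = 0
    for x0 in starts:
        res = optimize.minimize(
            objective, x0, method="Nelder-Mead",
            options=dict(xatol=opts.xatol, fatol=opts.fatol,
                         maxfev=opts.max_evals, maxiter=opts.max_evals))
        n_evals += res.nfev
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError(f"all {len(starts)} starts failed for method={method}")
    if opts.polish:
        res = optimize.minimize(
            objective, best.x, method="Nelder-Mead",
            options=dict(xatol=opts.xatol / 10, fatol=opts.fatol / 10,
                         maxfev=opts.max_evals))
        n_evals += res.nfev
        if np.isfinite(res.fun) and res.fun <= best.fun:
            best = res

    params = AIWParams(*np.exp(best.x))
    obj = -best.fun if method in ("ml", "mps") else best.fun

    se = cov = None
    if compute_se is None:
        compute_se = method == "ml"
    if compute_se and method == "ml":
        try:
            info = observed_information(params, sample)
            cov = np.linalg.inv(info)
            diag = np.diag(cov)
            if np.all(diag > 0):
                se = tuple(np.sqrt(diag))
        except np.linalg.LinAlgError:
            pass

    return FitResult(params=params, method=method, objective=float(obj),
                     converged=bool(best.success), n_evals=n_evals,
                     standard_errors=se, covariance=cov,
                     message=str(best.message))


def fit_iw(sample: Sample) -> tuple["IWParams", float]:
    """Baseline inverse-Weibull ML fit (profile likelihood).

    For fixed beta the scale maximizer is closed form, sigma_hat(beta) =
    n / sum(t**-beta); the remaining one-dimensional profile in log beta is
    maximized numerically.  Returns the fitted parameters and maximized lnL.
    """
    from .distribution import iw_logpdf
    from .params import IWParams

    t = sample.values
    n = sample.n

    def profile_nll(log_beta: float) -> float:
        b = math.exp(log_beta)
        s = n / np.sum(t ** (-b))
        return -float(np.sum(iw_logpdf(t, IWParams(b, s))))

    res = optimize.minimize_scalar(profile_nll, bounds=(-7.0, 7.0),
                                   method="bounded",
                                   options={"xatol": 1e-12})
    b = math.exp(res.x)
    s = n / float(np.sum(t ** (-b)))
    return IWParams(b, s), -res.fun


def observed_information(params: AIWParams, sample: Sample,
                         rel_step: float = 1e-4) -> np.ndarray:
    """Observed information J = -H(lnL), i.e. the Hessian of -lnL, by central
    second differences on the natural parameter scale (symmetrized)."""
    theta = params.as_array()
    h = rel_step * theta

    def f(v: np.ndarray) -> float:
        return neg_loglik(AIWParams(*v), sample)

    H = np.empty((3, 3))
    f0 = f(theta)
    for i in range(3):
        ei = np.zeros(3)
        ei[i] = h[i]
        H[i, i] = (f(theta + ei) - 2.0 * f0 + f(theta - ei)) / h[i] ** 2
        for j in range(i + 1, 3):
            ej = np.zeros(3)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(theta + ei + ej) - f(theta + ei - ej)
                - f(theta - ei + ej) + f(theta - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def standard_errors(params: AIWParams, sample: Sample) -> tuple[float, float, float]:
    """Asymptotic standard errors: sqrt of the diagonal of J**-1 at the ML fit."""
    info = observed_information(params, sample)
    cov = np.linalg.inv(info)
    diag = np.diag(cov)
    if np.any(diag <= 0):
        raise np.linalg.LinAlgError("observed information is not positive definite")
    return tuple(np.sqrt(diag))
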