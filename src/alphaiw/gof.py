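"""Goodness-of-fit statistics and information criteria for fitted lifetime models.

All three EDF statistics are the classical one-sample forms evaluated at a
*fitted* cdf (parameters estimated from the same data), reported without
p-values — they are used for ranking competing models, not for testing:

    KS   D_n  = max_i max( i/n - F(t_(i)),  F(t_(i)) - (i-1)/n )
    AD   A^2  = -n - (1/n) sum_i (2i-1) [ ln F(t_(i)) + ln(1 - F(t_(n+1-i))) ]
    CvM  W^2  = 1/(12n) + sum_i [ F(t_(i)) - (2i-1)/(2n) ]^2

Information criteria:

    AICc = -2 lnL + 2k + 2k(k+1)/(n-k-1)
    BIC  = -2 lnL + k ln n

``compare_models`` assembles one report row per model and annotates BIC
differences (a gap above 2 is conventionally taken as meaningful evidence).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .params import Sample

__all__ = [
    "GofReport",
    "ks_statistic",
    "ad_statistic",
    "cvm_statistic",
    "aicc",
    "bic",
    "gof_report",
    "compare_models",
]

_CLIP = 1e-15


def _fitted_cdf_at_order_stats(sample: Sample, cdf: Callable) -> np.ndarray:
    F = np.atleast_1d(np.asarray(cdf(sample.sorted_values), dtype=float))
    if F.shape != (sample.n,):
        raise ValueError("cdf callable must map the order statistics elementwise")
    return F


def ks_statistic(sample: Sample, cdf: Callable) -> float:
    """Two-sided Kolmogorov-Smirnov distance between the empirical cdf (right-
    continuous step convention) and the fitted cdf, over both step edges."""
    F = _fitted_cdf_at_order_stats(sample, cdf)
    n = sample.n
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - F)
    d_minus = np.max(F - (i - 1) / n)
    return float(max(d_plus, d_minus))


def ad_statistic(sample: Sample, cdf: Callable) -> float:
    """Anderson-Darling statistic; F values are clipped to machine-safe bounds
    before the logs."""
    F = np.clip(_fitted_cdf_at_order_stats(sample, cdf), _CLIP, 1.0 - _CLIP)
    n = sample.n
    i = np.arange(1, n + 1)
    return float(-n - np.mean((2 * i - 1) * (np.log(F) + np.log1p(-F[::-1]))))


def cvm_statistic(sample: Sample, cdf: Callable) -> float:
    """Cramer-von Mises statistic."""
    F = _fitted_cdf_at_order_stats(sample, cdf)
    n = sample.n
    i = np.arange(1, n + 1)
    return float(1.0 / (12.0 * n) + np.sum((F - (2 * i - 1) / (2.0 * n)) ** 2))


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike criterion; requires n > k + 1."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (needs n > k + 1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def bic(loglik: float, k: int, n: int) -> float:
    if n < 1:
        raise ValueError("n must be >= 1")
    return -2.0 * loglik + k * math.log(n)


@dataclass(frozen=True)
class GofReport:
    """One model's fit summary on one sample."""

    name: str
    loglik: float
    aicc: float
    bic: float
    ks: float
    ad: float
    cvm: float
    k: int
    n: int

    def as_row(self) -> dict:
        return {"model": self.name, "loglik": self.loglik, "aicc": self.aicc,
                "bic": self.bic, "ks": self.ks, "ad": self.ad, "cvm": self.cvm,
                "k": self.k, "n": self.n}


def gof_report(sample: Sample, name: str, cdf: Callable, loglik: float,
               k: int) -> GofReport:
    return GofReport(
        name=name, loglik=float(loglik),
        aicc=aicc(loglik, k, sample.n), bic=bic(loglik, k, sample.n),
        ks=ks_statistic(sample, cdf), ad=ad_statistic(sample, cdf),
        cvm=cvm_statistic(sample, cdf), k=k, n=sample.n)


def compare_models(sample: Sample,
                   fitted: Sequence[tuple[str, Callable, float, int]],
                   sort_by: str = "bic") -> pd.DataFrame:
    """Build a comparison table from (name, cdf, loglik, k) entries.

    Any externally fitted model can participate through this plugin contract;
    only its cdf callable, maximized log-likelihood and parameter count are
    needed.  The table carries a ``delta_bic`` column relative to the best
    model and flags gaps above 2 as significant.
    """
    if not fitted:
        raise ValueError("at least one fitted model is required")
    rows = [gof_report(sample, name, cdf, ll, k).as_row()
            for name, cdf, ll, k in fitted]
    df = pd.DataFrame(rows)
    if sort_by not in df.columns:
        raise ValueError(f"cannot sort by {sort_by!r}")
    ascending = sort_by != "loglik"
    df = df.sort_values(sort_by, ascending=ascending, kind="stable")
    df = df.reset_index(drop=True)
    df["delta_bic"] = df["bic"] - df["bic"].min()
    df["bic_significant"] = df["delta_bic"] > 2.0
    return df
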