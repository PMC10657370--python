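"""Parameter triples and sample container for the alpha-monotone inverse Weibull model.

The distribution of ``T = X * Y**(1/alpha)`` with ``X ~ IW(beta, sigma)`` and
``Y ~ U(0, 1)`` independent is abbreviated aIW throughout.  ``alpha`` is the
monotonicity ("stress") shape parameter, ``beta`` the baseline inverse-Weibull
shape and ``sigma`` its scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

__all__ = ["AIWParams", "IWParams", "Sample"]


def _check_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.isfinite(value) or value <= 0:
            raise ValueError(f"{name} must be a positive finite real, got {value!r}")


@dataclass(frozen=True)
class AIWParams:
    """The (alpha, beta, sigma) triple of the aIW law; all strictly positive."""

    alpha: float
    beta: float
    sigma: float

    def __post_init__(self) -> None:
        _check_positive(alpha=self.alpha, beta=self.beta, sigma=self.sigma)

    @classmethod
    def inverse_exponential(cls, alpha: float, sigma: float) -> "AIWParams":
        """alpha-monotone inverse exponential submodel (beta fixed at 1)."""
        return cls(alpha=alpha, beta=1.0, sigma=sigma)

    @classmethod
    def inverse_rayleigh(cls, alpha: float, sigma: float) -> "AIWParams":
        """alpha-monotone inverse Rayleigh submodel (beta fixed at 2)."""
        return cls(alpha=alpha, beta=2.0, sigma=sigma)

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.sigma], dtype=float)

    def iw_limit(self) -> "IWParams":
        """The IW(beta, sigma) law the aIW converges to as alpha -> infinity."""
        return IWParams(beta=self.beta, sigma=self.sigma)


@dataclass(frozen=True)
class IWParams:
    """Shape/scale pair of the baseline inverse Weibull (Frechet) law."""

    beta: float
    sigma: float

    def __post_init__(self) -> None:
        _check_positive(beta=self.beta, sigma=self.sigma)


class Sample:
    """An ordered collection of strictly positive observation times.

    Values are validated on construction and held immutably; ``sorted_values``
    exposes the order statistics ``t_(1) <= ... <= t_(n)`` (stable tie order).
    """

    __slots__ = ("_values", "_sorted")

    def __init__(self, values: Iterable[float]):
        arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                         dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("sample must be a non-empty 1-d sequence")
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            bad = np.flatnonzero(~np.isfinite(arr) | (arr <= 0))[0]
            raise ValueError(
                f"sample values must be strictly positive and finite; "
                f"entry {bad} is {arr[bad]!r}"
            )
        arr.flags.writeable = False
        self._values = arr
        srt = np.sort(arr, kind="stable")
        srt.flags.writeable = False
        self._sorted = srt

    @property
    def values(self) -> np.ndarray:
        return self._values

    @property
    def sorted_values(self) -> np.ndarray:
        return self._sorted

    @property
    def n(self) -> int:
        return int(self._values.size)

    def __len__(self) -> int:
        return self.n

    def __iter__(self):
        return iter(self._values)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Sample(n={self.n}, min={self._sorted[0]:g}, max={self._sorted[-1]:g})"
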