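"""Type-I censored samples and the sufficient statistics of the Chen likelihood.

Under type-I censoring, ``n`` items are put on test simultaneously and the
test stops at a fixed time ``tau``; only the ``r`` failures occurring at or
before ``tau`` are observed (``r`` is random).  With the shape parameter
``lam`` known, the censored Chen likelihood is an exponential family in the
scale ``theta`` with sufficient statistic

    T = sum_i exp(x_i**lam) + (n - r) * exp(tau**lam) - n,

through which every estimator in this package depends on the data.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "TypeICensoredSample",
    "SufficientStats",
    "censor",
    "stat_T",
    "stat_Tstar",
    "censored_loglike",
    "read_times",
]


@dataclass(frozen=True)
class TypeICensoredSample:
    """A type-I censored lifetime sample.

    Attributes
    ----------
    n : int
        Number of items put on test.
    tau : float
        Fixed censoring (termination) time, positive.
    failures : numpy.ndarray
        Observed failure times, sorted ascending, each in ``(0, tau]``.
        An observation exactly equal to ``tau`` counts as observed.
    """

    n: int
    tau: float
    failures: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not (self.tau > 0):
            raise ValueError("tau must be positive")
        f = np.sort(np.asarray(self.failures, dtype=float))
        if f.size > self.n:
            raise ValueError("more failures than items on test")
        if f.size and (f[0] <= 0 or f[-1] > self.tau):
            raise ValueError("failure times must lie in (0, tau]")
        object.__setattr__(self, "failures", f)

    @property
    def r(self) -> int:
        """Number of observed failures."""
        return int(self.failures.size)

    def sufficient_stats(self, lam: float) -> "SufficientStats":
        return stat_T(self, lam)


@dataclass(frozen=True)
class SufficientStats:
    """Sufficient statistic of the censored Chen likelihood for known shape.

    ``T`` is strictly positive for any sample with ``n >= 1`` and ``tau > 0``
    since every exponential term exceeds one.
    """

    r: int
    T: float
    lam: float

    def __post_init__(self) -> None:
        if self.r < 0:
            raise ValueError("r must be nonnegative")
        if not (self.T > 0):
            raise ValueError("T must be positive")
        if not (self.lam > 0):
            raise ValueError("lam must be positive")


def censor(times, tau: float) -> TypeICensoredSample:
    """Apply type-I censoring at time ``tau`` to a vector of lifetimes.

    Parameters
    ----------
    times : array_like
        Positive lifetimes of all ``n`` items (order irrelevant).
    tau : float
        Censoring time; failures with ``x <= tau`` are observed.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("times must be nonempty")
    if np.any(times <= 0):
        raise ValueError("all lifetimes must be positive")
    return TypeICensoredSample(n=times.size, tau=float(tau), failures=times[times <= tau])


def stat_T(sample: TypeICensoredSample, lam: float) -> SufficientStats:
    """Compute ``T = sum exp(x_i**lam) + (n-r)*exp(tau**lam) - n``."""
    if not (lam > 0):
        raise ValueError("lam must be positive")
    x = sample.failures
    T = float(np.exp(x**lam).sum() + (sample.n - sample.r) * np.exp(sample.tau**lam) - sample.n)
    return SufficientStats(r=sample.r, T=T, lam=float(lam))


def stat_Tstar(t: float, lam: float) -> float:
    """Reliability time-point statistic ``T* = exp(t**lam) - 1`` (zero iff t=0)."""
    if t < 0:
        raise ValueError("t must be nonnegative")
    if not (lam > 0):
        raise ValueError("lam must be positive")
    return float(np.expm1(float(t) ** lam))


def censored_loglike(sample: TypeICensoredSample, theta: float, lam: float) -> float:
    """Log-likelihood of a type-I censored Chen sample, up to an additive constant.

    The combinatorial prefactor ``n!/(n-r)!`` is constant in ``(theta, lam)``
    and dropped.  Returns

        r*log(theta) + r*log(lam) + sum((lam-1)*log x_i + x_i**lam) - T*theta.

    For ``r = 0`` only the ``-T*theta`` term remains (the likelihood is then
    flat in the shape-dependent part and the MLE of theta does not exist).
    """
    if not (theta > 0):
        raise ValueError("theta must be positive")
    st = stat_T(sample, lam)
    x = sample.failures
    v = float(((lam - 1.0) * np.log(x) + x**lam).sum()) if st.r else 0.0
    return st.r * (np.log(theta) + np.log(lam)) + v - st.T * theta


def read_times(path) -> np.ndarray:
    """Read a vector of positive lifetimes from a text/CSV file.

    Accepts one value per line or whitespace/comma separated fields.
    """
    text = Path(path).read_text()
    tokens = [tok for tok in re.split(r"[,\s]+", text.strip()) if tok]
    try:
        vals = np.array([float(tok) for tok in tokens])
    except ValueError as exc:
        raise ValueError(f"non-numeric value in {path}: {exc}") from None
    if vals.size == 0:
        raise ValueError(f"no values found in {path}")
    if np.any(vals <= 0):
        raise ValueError("all survival times must be positive")
    return vals
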