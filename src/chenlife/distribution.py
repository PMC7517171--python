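"""The Chen two-parameter bathtub-shaped lifetime distribution.

The distribution has cumulative distribution function

    F(x; theta, lambda) = 1 - exp(theta * (1 - exp(x**lambda))),   x > 0,

with scale parameter ``theta > 0`` and shape parameter ``lambda > 0``.  Its
hazard rate ``h(t) = theta * lambda * t**(lambda-1) * exp(t**lambda)`` is
bathtub-shaped (decreasing, then increasing) for ``lambda < 1`` and strictly
increasing for ``lambda >= 1``, which makes the family a standard parametric
model for lifetimes of organisms, patients and engineered components whose
failure risk is high early, low in mid-life and rising with age.

All quantities are evaluated on the log scale internally (``expm1``/``log1p``)
so that tail probabilities are accurate for small arguments and saturate
cleanly (survival -> 0, cdf -> 1) instead of overflowing when ``x**lambda``
exceeds the floating-point exponent range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ChenParams", "Chen"]


@dataclass(frozen=True)
class ChenParams:
    """Parameter pair (theta, lam) of the Chen distribution.

    Parameters
    ----------
    theta : float
        Scale parameter, must be positive.
    lam : float
        Shape parameter, must be positive.  ``lam < 1`` gives a
        bathtub-shaped hazard, ``lam >= 1`` an increasing hazard.
    """

    theta: float
    lam: float

    def __post_init__(self) -> None:
        if not (self.theta > 0.0) or not np.isfinite(self.theta):
            raise ValueError(f"theta must be a positive finite real, got {self.theta}")
        if not (self.lam > 0.0) or not np.isfinite(self.lam):
            raise ValueError(f"lam must be a positive finite real, got {self.lam}")


class Chen:
    """Frozen Chen distribution with fixed ``(theta, lam)``.

    Parameters
    ----------
    theta, lam : float
        Positive scale and shape parameters.

    Examples
    --------
    >>> d = Chen(theta=0.4, lam=0.8)
    >>> round(float(d.cdf(1.5)), 3)
    0.697
    """

    def __init__(self, theta: float, lam: float) -> None:
        self._params = ChenParams(float(theta), float(lam))

    @property
    def params(self) -> ChenParams:
        return self._params

    @property
    def theta(self) -> float:
        return self._params.theta

    @property
    def lam(self) -> float:
        return self._params.lam

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Chen(theta={self.theta!r}, lam={self.lam!r})"

    # ------------------------------------------------------------------
    # internal helpers
    # ------------------------------------------------------------------
    def _check_nonneg(self, x, name: str = "x") -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if np.any(x < 0):
            raise ValueError(f"{name} must be nonnegative")
        return x

    def _check_support(self, x, name: str = "t") -> np.ndarray:
        """Validate the argument of pdf/hazard, which are singular at 0 for lam<1."""
        x = self._check_nonneg(x, name)
        if self.lam < 1.0 and np.any(x == 0):
            raise ValueError(
                f"{name}=0 is a singular point of the density/hazard when lam < 1"
            )
        return x

    # ------------------------------------------------------------------
    # distribution functions
    # ------------------------------------------------------------------
    def logsf(self, t) -> np.ndarray:
        """Log survival function, ``theta * (1 - exp(t**lam))``."""
        t = self._check_nonneg(t, "t")
        with np.errstate(over="ignore"):
            return -self.theta * np.expm1(t**self.lam)

    def sf(self, t) -> np.ndarray:
        """Survival (reliability) function ``R(t) = exp(theta*(1 - exp(t**lam)))``."""
        return np.exp(self.logsf(t))

    def cdf(self, x) -> np.ndarray:
        """Cumulative distribution function ``F(x) = 1 - R(x)``."""
        return -np.expm1(self.logsf(x))

    def logpdf(self, x) -> np.ndarray:
        x = self._check_support(x, "x")
        th, lam = self.theta, self.lam
        with np.errstate(over="ignore", divide="ignore"):
            xl = x**lam
            return (
                np.log(th)
                + np.log(lam)
                + (lam - 1.0) * np.log(x)
                + xl
                - th * np.expm1(xl)
            )

    def pdf(self, x) -> np.ndarray:
        """Density ``f(x) = theta*lam*x**(lam-1) * exp(x**lam + theta*(1-exp(x**lam)))``."""
        return np.exp(self.logpdf(x))

    def hazard(self, t) -> np.ndarray:
        """Hazard rate ``h(t) = theta*lam*t**(lam-1) * exp(t**lam)``."""
        t = self._check_support(t, "t")
        th, lam = self.theta, self.lam
        with np.errstate(over="ignore", divide="ignore"):
            return th * lam * t ** (lam - 1.0) * np.exp(t**lam)

    def ppf(self, u) -> np.ndarray:
        """Quantile function, the inverse of :meth:`cdf`.

        ``ppf(u) = (log(1 - log(1-u)/theta))**(1/lam)`` for ``0 <= u < 1``.
        """
        u = np.asarray(u, dtype=float)
        if np.any((u < 0) | (u >= 1)):
            raise ValueError("u must lie in [0, 1)")
        return np.log1p(-np.log1p(-u) / self.theta) ** (1.0 / self.lam)

    def rvs(self, size: int, rng=None) -> np.ndarray:
        """Draw ``size`` i.i.d. lifetimes by inverse-transform sampling.

        Parameters
        ----------
        size : int
            Number of draws, at least 1.
        rng : int, numpy.random.Generator or None
            Seed or generator.  All randomness in the package is threaded
            through explicit generators; there is no global RNG state.
        """
        if size < 1:
            raise ValueError("size must be >= 1")
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        return self.ppf(rng.uniform(size=size))
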