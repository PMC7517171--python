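"""Model / results interface for Chen lifetime estimation.

Two model classes in the statsmodels idiom:

* :class:`ChenComplete` — complete (uncensored) sample; ``fit()`` returns the
  joint profile-likelihood MLE of ``(theta, lam)``.
* :class:`ChenTypeICensored` — type-I censored sample with known shape
  ``lam``; ``fit()`` gives the MLE of ``theta``, ``fit_bayes()`` the BSEL
  Bayes estimator under a Gamma prior, and ``fit_ebayes()`` the E-Bayesian
  estimator under a hyper-prior family.  Each results object carries the
  point estimate together with method-consistent reliability and hazard
  estimators and a ``summary()`` table.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import estimators as est
from .censoring import SufficientStats, TypeICensoredSample, censor, censored_loglike
from .distribution import Chen, ChenParams

__all__ = [
    "ChenComplete",
    "ChenCompleteResults",
    "ChenTypeICensored",
    "ChenCensoredResults",
    "estimate_table",
]


class ChenComplete:
    """Complete-sample Chen lifetime model.

    Parameters
    ----------
    endog : array_like
        Positive observed lifetimes (no censoring).
    """

    def __init__(self, endog) -> None:
        self.endog = np.asarray(endog, dtype=float)
        if self.endog.size < 2:
            raise ValueError("need at least two observations")
        if np.any(self.endog <= 0):
            raise ValueError("lifetimes must be positive")

    @property
    def nobs(self) -> int:
        return self.endog.size

    def loglike(self, params: ChenParams) -> float:
        """Complete-data log-likelihood (sum of log densities)."""
        return float(Chen(params.theta, params.lam).logpdf(self.endog).sum())

    def fit(self, lam_bounds=(1e-3, 10.0)) -> "ChenCompleteResults":
        params = est.complete_data_mle(self.endog, lam_bounds=lam_bounds)
        return ChenCompleteResults(self, params)


class ChenCompleteResults:
    """MLE fit of a complete Chen sample."""

    def __init__(self, model: ChenComplete, params: ChenParams) -> None:
        self.model = model
        self.params = params
        self.llf = model.loglike(params)

    @property
    def distribution(self) -> Chen:
        """The fitted Chen distribution (for plug-in reliability/hazard)."""
        return Chen(self.params.theta, self.params.lam)

    def reliability(self, t) -> np.ndarray:
        return self.distribution.sf(t)

    def hazard(self, t) -> np.ndarray:
        return self.distribution.hazard(t)

    def summary(self) -> str:
        p = self.params
        lines = [
            "Chen complete-data maximum likelihood",
            "=" * 42,
            f"nobs:            {self.model.nobs}",
            f"theta (scale):   {p.theta:.6g}",
            f"lambda (shape):  {p.lam:.6g}",
            f"log-likelihood:  {self.llf:.4f}",
            f"hazard shape:    {'bathtub' if p.lam < 1 else 'increasing'}",
        ]
        return "\n".join(lines)


class ChenTypeICensored:
    """Type-I censored Chen lifetime model with known shape parameter.

    Parameters
    ----------
    endog : array_like
        The full vector of ``n`` lifetimes; censoring at ``tau`` is applied
        internally (observations above ``tau`` contribute only through the
        censored-likelihood term).
    tau : float
        Fixed censoring time.
    lam : float
        Known shape parameter (e.g. fixed at a complete-data MLE).

    Use :meth:`from_censored` when only the observed failures and ``n``
    are available.
    """

    def __init__(self, endog, tau: float, lam: float) -> None:
        self.sample = censor(endog, tau)
        self._init_lam(lam)

    def _init_lam(self, lam: float) -> None:
        if not (lam > 0):
            raise ValueError("lam must be positive")
        self.lam = float(lam)
        self.stats: SufficientStats = self.sample.sufficient_stats(self.lam)

    @classmethod
    def from_censored(cls, failures, n: int, tau: float, lam: float) -> "ChenTypeICensored":
        obj = cls.__new__(cls)
        obj.sample = TypeICensoredSample(n=n, tau=float(tau), failures=np.asarray(failures, float))
        obj._init_lam(lam)
        return obj

    @property
    def nobs(self) -> int:
        return self.sample.n

    def loglike(self, theta: float) -> float:
        """Censored log-likelihood at (theta, lam), up to a constant."""
        return censored_loglike(self.sample, theta, self.lam)

    def fit(self) -> "ChenCensoredResults":
        """Maximum-likelihood fit; requires at least one observed failure."""
        theta = est.mle_theta(self.stats)
        return ChenCensoredResults(self, "MLE", theta)

    def fit_bayes(self, prior: est.GammaPrior, omega: float = 0.0) -> "ChenCensoredResults":
        """BSEL Bayes fit with a Gamma(a, b) prior and anchor weight omega."""
        theta = est.bayes_theta(self.stats, prior, omega)
        return ChenCensoredResults(self, "BS", theta, prior=prior, omega=omega)

    def fit_ebayes(self, hyper: est.HyperPrior, omega: float = 0.0) -> "ChenCensoredResults":
        """E-Bayesian fit under the hyper-prior family in ``hyper``."""
        theta = est.ebayes_theta(self.stats, hyper, omega)
        label = {"pi1": "EBS1", "pi2": "EBS2", "pi3": "EBS3"}[hyper.family]
        return ChenCensoredResults(self, label, theta, hyper=hyper, omega=omega)


class ChenCensoredResults:
    """Results of a censored-sample fit.

    ``theta`` is the point estimate of the scale parameter under the chosen
    method; :meth:`reliability` and :meth:`hazard` evaluate the
    method-consistent estimators of R(t) and h(t) (which for Bayes and
    E-Bayes are *not* plug-ins of ``theta``).
    """

    def __init__(
        self,
        model: ChenTypeICensored,
        method: str,
        theta: float,
        prior: Optional[est.GammaPrior] = None,
        hyper: Optional[est.HyperPrior] = None,
        omega: float = 0.0,
    ) -> None:
        self.model = model
        self.method = method
        self.theta = float(theta)
        self.prior = prior
        self.hyper = hyper
        self.omega = float(omega)

    @property
    def stats(self) -> SufficientStats:
        return self.model.stats

    def reliability(self, t: float) -> float:
        if self.method == "MLE":
            return est.mle_reliability(self.stats, t)
        if self.prior is not None:
            return est.bayes_reliability(self.stats, t, self.prior, self.omega)
        return est.ebayes_reliability(self.stats, t, self.hyper, self.omega)

    def hazard(self, t: float) -> float:
        if self.method == "MLE":
            return est.mle_hazard(self.stats, t)
        if self.prior is not None:
            return est.bayes_hazard(self.stats, t, self.prior, self.omega)
        return est.ebayes_hazard(self.stats, t, self.hyper, self.omega)

    def summary(self, t: Optional[float] = None) -> str:
        s = self.model.sample
        lines = [
            f"Chen type-I censored estimation — {self.method}",
            "=" * 46,
            f"n on test:       {s.n}",
            f"observed r:      {s.r}",
            f"tau:             {s.tau:.6g}",
            f"lambda (known):  {self.model.lam:.6g}",
            f"T statistic:     {self.stats.T:.6g}",
        ]
        if self.prior is not None:
            lines.append(f"prior:           Gamma(a={self.prior.a}, b={self.prior.b})")
        if self.hyper is not None:
            h = self.hyper
            lines.append(f"hyper-prior:     {h.family}(s={h.s}, u={h.u}, v={h.v})")
        if self.prior is not None or self.hyper is not None:
            lines.append(f"BSEL omega:      {self.omega}")
        lines.append(f"theta estimate:  {self.theta:.6g}")
        if t is not None:
            lines.append(f"R({t:g}) estimate: {self.reliability(t):.6g}")
            lines.append(f"h({t:g}) estimate: {self.hazard(t):.6g}")
        return "\n".join(lines)


def estimate_table(
    model: ChenTypeICensored,
    eval_time: float,
    prior: est.GammaPrior,
    hyper_s: float = 0.5,
    hyper_u: float = 0.5,
    hyper_v: float = 0.5,
    omega: float = 0.0,
) -> pd.DataFrame:
    """All point estimates of theta, R(t) and h(t) for every method.

    Returns a DataFrame with rows ``theta``, ``R``, ``h`` and columns
    ``MLE, BS, EBS1, EBS2, EBS3``.
    """
    fits: Sequence[ChenCensoredResults] = [
        model.fit(),
        model.fit_bayes(prior, omega),
        *[
            model.fit_ebayes(est.HyperPrior(hyper_s, hyper_u, hyper_v, fam), omega)
            for fam in est.HYPER_FAMILIES
        ],
    ]
    data = {
        f.method: [f.theta, f.reliability(eval_time), f.hazard(eval_time)] for f in fits
    }
    return pd.DataFrame(data, index=["theta", "R", "h"])
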