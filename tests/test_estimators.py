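"""MLE, BSEL-Bayes and E-Bayes estimators: limits, oracles, propositions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, special

from chenlife import (
    Chen,
    GammaPrior,
    HyperPrior,
    SufficientStats,
    bayes_hazard,
    bayes_reliability,
    bayes_theta,
    complete_data_mle,
    ebayes_hazard,
    ebayes_reliability,
    ebayes_theta,
    mle_hazard,
    mle_reliability,
    mle_theta,
)
from chenlife.estimators import hazard_prefactor, kummer_m

STATS = SufficientStats(r=3, T=5.766338, lam=1.0)


def make_hyper(s, u=0.5, v=0.5):
    return {fam: HyperPrior(s, u, v, fam) for fam in ("pi1", "pi2", "pi3")}


class TestMLE:
    def test_point_estimate_is_r_over_T(self):
        assert mle_theta(STATS) == pytest.approx(3 / 5.766338, rel=1e-14)

    def test_r_zero_raises(self):
        bad = SufficientStats(r=0, T=2.0, lam=1.0)
        with pytest.raises(ValueError, match="r = 0"):
            mle_theta(bad)

    def test_plug_in_reliability_and_hazard(self):
        th = mle_theta(STATS)
        assert mle_reliability(STATS, 0.0) == 1.0
        assert mle_reliability(STATS, 0.5) == pytest.approx(float(Chen(th, 1.0).sf(0.5)))
        assert mle_hazard(STATS, 0.5) == pytest.approx(hazard_prefactor(0.5, 1.0) * th)


class TestCompleteDataMLE:
    def test_parameter_recovery_on_simulated_data(self):
        x = Chen(0.4, 0.8).rvs(5000, rng=11)
        p = complete_data_mle(x)
        assert p.theta == pytest.approx(0.4, abs=0.05)
        assert p.lam == pytest.approx(0.8, abs=0.05)

    def test_profile_stationarity_identity(self, graft_times, complete_fit):
        p = complete_fit.params
        n = graft_times.size
        assert p.theta == pytest.approx(n / np.expm1(graft_times**p.lam).sum(), rel=1e-12)

    def test_rejects_degenerate_input(self):
        with pytest.raises(ValueError):
            complete_data_mle([1.0])
        with pytest.raises(ValueError):
            complete_data_mle([1.0, -1.0])


class TestBayes:
    def test_limits(self):
        prior = GammaPrior(0.3, 0.2)
        ml = mle_theta(STATS)
        assert bayes_theta(STATS, prior, omega=1 - 1e-12) == pytest.approx(ml, rel=1e-9)
        tiny = GammaPrior(1e-10, 1e-10)
        assert bayes_theta(STATS, tiny, omega=0.0) == pytest.approx(ml, rel=1e-9)

    def test_convex_combination_bounds(self):
        prior = GammaPrior(0.5, 0.1)
        ml = mle_theta(STATS)
        pm = (STATS.r + prior.a) / (prior.b + STATS.T)
        val = bayes_theta(STATS, prior, omega=0.3)
        lo, hi = sorted([ml, pm])
        assert lo < val < hi

    def test_posterior_mean_monte_carlo_oracle(self):
        prior = GammaPrior(0.7, 0.4)
        n = 1_000_000
        draws = np.random.default_rng(2).gamma(STATS.r + prior.a, 1 / (prior.b + STATS.T), n)
        se = draws.std() / np.sqrt(n)
        assert bayes_theta(STATS, prior, omega=0.0) == pytest.approx(draws.mean(), abs=4 * se)

    def test_reliability_posterior_expectation_oracle(self):
        prior = GammaPrior(0.7, 0.4)
        t, lam = 0.5, STATS.lam
        Tstar = np.expm1(t**lam)
        n = 1_000_000
        draws = np.random.default_rng(3).gamma(STATS.r + prior.a, 1 / (prior.b + STATS.T), n)
        vals = np.exp(-draws * Tstar)
        se = vals.std() / np.sqrt(n)
        assert bayes_reliability(STATS, t, prior, omega=0.0) == pytest.approx(
            vals.mean(), abs=4 * se
        )

    def test_reliability_at_zero_is_one(self):
        assert bayes_reliability(STATS, 0.0, GammaPrior(0.2, 0.2), omega=0.4) == 1.0

    def test_hazard_factorization(self):
        prior = GammaPrior(0.2, 0.3)
        for om in (0.0, 0.3, 0.9):
            assert bayes_hazard(STATS, 0.7, prior, om) == pytest.approx(
                hazard_prefactor(0.7, STATS.lam) * bayes_theta(STATS, prior, om), rel=1e-14
            )

    def test_large_r_hazard_ratio_tends_to_one(self):
        prior = GammaPrior(0.5, 0.5)
        big = SufficientStats(r=5000, T=9000.0, lam=0.8)
        ratio = bayes_hazard(big, 0.5, prior, 0.0) / mle_hazard(big, 0.5)
        assert ratio == pytest.approx(1.0, abs=2e-3)

    def test_informative_prior_warns(self):
        with pytest.warns(UserWarning, match="decreasing"):
            GammaPrior(2.0, 1.0)

    def test_anchor_requires_failures(self):
        bad = SufficientStats(r=0, T=2.0, lam=1.0)
        with pytest.raises(ValueError):
            bayes_theta(bad, GammaPrior(0.5, 0.5), omega=0.3)
        # posterior-only estimate exists at omega=0
        assert bayes_theta(bad, GammaPrior(0.5, 0.5), omega=0.0) > 0


class TestKummer:
    def test_beta_average_identity(self):
        """M(u, u+v; c) equals the Beta(u, v) average of exp(c*a)."""
        rng = np.random.default_rng(4)
        for _ in range(5):
            u, v = rng.uniform(0.2, 3, size=2)
            for c in np.linspace(-5, 0, 11):
                oracle, _ = integrate.quad(
                    lambda a: np.exp(c * a),
                    0, 1,
                    weight="alg", wvar=(u - 1.0, v - 1.0),
                )
                oracle /= special.beta(u, v)
                assert float(kummer_m(u, u + v, c)) == pytest.approx(oracle, rel=1e-10)


class TestEBayesTheta:
    def test_midpoint_identity_exact(self):
        hp = make_hyper(s=0.5)
        e = {f: ebayes_theta(STATS, hp[f], omega=0.3) for f in hp}
        assert e["pi1"] == pytest.approx((e["pi2"] + e["pi3"]) / 2, rel=1e-14)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        r=st.integers(1, 60),
        T=st.floats(1.0, 200.0),
        s_frac=st.floats(0.05, 0.95),
        u=st.floats(0.1, 3.0),
        v=st.floats(0.1, 3.0),
        omega=st.floats(0.0, 0.95),
    )
    def test_ordering_pi3_below_pi1_below_pi2(self, r, T, s_frac, u, v, omega):
        """For 0 < s < T the b-increasing family pi3 shrinks theta hardest.

        Larger b inflates the posterior rate b+T, so weighting large b
        (pi3) lowers the estimate and weighting small b (pi2) raises it.
        """
        stats = SufficientStats(r=r, T=T, lam=1.0)
        hp = make_hyper(s=s_frac * T, u=u, v=v)
        e = {f: ebayes_theta(stats, hp[f], omega=omega) for f in hp}
        assert e["pi3"] < e["pi1"] < e["pi2"]
        assert e["pi1"] == pytest.approx((e["pi2"] + e["pi3"]) / 2, rel=1e-12)

    def test_families_converge_as_T_grows(self):
        hp = make_hyper(s=0.5)
        spread = []
        for T in (5.0, 50.0):
            stats = SufficientStats(r=3, T=T, lam=1.0)
            e = [ebayes_theta(stats, hp[f], omega=0.0) for f in ("pi1", "pi2", "pi3")]
            spread.append(max(e) - min(e))
        assert spread[1] < spread[0] / 10


class TestEBayesReliability:
    def test_value_one_at_time_zero(self):
        hp = HyperPrior(0.5, 0.5, 0.5, "pi1")
        assert ebayes_reliability(STATS, 0.0, hp, omega=0.3) == 1.0

    def test_equal_spacing_of_families(self):
        hp = make_hyper(s=0.5)
        R = {f: ebayes_reliability(STATS, 0.5, hp[f], omega=0.3) for f in hp}
        assert R["pi3"] - R["pi1"] == pytest.approx(R["pi1"] - R["pi2"], abs=1e-10)
        assert R["pi2"] < R["pi1"] < R["pi3"]

    def test_beta_average_double_integral_oracle(self):
        """Quadrature route (Kummer integrand) vs direct 2-D hyper-prior average."""
        stats = SufficientStats(r=5, T=9.0, lam=0.8)
        t, om = 0.5, 0.2
        Tstar = np.expm1(t**stats.lam)
        for fam in ("pi1", "pi2", "pi3"):
            hp = HyperPrior(1.5, 0.7, 1.8, fam)

            def inner(a):
                val, _ = integrate.quad(
                    lambda b: hp.b_density(b)
                    * ((b + stats.T) / (b + stats.T + Tstar)) ** (stats.r + a),
                    0, hp.s,
                    epsabs=1e-13, epsrel=1e-12,
                )
                return val

            oracle, _ = integrate.quad(
                inner, 0, 1, weight="alg", wvar=(hp.u - 1.0, hp.v - 1.0)
            )
            oracle /= special.beta(hp.u, hp.v)
            anchor = np.exp(-(stats.r / stats.T) * Tstar)
            expected = om * anchor + (1 - om) * oracle
            assert ebayes_reliability(stats, t, hp, omega=om) == pytest.approx(
                expected, rel=1e-9
            )

    def test_convergence_as_T_grows(self):
        hp = make_hyper(s=0.5)
        spread = []
        for T in (5.0, 50.0):
            stats = SufficientStats(r=3, T=T, lam=1.0)
            R = [ebayes_reliability(stats, 0.5, hp[f], omega=0.0) for f in ("pi1", "pi2", "pi3")]
            spread.append(max(R) - min(R))
        assert spread[1] < spread[0] / 10


class TestEBayesHazard:
    def test_factorization_and_midpoint(self):
        hp = make_hyper(s=0.5)
        pref = hazard_prefactor(0.5, STATS.lam)
        h = {}
        for f in hp:
            h[f] = ebayes_hazard(STATS, 0.5, hp[f], omega=0.3)
            assert h[f] == pytest.approx(pref * ebayes_theta(STATS, hp[f], omega=0.3), rel=1e-14)
        assert h["pi1"] == pytest.approx((h["pi2"] + h["pi3"]) / 2, rel=1e-14)
        assert h["pi3"] < h["pi1"] < h["pi2"]

    def test_convergence_as_T_grows(self):
        hp = make_hyper(s=0.5)
        spread = []
        for T in (5.0, 50.0):
            stats = SufficientStats(r=3, T=T, lam=1.0)
            h = [ebayes_hazard(stats, 0.5, hp[f], omega=0.0) for f in ("pi1", "pi2", "pi3")]
            spread.append(max(h) - min(h))
        assert spread[1] < spread[0] / 10


def test_hyper_prior_validation():
    with pytest.raises(ValueError):
        HyperPrior(-1.0, 0.5, 0.5, "pi1")
    with pytest.raises(ValueError):
        HyperPrior(0.5, 0.5, 0.5, "pi4")
    hp = HyperPrior(2.0, 1.0, 3.0, "pi2")
    assert hp.mean_a == pytest.approx(0.25)
    # family densities integrate to one over (0, s)
    for fam in ("pi1", "pi2", "pi3"):
        hp = HyperPrior(2.0, 1.0, 3.0, fam)
        total, _ = integrate.quad(hp.b_density, 0, hp.s)
        assert total == pytest.approx(1.0, rel=1e-10)
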