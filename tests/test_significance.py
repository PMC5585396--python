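from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from dhsdriver.significance import (
    ClusterPoissonTest,
    fdr_curve,
    fit_cluster_mu,
    ks_poisson_check,
    poisson_tail_p,
    poisson_tail_p_array,
    select_threshold,
    simulate_null,
)


def tail_oracle(n, lam: Fraction, digits=60) -> float:
    """Exact Poisson upper tail by Fraction summation + high-precision exp."""
    import sympy as sp

    lam_s = sp.Rational(lam.numerator, lam.denominator)
    partial = sum(lam**k / _factorial(k) for k in range(n))
    s = sp.Rational(partial.numerator, partial.denominator)
    return float(sp.N(1 - sp.exp(-lam_s) * s, digits))


def _factorial(k):
    out = 1
    for i in range(2, k + 1):
        out *= i
    return out


class TestClusterMu:
    def test_direct_ratio(self):
        assert fit_cluster_mu([2, 0, 1], [100, 50, 50]) == pytest.approx(0.015)

    def test_all_zero_counts(self):
        assert fit_cluster_mu([0, 0], [10, 20]) == 0.0

    def test_zero_total_length_errors(self):
        with pytest.raises(ValueError):
            fit_cluster_mu([1], [0])

    def test_random_members_match_summation_oracle(self, rng):
        n = rng.integers(0, 5, 100)
        L = rng.integers(50, 500, 100)
        assert fit_cluster_mu(n, L) == pytest.approx(sum(n) / sum(L), rel=1e-15)


class TestPoissonTail:
    def test_zero_observed_gives_one(self):
        assert poisson_tail_p(0, 0.0) == 1.0
        assert poisson_tail_p(0, 17.3) == 1.0

    def test_worked_examples(self):
        # frozen from exact Fraction + high-precision exponential
        assert poisson_tail_p(3, 1.0) == pytest.approx(0.08030139707139420, rel=1e-12)
        assert poisson_tail_p(4, 0.2) == pytest.approx(5.684024075815661e-05, rel=1e-12)

    def test_zero_rate_with_observations(self):
        assert poisson_tail_p(5, 0.0) == 0.0

    def test_negative_inputs_error(self):
        with pytest.raises(ValueError):
            poisson_tail_p(-1, 1.0)
        with pytest.raises(ValueError):
            poisson_tail_p(1, -0.5)

    @pytest.mark.parametrize("lam", [Fraction(1, 100), Fraction(1, 2), Fraction(3), Fraction(30)])
    @pytest.mark.parametrize("n", [1, 2, 5, 20, 60])
    def test_matches_exact_summation(self, n, lam):
        expected = tail_oracle(n, lam)
        got = poisson_tail_p(n, float(lam))
        if expected == 0.0:
            assert got == 0.0
        else:
            assert got == pytest.approx(expected, rel=1e-12)

    def test_array_version_agrees_with_scalar(self, rng):
        n = rng.integers(0, 30, 200)
        lam = rng.random(200) * 10
        arr = poisson_tail_p_array(n, lam)
        for i in range(0, 200, 17):
            assert arr[i] == pytest.approx(poisson_tail_p(int(n[i]), float(lam[i])), rel=1e-9)


class TestSimulateNull:
    def test_zero_rate_gives_all_ones(self):
        pool = simulate_null(np.zeros(10), replicates=3, seed=0)
        assert (pool == 1.0).all()

    def test_pool_size_and_determinism(self):
        lam = np.full(50, 0.7)
        a = simulate_null(lam, replicates=4, seed=123)
        b = simulate_null(lam, replicates=4, seed=123)
        assert a.shape == (200,)
        assert np.array_equal(a, b)

    def test_tail_fraction_matches_closed_form(self):
        # P(n >= 2 | lam=0.5) = 1 - e^-0.5 * 1.5 = 0.090204...
        lam = np.full(1000, 0.5)
        pool = simulate_null(lam, replicates=100, seed=7)
        # p < 0.5 iff n >= 2 for lam = 0.5 (p(1) = 0.3935, p(2) = 0.0902)
        frac = (pool <= 0.0903).mean()
        assert frac == pytest.approx(0.0902040104310499, abs=0.003)


class TestFDRCurve:
    def test_ratio_value(self):
        observed = np.array([0.01] * 4 + [1.0] * 96)
        null = np.array([0.01] * 1 + [1.0] * 99)
        curve = fdr_curve(observed, null)
        assert curve.fdr[0] == pytest.approx(0.25)

    def test_identical_distributions_give_fdr_one(self):
        vals = np.linspace(0.01, 1, 50)
        curve = fdr_curve(vals, np.tile(vals, 10))
        assert np.allclose(curve.fdr, 1.0)

    def test_matches_counting_oracle(self, rng):
        observed = rng.random(50)
        null = rng.random(500)
        curve = fdr_curve(observed, null)
        for t, f_obs, f_exp, q in zip(curve.thresholds, curve.f_obs, curve.f_exp, curve.fdr):
            fo = (observed <= t).sum() / 50
            fe = (null <= t).sum() / 500
            assert f_obs == pytest.approx(fo)
            assert f_exp == pytest.approx(fe)
            assert q == pytest.approx(fe / fo)

    def test_cumulative_fractions_nondecreasing(self, rng):
        curve = fdr_curve(rng.random(200), rng.random(1000))
        assert (np.diff(curve.f_obs) >= 0).all()
        assert (np.diff(curve.f_exp) >= 0).all()


class TestSelectThreshold:
    def test_monotone_crossing(self):
        from dhsdriver.significance import FDRCurve

        curve = FDRCurve(
            np.array([0.001, 0.01, 0.1, 1.0]),
            np.array([0.04, 0.1, 0.3, 1.0]),
            np.array([0.004, 0.03, 0.27, 1.0]),
            np.array([0.1, 0.3, 0.9, 1.0]),
        )
        p_star, _ = select_threshold(curve, q=0.25)
        # p* sits just above the largest qualifying threshold so that the
        # strict rule p < p* rejects exactly {p <= 0.001}
        assert 0.001 < p_star < 0.01
        assert 0.001 < p_star and not 0.01 < p_star

    def test_no_threshold_qualifies(self):
        from dhsdriver.significance import FDRCurve

        curve = FDRCurve(np.array([0.1]), np.array([0.5]), np.array([0.5]), np.array([1.0]))
        p_star, mask = select_threshold(curve, q=0.25)
        assert p_star is None and not mask.any()

    def test_non_monotone_curve_takes_largest_qualifying(self):
        from dhsdriver.significance import FDRCurve

        fdr = np.array([0.2, 0.4, 0.22, 0.8])
        thresholds = np.array([1e-4, 1e-3, 1e-2, 1e-1])
        curve = FDRCurve(thresholds, np.ones(4), np.ones(4), fdr)
        p_star, _ = select_threshold(curve, 0.25)
        # exhaustive scan oracle: rejection set bounded by the largest
        # qualifying threshold
        best = max(t for t, f in zip(thresholds, fdr) if f <= 0.25)
        assert best < p_star <= np.nextafter(best, np.inf)


class TestKS:
    def test_identical_samples_d_zero(self):
        x = np.linspace(0, 1, 100)
        d, _ = ks_poisson_check(x, x)
        assert d == pytest.approx(0.0)

    def test_disjoint_supports_d_one(self):
        d, p = ks_poisson_check(np.full(100, 0.1), np.full(100, 0.9))
        assert d == pytest.approx(1.0)
        assert p < 1e-10

    def test_matches_sup_over_pooled_points(self, rng):
        a, b = rng.random(100), rng.random(100)
        d, _ = ks_poisson_check(a, b)
        pooled = np.concatenate([a, b])
        sup = max(
            abs((a <= t).mean() - (b <= t).mean()) for t in pooled
        )
        assert d == pytest.approx(sup)


class TestEstimator:
    def _toy_table(self, rng, n_dhs=2000, mu=0.002):
        L = rng.integers(100, 1000, n_dhs)
        cluster = rng.integers(0, 4, n_dhs)
        n = rng.poisson(mu * L)
        return pd.DataFrame({"n": n, "L": L, "cluster": cluster})

    def test_fitted_mu_matches_functional_form(self, rng):
        table = self._toy_table(rng)
        est = ClusterPoissonTest(null_replicates=5, random_state=0).fit(table)
        for cl, grp in table.groupby("cluster"):
            assert est.mu_[cl] == pytest.approx(fit_cluster_mu(grp["n"], grp["L"]))

    def test_zero_count_dhs_has_p_one(self, rng):
        table = self._toy_table(rng)
        est = ClusterPoissonTest(null_replicates=5, random_state=0).fit(table)
        zero = table["n"].to_numpy() == 0
        assert (est.results_.loc[zero, "p"] == 1.0).all()

    def test_determinism_under_seed(self, rng):
        table = self._toy_table(rng)
        a = ClusterPoissonTest(null_replicates=10, random_state=42).fit(table)
        b = ClusterPoissonTest(null_replicates=10, random_state=42).fit(table)
        assert np.array_equal(a.null_pool_, b.null_pool_)
        assert a.p_star_ == b.p_star_

    def test_conservative_for_contaminated_clusters(self, rng):
        # a cluster containing selected DHSs has inflated mu_hat, so every
        # driver's p exceeds the p computed with the true neutral rate
        L = np.full(500, 1000)
        mu_true = 0.001
        n = rng.poisson(mu_true * L)
        drivers = np.arange(10)
        n[drivers] = rng.poisson(10 * mu_true * L[drivers])
        table = pd.DataFrame({"n": n, "L": L, "cluster": 0})
        est = ClusterPoissonTest(null_replicates=5, random_state=0).fit(table)
        assert est.mu_[0] >= mu_true  # MLE inflated above the neutral rate
        p_fit = est.results_["p"].to_numpy()[drivers]
        p_true = poisson_tail_p_array(n[drivers], mu_true * L[drivers])
        assert (p_fit >= p_true).all()
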