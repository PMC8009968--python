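"""Bivariate/multivariate normal primitives against independent oracles."""

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import multivariate_normal, norm

from omnitrait import TraitCorrelation, pair_exceedance_cov, var_exceedance_count
from omnitrait.bvn import abs_exceed2, abs_union_prob, bvn_cdf, sym_rectangle_prob


def _pair_cov_quad(t, rho):
    """Adaptive 2-D quadrature oracle for the exceedance-indicator covariance."""

    def dens(y, x):
        det = 1.0 - rho * rho
        return np.exp(-(x * x - 2 * rho * x * y + y * y) / (2 * det)) / (
            2 * np.pi * np.sqrt(det)
        )

    lim = 12.0
    total = 0.0
    for sx in (1, -1):
        for sy in (1, -1):
            lo_x, hi_x = (t, lim) if sx > 0 else (-lim, -t)
            lo_y, hi_y = (t, lim) if sy > 0 else (-lim, -t)
            v, _ = integrate.dblquad(dens, lo_x, hi_x, lo_y, hi_y, epsabs=1e-12)
            total += v
    p = 2 * norm.sf(t)
    return total - p * p


class TestBvnCdf:
    def test_matches_scipy_mvn(self, rng):
        for _ in range(100):
            h, k = rng.normal(size=2) * 2
            rho = rng.uniform(-0.99, 0.99)
            ref = multivariate_normal.cdf(
                [h, k], mean=[0, 0], cov=[[1, rho], [rho, 1]], abseps=1e-12, releps=1e-12
            )
            assert bvn_cdf(h, k, rho) == pytest.approx(ref, abs=5e-11)

    def test_degenerate_correlations(self):
        assert bvn_cdf(0.5, 1.5, 1.0) == pytest.approx(norm.cdf(0.5), abs=1e-14)
        assert bvn_cdf(0.5, -0.2, -1.0) == pytest.approx(
            max(0.0, norm.cdf(0.5) + norm.cdf(-0.2) - 1), abs=1e-14
        )


class TestPairExceedanceCov:
    def test_independence_is_zero(self):
        assert pair_exceedance_cov(1.0, 0.0) == pytest.approx(0.0, abs=1e-14)

    def test_perfect_dependence(self):
        p = 2 * norm.sf(1.0)
        assert pair_exceedance_cov(1.0, 1.0) == pytest.approx(p * (1 - p), abs=1e-12)

    def test_quadrature_oracle(self):
        assert pair_exceedance_cov(2.0, 0.5) == pytest.approx(
            _pair_cov_quad(2.0, 0.5), abs=1e-8
        )

    @pytest.mark.parametrize("t,rho", [(1.0, 0.3), (2.5, 0.7), (0.5, 0.9)])
    def test_even_in_rho(self, t, rho):
        assert pair_exceedance_cov(t, rho) == pytest.approx(
            pair_exceedance_cov(t, -rho), abs=1e-13
        )

    def test_bounds_and_errors(self):
        t, rho = 1.3, 0.4
        p = 2 * norm.sf(t)
        c = pair_exceedance_cov(t, rho)
        assert -(p * p) <= c <= p * (1 - p)
        with pytest.raises(ValueError):
            pair_exceedance_cov(1.0, 1.5)
        with pytest.raises(ValueError):
            pair_exceedance_cov(-0.1, 0.0)


class TestVarExceedanceCount:
    def test_independence_closed_form(self):
        p = 2 * norm.sf(1.0)
        assert var_exceedance_count(1.0, np.eye(5)) == pytest.approx(
            5 * p * (1 - p), abs=1e-12
        )

    def test_vanishing_tail(self):
        assert var_exceedance_count(10.0, TraitCorrelation.exchangeable(4, 0.5).sigma) < 1e-10

    def test_monte_carlo_oracle(self, rng):
        # spec-scale oracle: 1e7 trivariate draws, agreement within 3 SE
        t, K, rho = 1.5, 3, 0.3
        sig = TraitCorrelation.exchangeable(K, rho)
        n = 10_000_000
        var_mc = []
        L = np.linalg.cholesky(sig.sigma)
        counts = np.empty(0)
        for _ in range(10):
            z = rng.standard_normal((n // 10, K)) @ L.T
            counts = np.concatenate([counts, np.sum(np.abs(z) >= t, axis=1)])
        var_mc = counts.var()
        se = np.sqrt(2.0 / n) * var_mc  # rough SE of a variance estimate
        ours = var_exceedance_count(t, sig.sigma)
        assert abs(ours - var_mc) < 3 * max(se, 1e-3)

    def test_sign_flip_invariance(self):
        s = np.array([[1, 0.3, -0.2], [0.3, 1, 0.5], [-0.2, 0.5, 1]])
        d = np.diag([1.0, -1.0, 1.0])
        assert var_exceedance_count(1.2, s) == pytest.approx(
            var_exceedance_count(1.2, d @ s @ d), abs=1e-12
        )


class TestUnionAndRectangle:
    def test_k1_and_k2_closed_forms(self):
        c = 1.7
        p1 = 2 * norm.sf(c)
        assert abs_union_prob(c, TraitCorrelation.identity(1)) == pytest.approx(p1, abs=1e-14)
        got = abs_union_prob(c, TraitCorrelation.identity(2))
        assert got == pytest.approx(1 - (1 - p1) ** 2, abs=1e-12)

    def test_k3_against_scipy_rectangle(self, lipid_corr):
        for c in (0.8, 1.6, 2.4):
            ref = multivariate_normal.cdf(
                np.full(3, c), mean=np.zeros(3), cov=lipid_corr.sigma,
                lower_limit=np.full(3, -c), abseps=1e-10, releps=1e-10,
                rng=np.random.default_rng(5),
            )
            assert sym_rectangle_prob(c, lipid_corr) == pytest.approx(ref, abs=5e-6)

    def test_deep_tail_equals_truncated_inclusion_exclusion(self, lipid_corr):
        # at genome-wide thresholds the union is dominated by the singles term
        c = norm.isf(5e-8 / 2)
        got = abs_union_prob(c, lipid_corr)
        singles = 3 * 2 * norm.sf(c)
        assert 0.9 * singles < got < 1.05 * singles

    def test_exchangeable_large_k(self):
        sig = TraitCorrelation.exchangeable(6, 0.4)
        c = 1.2
        ref = multivariate_normal.cdf(
            np.full(6, c), mean=np.zeros(6), cov=sig.sigma, lower_limit=np.full(6, -c),
            abseps=1e-9, releps=1e-9, rng=np.random.default_rng(6),
        )
        assert sym_rectangle_prob(c, sig) == pytest.approx(ref, abs=5e-5)

    def test_abs_exceed2_shifted_means(self):
        # against plain 2-D Monte Carlo
        rng = np.random.default_rng(11)
        rho, m1, m2, c = 0.4, 0.8, -0.5, 1.1
        L = np.linalg.cholesky([[1, rho], [rho, 1]])
        z = rng.standard_normal((2_000_000, 2)) @ L.T + [m1, m2]
        mc = np.mean((np.abs(z[:, 0]) >= c) & (np.abs(z[:, 1]) >= c))
        got = float(abs_exceed2(c, c, m1, m2, 1.0, 1.0, rho))
        assert got == pytest.approx(mc, abs=3 * np.sqrt(mc * (1 - mc) / 2e6))
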