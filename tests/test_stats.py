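"""Test statistics, Cauchy combination and the per-SNP omnibus contract."""

import math
import warnings

import numpy as np
import pytest
from scipy.stats import binom, norm

from omnitrait import (
    MultiTraitZ,
    TraitCorrelation,
    acat_combine,
    gbj_pvalue,
    gbj_statistic,
    gbj_terms,
    ghc_pvalue,
    ghc_statistic,
    minp_pvalue,
    omni_test,
    solve_mu_hat,
)


class TestGhcStatistic:
    def test_zero_vector_gives_zero(self):
        assert ghc_statistic(np.zeros(2), np.eye(2), t0=0.0) == 0.0

    def test_sup_attained_at_order_statistics(self, rng):
        # brute-force the supremum on a fine grid of thresholds
        z = rng.normal(size=4)
        sig = TraitCorrelation.exchangeable(4, 0.3)
        from omnitrait.stats import _ghc_process

        m = np.sort(np.abs(z))[::-1]
        stat = ghc_statistic(z, sig)
        grid = np.linspace(1e-3, np.max(m), 3000)
        counts = np.array([(np.abs(z) >= t).sum() for t in grid])
        vals = _ghc_process(grid, counts, sig)
        assert stat >= np.max(vals) - 1e-6

    def test_t0_warning_when_no_candidate(self):
        with pytest.warns(RuntimeWarning):
            ghc_statistic(np.array([0.1, -0.2]), np.eye(2), t0=3.0)


class TestGbjStatistic:
    def test_no_active_term_gives_zero(self):
        z = np.array([0.1, -0.1])
        assert gbj_statistic(z, np.eye(2)) == 0.0
        terms = gbj_terms(z, np.eye(2))
        assert all(not t.active and t.lr_value == 0.0 for t in terms)

    def test_reduces_to_binomial_berk_jones(self, rng):
        """With sigma = I the EBB machinery must equal the plain binomial
        likelihood-ratio Berk-Jones computation (independent oracle)."""
        K = 6
        ident = TraitCorrelation.identity(K)
        for _ in range(20):
            z = rng.normal(size=K) * 1.5
            m = np.sort(np.abs(z))[::-1]
            oracle = 0.0
            for k in range(1, K):  # finite-root ranks
                t = m[k - 1]
                p0 = 2 * norm.sf(t)
                if p0 >= k / K:
                    continue
                term = np.log(binom.pmf(k, K, k / K)) - np.log(binom.pmf(k, K, p0))
                oracle = max(oracle, term)
            assert gbj_statistic(z, ident) == pytest.approx(oracle, abs=1e-8)

    def test_mu_hat_enters_terms(self):
        z = np.array([3.0, 2.5, 0.3])
        terms = gbj_terms(z, np.eye(3))
        active = [t for t in terms if t.active]
        assert active, "large Z-scores must activate at least one rank"
        for t in active:
            assert t.mu_hat == pytest.approx(solve_mu_hat(t.order_stat, t.k, 3), abs=1e-10)


class TestMinP:
    def test_k1_two_sided(self):
        z = np.array([1.7])
        assert minp_pvalue(z, np.eye(1)) == pytest.approx(2 * norm.sf(1.7), abs=1e-14)

    def test_k2_independent(self):
        z = np.array([0.5, 2.2])
        pmin = 2 * norm.sf(2.2)
        assert minp_pvalue(z, np.eye(2)) == pytest.approx(1 - (1 - pmin) ** 2, abs=1e-12)

    def test_bonferroni_bracket(self, rng, lipid_corr):
        for _ in range(10):
            z = rng.normal(size=3) * 2
            pmin = 2 * norm.sf(np.max(np.abs(z)))
            p = minp_pvalue(z, lipid_corr)
            assert pmin - 1e-12 <= p <= min(3 * pmin, 1.0) + 1e-12


class TestAcatCombine:
    def test_identical_pvalues_round_trip(self):
        for p in (0.5, 0.01, 1e-5, 0.9):
            stat, combined = acat_combine([p, p, p])
            assert combined == pytest.approx(p, rel=1e-10)

    def test_median_gives_half(self):
        stat, p = acat_combine([0.5, 0.5, 0.5])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(0.5, abs=1e-12)

    def test_single_pvalue_weight_one(self):
        _, p = acat_combine([0.037], weights=[1.0])
        assert p == pytest.approx(0.037, rel=1e-12)

    def test_small_p_guard_keeps_relative_accuracy(self):
        _, p = acat_combine([1e-30, 1e-30, 1e-30])
        assert p == pytest.approx(1e-30, rel=1e-6)

    def test_errors_and_warnings(self):
        with pytest.raises(ValueError):
            acat_combine([1.2, 0.5])
        with pytest.raises(ValueError):
            acat_combine([0.5, 0.5], weights=[0.9, 0.2])
        with pytest.warns(RuntimeWarning):
            _, p = acat_combine([0.0, 0.5])
        assert p == 0.0


class TestOmniContract:
    def test_result_internally_consistent(self, rng, lipid_corr):
        z = rng.normal(size=3) * 2
        res = omni_test(MultiTraitZ(z, "snp1"), lipid_corr)
        stat, p = acat_combine([res.p_gbj, res.p_ghc, res.p_minp])
        assert res.p_omni == pytest.approx(p, abs=1e-12)
        assert all(0 <= v <= 1 for v in res.pvalues().values())

    def test_trait_permutation_invariance(self, rng, lipid_corr):
        z = rng.normal(size=3) * 1.5
        perm = np.array([2, 0, 1])
        s_perm = TraitCorrelation(lipid_corr.sigma[np.ix_(perm, perm)])
        a = omni_test(z, lipid_corr)
        b = omni_test(z[perm], s_perm)
        for name in ("p_gbj", "p_ghc", "p_minp", "p_omni"):
            assert getattr(a, name) == pytest.approx(getattr(b, name), abs=1e-12)

    def test_trait_sign_invariance(self, rng, lipid_corr):
        z = rng.normal(size=3) * 1.5
        d = np.diag([1.0, -1.0, -1.0])
        s_flip = TraitCorrelation(d @ lipid_corr.sigma @ d)
        a = omni_test(z, lipid_corr)
        b = omni_test(d @ z, s_flip)
        for name in ("p_gbj", "p_ghc", "p_minp", "p_omni"):
            assert getattr(a, name) == pytest.approx(getattr(b, name), abs=1e-10)

    def test_k1_all_tests_equal_two_sided_p(self):
        z = np.array([2.3])
        expected = 2 * norm.sf(2.3)
        assert gbj_pvalue(z, np.eye(1)) == pytest.approx(expected, rel=1e-6)
        assert ghc_pvalue(z, np.eye(1)) == pytest.approx(expected, rel=1e-6)
        assert minp_pvalue(z, np.eye(1)) == pytest.approx(expected, rel=1e-12)
        res = omni_test(z, np.eye(1))
        assert res.p_omni == pytest.approx(expected, rel=1e-5)

    def test_no_signal_pvalues_large(self):
        res = omni_test(np.zeros(2), np.eye(2))
        assert res.p_gbj >= 0.5 and res.p_ghc >= 0.5 and res.p_minp >= 0.5
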