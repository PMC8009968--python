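"""Multi-phenotype association tests on a vector of GWAS Z-scores.

Given a per-SNP vector Z of K trait Z-scores, multivariate normal with
correlation ``sigma`` under the null of no association, this module provides

* the generalized higher criticism (GHC) statistic
  ``sup_t (S(t) - 2*K*phibar(t)) / sqrt(var S(t))`` with the count variance
  adjusted for the between-trait correlation,
* the generalized Berk-Jones (GBJ) statistic, a maximum of per-rank
  likelihood-ratio terms in which the exceedance count S(t) is modelled by an
  extended beta-binomial (EBB) whose variance is matched to ``sigma``,
* the correlation-aware MinP test (multivariate normal rectangle at the
  largest |Z|), and
* the Cauchy-combination (ACAT) omnibus of the three p-values.

Analytic p-values for the supremum-type statistics come from a shared
boundary-crossing engine: the observed statistic is inverted into per-rank
magnitude thresholds t_1 >= ... >= t_K, and the probability that the ordered
|Z| ever cross that boundary is evaluated under an exchangeable EBB
approximation of the exceedance counts (a Markov chain over nested
thresholds whose increment distributions are EBBs with variance matched per
threshold).  With sigma = I the chain is exact and GBJ/GHC collapse to the
classical Berk-Jones and higher criticism tests.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtri

from . import bvn
from .ebb import clamp_dispersion, ebb_logpmf, ebb_pmf_vector
from .types import CrossingBoundary, GbjTerm, MultiTraitZ, TestResult, TraitCorrelation

__all__ = [
    "exceedance_count",
    "pair_exceedance_cov",
    "var_exceedance_count",
    "solve_mu_hat",
    "ghc_statistic",
    "gbj_statistic",
    "gbj_terms",
    "crossing_pvalue",
    "minp_pvalue",
    "acat_combine",
    "gbj_pvalue",
    "ghc_pvalue",
    "omni_test",
    "batch_pvalues",
    "batch_statistics",
]

KINDS = ("GBJ", "GHC", "HC", "BJ", "MinP")

#: p-value below which tan((0.5 - p) * pi) is replaced by its 1/(p*pi) limit
_ACAT_GUARD = 1e-16
#: magnitudes above this are treated as "infinite" thresholds (2*phibar
#: underflows); keeps owens_t away from non-finite arguments
_T_MAX = 40.0
_V_FLOOR = 1e-320


# ---------------------------------------------------------------------------
# small shared helpers


def _as_z(z) -> np.ndarray:
    if isinstance(z, MultiTraitZ):
        return z.z
    arr = np.atleast_1d(np.asarray(z, dtype=float))
    if arr.ndim != 1:
        raise ValueError("z must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValueError("all Z-scores must be finite")
    return arr


def _as_corr(sigma, n_traits: int | None = None) -> TraitCorrelation:
    corr = sigma if isinstance(sigma, TraitCorrelation) else TraitCorrelation(np.asarray(sigma))
    if n_traits is not None and corr.n_traits != n_traits:
        raise ValueError(f"sigma is {corr.n_traits}x{corr.n_traits}, expected {n_traits}")
    return corr


def _p0(t):
    """Two-sided tail probability 2*phibar(t) of a standard normal."""
    return 2.0 * bvn.phibar(t)


def _pmu(t, mu):
    """P(|Z| >= t) for Z ~ N(mu, 1); mu = +inf gives 1."""
    t = np.asarray(t, dtype=float)
    mu = np.asarray(mu, dtype=float)
    out = np.where(
        np.isinf(mu), 1.0, bvn.phibar(t - np.where(np.isinf(mu), 0.0, mu)) + bvn.phibar(t + mu)
    )
    return out


def _pair_cov(t, rho, mu=0.0):
    """Cov(1{|Z_i|>=t}, 1{|Z_j|>=t}) for bivariate normal with common mean."""
    joint = bvn.abs_exceed2(t, t, mu, mu, 1.0, 1.0, rho)
    marg = _pmu(t, mu)
    return joint - marg * marg


def _count_variance(t, corr: TraitCorrelation, mu=None, absolute: bool = False):
    """Variance of S(t) = sum_k 1{|Z_k| >= t}; vectorized over t (and mu).

    Under the null (mu = None) the pair covariances are even functions of the
    correlations, so the result is invariant to per-trait sign conventions.
    Under a common mean shift they are not; ``absolute=True`` couples every
    pair through |rho| (signs aligned with the shift), which restores the
    invariance and is the convention used for the GBJ numerator.
    """
    t = np.asarray(t, dtype=float)
    K = corr.n_traits
    if mu is None:
        marg = _p0(t)
        mu_arr = 0.0
    else:
        mu_arr = np.asarray(mu, dtype=float)
        marg = _pmu(t, mu_arr)
    var = K * marg * (1.0 - marg)
    if K > 1:
        vals, counts = corr.offdiag_values()
        if absolute:
            vals, counts = np.unique(np.repeat(np.abs(vals), counts), return_counts=True)
        for r, cnt in zip(vals, counts):
            var = var + 2.0 * cnt * _pair_cov(t, r, mu_arr)
    return np.maximum(var, 0.0)


def _dispersion_from_variance(n: int, p, var):
    """Indicator pairwise correlation implied by a target count variance."""
    p = np.asarray(p, dtype=float)
    var = np.asarray(var, dtype=float)
    base = n * p * (1.0 - p)
    if n <= 1:
        return np.zeros(np.broadcast(p, var).shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = (var / np.maximum(base, _V_FLOOR) - 1.0) / (n - 1)
    return np.where(base <= _V_FLOOR, 0.0, g)


# ---------------------------------------------------------------------------
# elementary operations


def exceedance_count(z, t: float) -> int:
    """Number of traits with |Z_k| >= t (closed threshold)."""
    if t < 0:
        raise ValueError("threshold t must be non-negative")
    return int(np.count_nonzero(np.abs(_as_z(z)) >= t))


def pair_exceedance_cov(t: float, rho: float) -> float:
    """Covariance of the two exceedance indicators of a standard bivariate
    normal pair with correlation rho at threshold t; an even function of rho."""
    if abs(rho) > 1:
        raise ValueError("|rho| must be <= 1")
    if t < 0:
        raise ValueError("threshold t must be non-negative")
    return float(_pair_cov(min(t, _T_MAX), float(rho)))


def var_exceedance_count(t: float, sigma) -> float:
    """Variance of the exceedance count S(t) under MVN(0, sigma)."""
    if t < 0:
        raise ValueError("threshold t must be non-negative")
    corr = _as_corr(sigma)
    return float(_count_variance(min(t, _T_MAX), corr))


def _mu_hat_vec(t, k, n_traits: int, iters: int = 64):
    """Vectorized solve of k/K = P(|N(mu,1)| >= t) for mu >= 0.

    Returns 0 when the equation already holds at mu = 0 (2*phibar(t) >= k/K)
    and +inf for k = K with t > 0, where the target 1 is reached only in the
    limit (the rank-K likelihood-ratio term then uses a degenerate count).
    """
    t = np.asarray(t, dtype=float)
    k = np.asarray(k, dtype=float)
    target = k / n_traits
    at_zero = _p0(t) >= target - 1e-12
    full = (k >= n_traits) & (t > 0)
    lo = np.zeros_like(t)
    hi = t + 10.0
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        below = bvn.phibar(t - mid) + bvn.phibar(t + mid) < target
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    mu = 0.5 * (lo + hi)
    mu = np.where(at_zero, 0.0, mu)
    return np.where(full & ~at_zero, np.inf, mu)


def solve_mu_hat(order_stat: float, k: int, n_traits: int) -> float:
    """Positive root mu of k/K = phibar(t - mu) + phibar(t + mu) at t = order_stat.

    Bracketed bisection on [0, t + 10] to ~1e-10; returns 0 when no positive
    root exists because the left side already dominates at mu = 0, and +inf
    for the boundary rank k = K (target 1 is only reached asymptotically).
    """
    if not (1 <= k <= n_traits):
        raise ValueError(f"k={k} outside 1..{n_traits}")
    if order_stat < 0:
        raise ValueError("order_stat must be >= 0")
    return float(_mu_hat_vec(np.asarray(order_stat, dtype=float), k, n_traits))


# ---------------------------------------------------------------------------
# GHC


def _ghc_process(t, k, corr: TraitCorrelation):
    """Standardized exceedance process (k - K*2*phibar(t)) / sqrt(var S(t)).

    The 0/0 limit at t = 0 (all mass, zero variance) is defined as 0, matching
    the k = K boundary case.
    """
    K = corr.n_traits
    t = np.minimum(np.asarray(t, dtype=float), _T_MAX)
    num = np.asarray(k, dtype=float) - K * _p0(t)
    var = _count_variance(t, corr)
    g = num / np.sqrt(np.maximum(var, _V_FLOOR))
    return np.where(num == 0.0, 0.0, g)


def ghc_statistic(z, sigma, t0: float = 0.0) -> float:
    """GHC statistic: supremum of the standardized exceedance process over
    t >= t0, attained at the observed order statistics of |Z|."""
    zz = _as_z(z)
    corr = _as_corr(sigma, zz.size)
    m = np.sort(np.abs(zz))[::-1]
    cand = m >= t0
    if not np.any(cand):
        warnings.warn(
            "no |Z| reaches t0; GHC evaluated at the largest |Z| only", RuntimeWarning
        )
        cand = np.zeros_like(cand)
        cand[0] = True
    k = np.arange(1, zz.size + 1)
    vals = _ghc_process(m[cand], k[cand], corr)
    return float(np.max(vals))


# ---------------------------------------------------------------------------
# GBJ


def _gbj_term_vec(t, k, corr: TraitCorrelation):
    """GBJ likelihood-ratio term at order statistic t for rank k (vectorized).

    Returns (term, clamped): the log ratio of the EBB probability of observing
    exactly k exceedances at threshold t under the fitted common mean versus
    under the null, zeroed where the rank is inactive (2*phibar(t) >= k/K).
    """
    K = corr.n_traits
    t = np.minimum(np.asarray(t, dtype=float), _T_MAX)
    k_arr = np.broadcast_to(np.asarray(k), t.shape)
    p_den = np.clip(_p0(t), 1e-300, 1.0 - 1e-16)
    active = p_den < k_arr / K

    mu = _mu_hat_vec(t, k_arr, K)
    p_num = np.clip(_pmu(t, mu), 1e-300, 1.0)
    degen = p_num >= 1.0 - 1e-15  # rank-K term: numerator count is degenerate at K

    v_den = _count_variance(t, corr)
    g_den = _dispersion_from_variance(K, p_den, v_den)
    g_den, cl1 = clamp_dispersion(K, p_den, g_den)
    logden = ebb_logpmf(k_arr, K, p_den, g_den)

    mu_safe = np.where(np.isfinite(mu), mu, 0.0)
    v_num = _count_variance(t, corr, mu=mu_safe, absolute=True)
    p_num_safe = np.clip(p_num, 1e-300, 1.0 - 1e-16)
    g_num = _dispersion_from_variance(K, p_num_safe, v_num)
    g_num, cl2 = clamp_dispersion(K, p_num_safe, g_num)
    lognum = np.where(degen, 0.0, ebb_logpmf(k_arr, K, p_num_safe, g_num))

    term = np.where(active, lognum - logden, 0.0)
    return term, (cl1 or cl2)


def gbj_terms(z, sigma, index_range: str = "auto") -> list[GbjTerm]:
    """Per-rank GBJ terms for diagnostics; ranks run over 1..K by default or
    1..floor(K/2) when ``index_range='half'``."""
    zz = _as_z(z)
    corr = _as_corr(sigma, zz.size)
    K = zz.size
    m = np.sort(np.abs(zz))[::-1]
    ks = _rank_range(K, index_range)
    term, _ = _gbj_term_vec(m[ks - 1], ks, corr)
    mus = _mu_hat_vec(m[ks - 1], ks, K)
    active = _p0(np.minimum(m[ks - 1], _T_MAX)) < ks / K
    out = []
    for i, k in enumerate(ks):
        out.append(
            GbjTerm(
                k=int(k),
                order_stat=float(m[k - 1]),
                mu_hat=float(mus[i]) if np.isfinite(mus[i]) else np.inf,
                lr_value=float(term[i]) if active[i] else 0.0,
                active=bool(active[i]),
            )
        )
    return out


def _rank_range(n_traits: int, index_range: str) -> np.ndarray:
    """Ranks entering the GBJ maximum.

    'auto' (default) keeps the ranks whose mean-shift equation has a finite
    root, 1..K-1 (the k = K target of 1 is reached only as mu -> infinity and
    its degenerate term distorts the deep-tail crossing probability); the
    single rank is kept when K = 1.  'full' uses 1..K with the degenerate
    limit, 'half' the sparse-focused 1..floor(K/2).
    """
    if index_range == "auto":
        return np.arange(1, max(n_traits - 1, 1) + 1)
    if index_range == "full":
        return np.arange(1, n_traits + 1)
    if index_range == "half":
        return np.arange(1, max(n_traits // 2, 1) + 1)
    raise ValueError("index_range must be 'auto', 'full' or 'half'")


def gbj_statistic(z, sigma, index_range: str = "auto") -> float:
    """GBJ statistic: maximum over ranks of the EBB likelihood-ratio terms,
    floored at zero."""
    zz = _as_z(z)
    corr = _as_corr(sigma, zz.size)
    m = np.sort(np.abs(zz))[::-1]
    ks = _rank_range(zz.size, index_range)
    term, _ = _gbj_term_vec(m[ks - 1], ks, corr)
    return float(max(np.max(term), 0.0))


# ---------------------------------------------------------------------------
# boundary-crossing engine


def _chain_cross_binom(p: np.ndarray, ranks: np.ndarray, n_traits: int):
    """Exact binomial count chain (iid indicators); log-space pmf and
    incomplete-beta survival keep deep-tail relative precision."""
    from scipy.special import betainc, gammaln

    B, m = p.shape
    K = n_traits
    logC = gammaln(np.arange(K + 1) + 1.0)
    cross = np.zeros(B)
    f = np.zeros((B, K + 1))
    f[:, 0] = 1.0
    p_prev = np.zeros(B)
    with np.errstate(divide="ignore"):
        for j in range(m):
            pj = p[:, j]
            denom = 1.0 - p_prev
            q = np.clip(
                np.where(denom > 1e-15, (pj - p_prev) / np.maximum(denom, 1e-15), 1.0),
                0.0,
                1.0,
            )
            lq = np.log(np.maximum(q, 1e-320))
            l1q = np.log1p(-np.minimum(q, 1.0 - 1e-16))
            limit = int(ranks[j])
            f_new = np.zeros_like(f)
            for s in range(min(limit, K + 1)):
                fs = f[:, s]
                if not np.any(fs > 0):
                    continue
                n_s = K - s
                if n_s == 0:
                    f_new[:, s] += fs
                    continue
                d_keep = min(limit - 1 - s, n_s)
                d = np.arange(d_keep + 1)
                lbin = logC[n_s] - logC[d] - logC[n_s - d]
                pmf = np.exp(lbin[None, :] + d[None, :] * lq[:, None] + (n_s - d)[None, :] * l1q[:, None])
                f_new[:, s : s + d_keep + 1] += fs[:, None] * pmf
                if d_keep < n_s:
                    cross += fs * betainc(d_keep + 1, n_s - d_keep, q)
            f = f_new
            p_prev = pj
    return np.clip(cross, 0.0, 1.0)


def _chain_cross(p: np.ndarray, gamma: np.ndarray, ranks: np.ndarray, n_traits: int):
    """Crossing mass of the count Markov chain over nested thresholds.

    ``p`` (B, m) holds the per-variable exceedance probability at each step
    (non-decreasing along axis 1) and ``gamma`` the dispersion of each EBB
    increment (0 = exact binomial chain).  At step j any state with count
    >= ranks[j] has crossed; the crossed mass is accumulated directly so deep
    tails keep full relative precision.
    """
    if not np.any(gamma):
        return _chain_cross_binom(p, ranks, n_traits)
    B, m = p.shape
    K = n_traits
    cross = np.zeros(B)
    f = np.zeros((B, K + 1))
    f[:, 0] = 1.0
    p_prev = np.zeros(B)
    for j in range(m):
        pj = p[:, j]
        denom = 1.0 - p_prev
        q = np.where(denom > 1e-15, (pj - p_prev) / np.maximum(denom, 1e-15), 1.0)
        q = np.clip(q, 0.0, 1.0)
        g = gamma[:, j]
        limit = int(ranks[j])  # states with count >= limit have crossed
        f_new = np.zeros_like(f)
        for s in range(min(limit, K + 1)):
            fs = f[:, s]
            if not np.any(fs > 0):
                continue
            n_s = K - s
            if n_s == 0:
                f_new[:, s] += fs
                continue
            gs, _ = clamp_dispersion(n_s, q, g)
            pmf = ebb_pmf_vector(n_s, q, gs)  # (B, n_s + 1)
            d_keep = min(limit - 1 - s, n_s)
            for d in range(d_keep + 1):
                f_new[:, s + d] += fs * pmf[:, d]
            if d_keep < n_s:
                cross += fs * np.sum(pmf[:, d_keep + 1 :], axis=1)
        f = f_new
        p_prev = pj
    return np.clip(cross, 0.0, 1.0)


#: Gauss-Legendre nodes for the exchangeable one-factor mixture
_FACTOR_NODES = 48
_FACTOR_LIM = 9.0


def _crossing_prob_batch(bounds: np.ndarray, ranks: np.ndarray, corr: TraitCorrelation):
    """P(exists j: S(t_j) >= rank_j) for a batch of non-increasing boundaries.

    For exchangeable correlation with rho >= 0 the probability is computed
    (numerically) exactly: conditioning on the shared one-factor component W
    makes the exceedance indicators iid, so the count chain is binomial and
    the conditional crossing mass is integrated over W by Gauss-Legendre
    quadrature.  For a general sigma the counts are approximated by a Markov
    chain whose EBB increments have their dispersion matched so every
    marginal count variance equals var S(t_j) under sigma; with sigma = I
    this reduces to the exact iid chain.
    """
    K = corr.n_traits
    bounds = np.minimum(np.asarray(bounds, dtype=float), _T_MAX)
    B, m = bounds.shape
    exch, rho = bvn._is_exchangeable(corr.sigma) if K >= 2 else (False, 0.0)

    if exch and 1e-12 <= rho < 1.0 - 1e-10:
        x, w = np.polynomial.legendre.leggauss(_FACTOR_NODES)
        ww = _FACTOR_LIM * x
        weight = _FACTOR_LIM * w * np.exp(-0.5 * ww * ww) / np.sqrt(2 * np.pi)
        sr, s = np.sqrt(rho), np.sqrt(1.0 - rho)
        # conditional per-variable exceedance probs, shape (nodes, B, m)
        pw = bvn.phibar((bounds[None] - sr * ww[:, None, None]) / s) + bvn.phibar(
            (bounds[None] + sr * ww[:, None, None]) / s
        )
        pw = np.maximum.accumulate(np.clip(pw, 0.0, 1.0), axis=2)
        pw = pw.reshape(_FACTOR_NODES * B, m)
        cross = _chain_cross(pw, np.zeros_like(pw), ranks, K)
        cross = cross.reshape(_FACTOR_NODES, B)
        return np.clip(weight @ cross, 0.0, 1.0)

    p = np.maximum.accumulate(_p0(bounds), axis=1)  # monotone marginals
    V = np.empty_like(p)
    for j in range(m):
        V[:, j] = _count_variance(bounds[:, j], corr)
    # increment dispersions chosen so the chain's marginal count variance
    # propagates to the matched target at every threshold
    gamma = np.zeros_like(p)
    p_prev = np.zeros(B)
    v_prev = np.zeros(B)
    for j in range(m):
        pj, vj = p[:, j], V[:, j]
        denom = 1.0 - p_prev
        q = np.where(denom > 1e-15, (pj - p_prev) / np.maximum(denom, 1e-15), 1.0)
        q = np.clip(q, 0.0, 1.0)
        A = K * (1.0 - p_prev)
        Bq = v_prev + A * A - A
        with np.errstate(divide="ignore", invalid="ignore"):
            g = (vj - (1.0 - q) ** 2 * v_prev - q * (1.0 - q) * A) / (q * (1.0 - q) * Bq)
        gamma[:, j] = np.where(
            (q <= 1e-14) | (q >= 1.0 - 1e-14) | (Bq <= 1e-14), 0.0, g
        )
        p_prev, v_prev = pj, vj
    return _chain_cross(p, gamma, ranks, K)


def _crossing_prob(boundary: CrossingBoundary, corr: TraitCorrelation, ranks=None) -> float:
    t = boundary.thresholds
    if ranks is None:
        ranks = np.arange(1, t.size + 1)
    return float(_crossing_prob_batch(t[None, :], np.asarray(ranks), corr)[0])


def _invert_ghc(stat: float, corr: TraitCorrelation, t0: float = 0.0) -> np.ndarray:
    """Per-rank thresholds t_k: smallest t with the GHC process >= stat."""
    K = corr.n_traits
    bounds = np.full(K, np.inf)
    for k in range(1, K + 1):
        f = lambda t: float(_ghc_process(np.asarray([t]), np.asarray([k]), corr)[0]) - stat
        grid = np.linspace(1e-6, _T_MAX, 600)
        vals = _ghc_process(grid, np.full(grid.shape, k), corr) - stat
        idx = np.nonzero(vals >= 0)[0]
        if idx.size == 0:
            continue
        i = idx[0]
        if i == 0:
            bounds[k - 1] = grid[0]
        else:
            bounds[k - 1] = brentq(f, grid[i - 1], grid[i], xtol=1e-12)
    bounds = np.maximum(bounds, t0)
    return np.minimum.accumulate(bounds)


def _invert_gbj(stat: float, corr: TraitCorrelation, index_range: str = "auto") -> tuple:
    """Per-rank thresholds where the GBJ term reaches ``stat``; ranks with an
    unreachable level get an infinite threshold (they cannot trigger)."""
    K = corr.n_traits
    ks = _rank_range(K, index_range)
    bounds = np.full(ks.size, np.inf)
    for i, k in enumerate(ks):
        zstar = float(ndtri(1.0 - min(k / (2.0 * K), 0.5)))  # activation threshold
        lo = zstar + 1e-9

        def f(t, kk=k):
            return float(_gbj_term_vec(np.asarray([t]), np.asarray([kk]), corr)[0][0]) - stat

        hi = max(lo + 0.5, 1.0)
        fhi = f(hi)
        while fhi < 0 and hi < _T_MAX:
            hi = min(hi * 1.6 + 0.5, _T_MAX)
            fhi = f(hi)
        if fhi < 0:
            continue
        flo = f(lo)
        if flo >= 0:
            bounds[i] = lo
        else:
            bounds[i] = brentq(f, lo, hi, xtol=1e-12)
    return ks, np.minimum.accumulate(bounds)


def crossing_pvalue(observed_stat: float, statistic_kind: str, n_traits: int, sigma,
                    t0: float = 0.0, index_range: str = "auto") -> float:
    """Analytic p-value of a supremum-type statistic via boundary crossing.

    Inverts the statistic into per-rank thresholds and returns the probability
    that the ordered |Z| cross them anywhere.  ``statistic_kind`` is one of
    GBJ, GHC (correlation-adjusted), BJ, HC (their independence versions,
    evaluated with sigma = I), or MinP (threshold at the observed max |Z|).
    Monotone non-increasing in the observed statistic; values below the
    attainable minimum give 1, +inf gives 0.
    """
    if statistic_kind not in KINDS:
        raise ValueError(f"unknown statistic kind {statistic_kind!r}")
    if np.isnan(observed_stat):
        raise ValueError("observed_stat must not be NaN")
    if np.isposinf(observed_stat):
        return 0.0
    corr = (
        TraitCorrelation.identity(n_traits)
        if statistic_kind in ("BJ", "HC")
        else _as_corr(sigma, n_traits)
    )
    if statistic_kind == "MinP":
        c = max(float(observed_stat), 0.0)
        return float(bvn.abs_union_prob(c, corr))
    if statistic_kind in ("GHC", "HC"):
        bounds = _invert_ghc(float(observed_stat), corr, t0)
        ranks = np.arange(1, n_traits + 1)
    else:
        if observed_stat <= 0.0:
            return 1.0
        ranks, bounds = _invert_gbj(float(observed_stat), corr, index_range)
    finite = np.isfinite(bounds)
    if not np.any(finite):
        return 0.0 if statistic_kind in ("GBJ", "BJ") else 1.0
    return float(
        _crossing_prob_batch(bounds[None, finite], ranks[finite], corr)[0]
    )


# ---------------------------------------------------------------------------
# MinP, ACAT, compositions


def minp_pvalue(z, sigma) -> float:
    """Correlation-aware MinP: P(max_k |Z_k| >= observed max) under MVN(0, sigma)."""
    zz = _as_z(z)
    corr = _as_corr(sigma, zz.size)
    c = float(np.max(np.abs(zz)))
    return float(bvn.abs_union_prob(c, corr))


def acat_combine(pvalues: Sequence[float], weights: Sequence[float] | None = None):
    """Cauchy combination: stat = sum_i w_i * tan((0.5 - p_i) * pi).

    Returns (stat, pvalue) with pvalue = 1/2 - arctan(stat)/pi.  For p below
    1e-16 the tangent is replaced by its asymptote 1/(p*pi), and for very
    large stats the p-value by 1/(pi*stat); both preserve relative accuracy
    where the direct formulas overflow or lose precision.
    """
    p = np.atleast_1d(np.asarray(pvalues, dtype=float))
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if weights is None:
        w = np.full(p.size, 1.0 / p.size)
    else:
        w = np.atleast_1d(np.asarray(weights, dtype=float))
        if w.size != p.size or np.any(w < 0):
            raise ValueError("weights must be non-negative and match pvalues")
        total = w.sum()
        if not np.isclose(total, 1.0):
            raise ValueError("weights must sum to 1")
    if np.any(p == 0.0):
        warnings.warn("a combined p-value is exactly 0; returning 0", RuntimeWarning)
        return np.inf, 0.0
    small = p < _ACAT_GUARD
    terms = np.where(small, 1.0 / (np.maximum(p, 1e-320) * np.pi),
                     np.tan((0.5 - np.clip(p, _ACAT_GUARD, 1.0)) * np.pi))
    stat = float(np.sum(w * terms))
    if stat > 1e15:
        pval = 1.0 / (np.pi * stat)
    else:
        pval = 0.5 - np.arctan(stat) / np.pi
    return stat, float(np.clip(pval, 0.0, 1.0))


def gbj_pvalue(z, sigma, index_range: str = "auto") -> float:
    """Analytic GBJ p-value (statistic + boundary crossing)."""
    zz = _as_z(z)
    stat = gbj_statistic(zz, sigma, index_range)
    return crossing_pvalue(stat, "GBJ", zz.size, sigma, index_range=index_range)


def ghc_pvalue(z, sigma, t0: float = 0.0) -> float:
    """Analytic GHC p-value (statistic + boundary crossing)."""
    zz = _as_z(z)
    stat = ghc_statistic(zz, sigma, t0)
    return crossing_pvalue(stat, "GHC", zz.size, sigma, t0=t0)


def omni_test(z, sigma, t0: float = 0.0, index_range: str = "auto") -> TestResult:
    """Run GBJ, GHC and MinP and combine their p-values with equal Cauchy
    weights into the omnibus (OMNI) p-value."""
    zz = _as_z(z)
    corr = _as_corr(sigma, zz.size)
    snp_id = z.snp_id if isinstance(z, MultiTraitZ) else ""
    stat_gbj = gbj_statistic(zz, corr, index_range)
    stat_ghc = ghc_statistic(zz, corr, t0)
    c = float(np.max(np.abs(zz)))
    p_gbj = crossing_pvalue(stat_gbj, "GBJ", zz.size, corr, index_range=index_range)
    p_ghc = crossing_pvalue(stat_ghc, "GHC", zz.size, corr, t0=t0)
    p_minp = minp_pvalue(zz, corr)
    omni_stat, p_omni = acat_combine([p_gbj, p_ghc, p_minp])
    return TestResult(
        snp_id=snp_id,
        stat_gbj=stat_gbj,
        stat_ghc=stat_ghc,
        stat_minp=c,
        p_gbj=p_gbj,
        p_ghc=p_ghc,
        p_minp=p_minp,
        omni_stat=float(omni_stat),
        p_omni=p_omni,
    )


# ---------------------------------------------------------------------------
# batched evaluation (simulation / genome-scan path)


def _grid_invert(env_t: np.ndarray, env_v: np.ndarray, stats: np.ndarray) -> np.ndarray:
    """First grid crossing of a (cummax-monotonized) curve, linearly refined."""
    env = np.maximum.accumulate(env_v)
    idx = np.searchsorted(env, stats, side="left")
    out = np.full(stats.shape, np.inf)
    inside = idx < env_t.size
    if np.any(inside):
        ii = idx[inside]
        at_start = ii == 0
        ii = np.clip(ii, 1, env_t.size - 1)
        lo_v, hi_v = env[ii - 1], env[ii]
        frac = np.clip((stats[inside] - lo_v) / np.maximum(hi_v - lo_v, 1e-300), 0.0, 1.0)
        vals = env_t[ii - 1] + frac * (env_t[ii] - env_t[ii - 1])
        vals[at_start] = env_t[0]
        out[inside] = vals
    return out


def batch_pvalues(Z: np.ndarray, sigma, t0: float = 0.0, index_range: str = "auto",
                  tests: Iterable[str] = ("GBJ", "GHC", "MinP", "OMNI"),
                  n_grid: int = 3000) -> dict[str, np.ndarray]:
    """Vectorized p-values for many Z-vectors under one correlation matrix.

    Statistic inversion uses per-rank grids of the (Z-independent) term
    curves, which makes the per-row cost trivial; results agree with the
    scalar path to well below Monte-Carlo resolution.  Returns a dict with
    per-test statistic and p-value arrays.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2:
        raise ValueError("Z must be (n_snps, n_traits)")
    n, K = Z.shape
    corr = _as_corr(sigma, K)
    tests = set(tests)
    if "OMNI" in tests:
        tests |= {"GBJ", "GHC", "MinP"}
    M = np.sort(np.abs(Z), axis=1)[:, ::-1]
    out: dict[str, np.ndarray] = {}

    need_gbj = "GBJ" in tests
    need_ghc = "GHC" in tests

    if need_ghc:
        kk = np.arange(1, K + 1)
        vals = _ghc_process(M, kk[None, :], corr)
        if t0 > 0:
            vals = np.where(M >= t0, vals, -np.inf)
            none = ~np.any(M >= t0, axis=1)
            if np.any(none):
                vals[none, 0] = _ghc_process(M[none, 0], np.ones(none.sum()), corr)
        stat_ghc = np.max(vals, axis=1)
        bounds = np.full((n, K), np.inf)
        for k in range(1, K + 1):
            tgrid = np.linspace(1e-6, 12.0, n_grid)
            g = _ghc_process(tgrid, np.full(tgrid.shape, k), corr)
            bounds[:, k - 1] = _grid_invert(tgrid, g, stat_ghc)
        bounds = np.maximum(bounds, t0)
        bounds = np.minimum.accumulate(bounds, axis=1)
        out["GHC_stat"] = stat_ghc
        out["GHC"] = _crossing_prob_batch(bounds, np.arange(1, K + 1), corr)

    if need_gbj:
        ks = _rank_range(K, index_range)
        term, _ = _gbj_term_vec(M[:, ks - 1], ks[None, :], corr)
        stat_gbj = np.maximum(np.max(term, axis=1), 0.0)
        bounds = np.full((n, ks.size), np.inf)
        for i, k in enumerate(ks):
            zstar = float(ndtri(1.0 - min(k / (2.0 * K), 0.5)))
            tgrid = np.linspace(zstar + 1e-6, 12.0, n_grid)
            g, _ = _gbj_term_vec(tgrid, np.full(tgrid.shape, k), corr)
            bounds[:, i] = _grid_invert(tgrid, g, stat_gbj)
        bounds = np.minimum.accumulate(bounds, axis=1)
        p_gbj = _crossing_prob_batch(bounds, ks, corr)
        p_gbj = np.where(stat_gbj <= 0.0, 1.0, p_gbj)
        out["GBJ_stat"] = stat_gbj
        out["GBJ"] = p_gbj

    if "MinP" in tests:
        c = M[:, 0]
        out["MinP_stat"] = c
        out["MinP"] = np.asarray(bvn.abs_union_prob(c, corr))

    if "OMNI" in tests:
        stats = np.empty(n)
        pvals = np.empty(n)
        trio = np.column_stack([out["GBJ"], out["GHC"], out["MinP"]])
        small = trio < _ACAT_GUARD
        terms = np.where(
            small,
            1.0 / (np.maximum(trio, 1e-320) * np.pi),
            np.tan((0.5 - np.clip(trio, _ACAT_GUARD, 1.0)) * np.pi),
        )
        stats = terms.mean(axis=1)
        pvals = np.where(stats > 1e15, 1.0 / (np.pi * stats), 0.5 - np.arctan(stats) / np.pi)
        out["OMNI_stat"] = stats
        out["OMNI"] = np.clip(pvals, 0.0, 1.0)
    return out


def batch_statistics(Z: np.ndarray, sigma, t0: float = 0.0,
                     index_range: str = "auto") -> dict[str, np.ndarray]:
    """Vectorized GBJ/GHC/MinP statistics (no p-values) for many Z-vectors.

    Useful for Monte-Carlo null distributions, where only the statistic is
    needed and the p-value inversion would dominate the cost.
    """
    Z = np.asarray(Z, dtype=float)
    n, K = Z.shape
    corr = _as_corr(sigma, K)
    M = np.sort(np.abs(Z), axis=1)[:, ::-1]
    kk = np.arange(1, K + 1)
    vals = _ghc_process(M, kk[None, :], corr)
    if t0 > 0:
        vals = np.where(M >= t0, vals, -np.inf)
    ks = _rank_range(K, index_range)
    term, _ = _gbj_term_vec(M[:, ks - 1], ks[None, :], corr)
    return {
        "GHC": np.max(vals, axis=1),
        "GBJ": np.maximum(np.max(term, axis=1), 0.0),
        "MinP": M[:, 0],
    }
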