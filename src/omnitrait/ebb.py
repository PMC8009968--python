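"""Extended beta-binomial (EBB) distribution, Prentice (1986) parameterization.

The EBB approximates the distribution of the exceedance count
S(t) = sum_k 1{|Z_k| >= t} when the Z-scores are correlated: it keeps the
binomial mean n*p while inflating (or deflating) the variance to
n*p*(1-p)*(1 + (n-1)*gamma), where gamma is the common pairwise correlation
of the indicators.  The pmf is built from the Prentice product parameter
theta = gamma/(1-gamma): factors p + j*theta and (1-p) + j*theta over
j = 0..n-1.  Unlike the classical beta-binomial, gamma may be slightly
negative; the pmf stays a proper distribution as long as every factor is
non-negative, i.e. theta >= -min(p, 1-p)/(n-1).
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

from .types import EbbParams

__all__ = ["ebb_pmf", "ebb_logpmf", "ebb_pmf_vector", "dispersion_bounds", "clamp_dispersion"]

_LOG_FLOOR = 1e-300


def _theta(rho):
    """Prentice product parameter theta = rho / (1 - rho) from the indicator
    pairwise correlation rho; the pmf factors are p + j*theta etc."""
    r = np.minimum(np.asarray(rho, dtype=float), 1.0 - 1e-12)
    return r / (1.0 - r)


def dispersion_bounds(n: int, p) -> np.ndarray:
    """Lower validity bound on the correlation parameter rho.

    The pmf factors require theta >= -min(p, 1-p)/(n-1); mapped back through
    theta = rho/(1-rho) this gives the admissible (slightly negative) rho.
    """
    p = np.asarray(p, dtype=float)
    if n <= 1:
        return np.full_like(p, -np.inf)
    tmin = -np.minimum(p, 1.0 - p) / (n - 1)
    return tmin / (1.0 + tmin)


def clamp_dispersion(n: int, p, gamma):
    """Clamp gamma into the EBB validity region; returns (gamma, clamped_any)."""
    lo = dispersion_bounds(n, p)
    g = np.asarray(gamma, dtype=float)
    clamped = np.maximum(g, lo + 1e-14)
    return clamped, bool(np.any(clamped > g))


def ebb_logpmf(s, n: int, p, gamma):
    """Vectorized log pmf; ``gamma`` is the pairwise-correlation parameter.

    Callers are expected to pass gamma inside (or clamped to) the validity
    region; factors that still come out non-positive are floored, which sends
    the corresponding log-mass to -inf rather than producing NaNs.
    """
    s = np.asarray(s)
    p = np.asarray(p, dtype=float)
    gamma = _theta(gamma)
    s_b, p_b, g_b = np.broadcast_arrays(s, p, gamma)
    out = gammaln(n + 1) - gammaln(s_b + 1.0) - gammaln(n - s_b + 1.0)
    out = np.array(out, dtype=float)
    for j in range(n):
        out += np.where(j < s_b, np.log(np.maximum(p_b + j * g_b, _LOG_FLOOR)), 0.0)
        out += np.where(j < n - s_b, np.log(np.maximum(1.0 - p_b + j * g_b, _LOG_FLOOR)), 0.0)
        if j >= 1:
            out -= np.log(np.maximum(1.0 + j * g_b, _LOG_FLOOR))
    return out


def ebb_pmf_vector(n: int, p, gamma) -> np.ndarray:
    """Full pmf over {0..n} for batched (p, gamma); output shape (..., n+1).

    Degenerate success probabilities are handled as point masses at 0 or n.
    """
    p = np.atleast_1d(np.asarray(p, dtype=float))
    gamma = np.broadcast_to(np.asarray(gamma, dtype=float), p.shape).copy()
    shape = p.shape
    out = np.zeros(shape + (n + 1,), dtype=float)
    lo = p <= 1e-15
    hi = p >= 1.0 - 1e-15
    out[lo, 0] = 1.0
    out[hi, n] = 1.0
    mid = ~(lo | hi)
    if np.any(mid):
        pm = p[mid][..., None]
        gm = gamma[mid][..., None]
        s = np.arange(n + 1)
        out[mid] = np.exp(ebb_logpmf(s, n, pm, gm))
        # renormalize away the tiny drift of the product identity in floats
        out[mid] /= np.sum(out[mid], axis=-1, keepdims=True)
    return out


def ebb_pmf(s: int, params: EbbParams) -> float:
    """pmf of the extended beta-binomial at count s.

    Reduces exactly to Binomial(n, p) when dispersion is zero.  Raises if the
    parameters fall outside the validity region (some pmf value would be
    negative).
    """
    n, p, g = params.n_trials, params.mean_prob, params.dispersion
    if not (0 <= s <= n):
        raise ValueError(f"s={s} outside {{0..{n}}}")
    lo = float(dispersion_bounds(n, p))
    if g < lo - 1e-12:
        raise ValueError(
            f"dispersion {g} below the EBB validity bound {lo:.3g} for n={n}, p={p}"
        )
    return float(np.exp(ebb_logpmf(np.asarray(s), n, p, g)))
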