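"""Core value types shared across the package.

The central objects are the per-SNP vector of trait Z-scores and the K x K
between-trait correlation matrix of those Z-scores under the null.  Both are
thin, validated wrappers around numpy arrays so that every downstream routine
can assume well-formed input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MultiTraitZ",
    "TraitCorrelation",
    "CrossingBoundary",
    "EbbParams",
    "GbjTerm",
    "TestResult",
]

#: tolerance on the smallest eigenvalue when checking positive semi-definiteness
PSD_TOL = 1e-8


@dataclass(frozen=True)
class MultiTraitZ:
    """A length-K vector of per-trait Z-scores for one SNP."""

    z: np.ndarray
    snp_id: str = ""

    def __post_init__(self) -> None:
        z = np.atleast_1d(np.asarray(self.z, dtype=float))
        if z.ndim != 1 or z.size < 1:
            raise ValueError("z must be a 1-D vector of length >= 1")
        if not np.all(np.isfinite(z)):
            raise ValueError("all Z-scores must be finite")
        object.__setattr__(self, "z", z)

    @property
    def n_traits(self) -> int:
        return self.z.size


@dataclass(frozen=True)
class TraitCorrelation:
    """K x K correlation matrix of null Z-scores across traits.

    Must be symmetric with unit diagonal, off-diagonals in [-1, 1], and
    positive semi-definite up to a small eigenvalue tolerance.
    """

    sigma: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.sigma, dtype=float)
        if s.ndim != 2 or s.shape[0] != s.shape[1]:
            raise ValueError("sigma must be a square matrix")
        if not np.all(np.isfinite(s)):
            raise ValueError("sigma entries must be finite")
        if not np.allclose(s, s.T, atol=1e-8):
            raise ValueError("sigma must be symmetric")
        if not np.allclose(np.diag(s), 1.0, atol=1e-8):
            raise ValueError("sigma must have unit diagonal")
        if np.any(np.abs(s) > 1 + 1e-12):
            raise ValueError("off-diagonal correlations must lie in [-1, 1]")
        s = (s + s.T) / 2.0
        np.fill_diagonal(s, 1.0)
        if s.shape[0] > 1:
            evmin = float(np.linalg.eigvalsh(s)[0])
            if evmin < -PSD_TOL:
                raise ValueError(
                    f"sigma is not positive semi-definite (min eigenvalue {evmin:.3g})"
                )
        object.__setattr__(self, "sigma", s)

    @property
    def n_traits(self) -> int:
        return self.sigma.shape[0]

    @classmethod
    def exchangeable(cls, n_traits: int, rho: float) -> "TraitCorrelation":
        """Unit-diagonal matrix with a single common off-diagonal value."""
        if n_traits >= 2 and rho < -1.0 / (n_traits - 1) - 1e-12:
            raise ValueError("exchangeable rho below the PSD bound -1/(K-1)")
        s = np.full((n_traits, n_traits), float(rho))
        np.fill_diagonal(s, 1.0)
        return cls(s)

    @classmethod
    def identity(cls, n_traits: int) -> "TraitCorrelation":
        return cls(np.eye(n_traits))

    def offdiag_values(self) -> tuple[np.ndarray, np.ndarray]:
        """Unique off-diagonal values and their (unordered-pair) counts."""
        k = self.n_traits
        iu = np.triu_indices(k, 1)
        vals = self.sigma[iu]
        uniq, counts = np.unique(vals, return_counts=True)
        return uniq, counts


@dataclass(frozen=True)
class CrossingBoundary:
    """Non-increasing vector of magnitude thresholds t_1 >= ... >= t_K >= 0.

    The boundary is crossed when, for some rank k, the k-th largest |Z|
    reaches t_k; equivalently when the exceedance count S(t_k) >= k.
    """

    thresholds: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        t = np.atleast_1d(np.asarray(self.thresholds, dtype=float))
        if np.any(t < 0):
            raise ValueError("thresholds must be non-negative")
        if np.any(np.diff(t) > 1e-10):
            raise ValueError("thresholds must be non-increasing")
        if self.t0 < 0:
            raise ValueError("t0 must be non-negative")
        object.__setattr__(self, "thresholds", t)


@dataclass(frozen=True)
class EbbParams:
    """Extended beta-binomial parameters for the exceedance count S(t).

    ``dispersion`` is the common pairwise correlation of the exceedance
    indicators; the count variance is n*p*(1-p)*(1 + (n-1)*dispersion).
    Slightly negative dispersion is allowed within the validity region of the
    Prentice (1986) parameterization.
    """

    n_trials: int
    mean_prob: float
    dispersion: float = 0.0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be a positive integer")
        if not (0.0 < self.mean_prob < 1.0):
            raise ValueError("mean_prob must lie in (0, 1)")
        if self.variance < -1e-12:
            raise ValueError("implied variance is negative")

    @property
    def variance(self) -> float:
        n, p, g = self.n_trials, self.mean_prob, self.dispersion
        return n * p * (1.0 - p) * (1.0 + (n - 1) * g)


@dataclass(frozen=True)
class GbjTerm:
    """One rank-k term of the GBJ maximum."""

    k: int
    order_stat: float
    mu_hat: float
    lr_value: float
    active: bool

    def __post_init__(self) -> None:
        if self.mu_hat < 0:
            raise ValueError("mu_hat must be >= 0")
        if not self.active and self.lr_value != 0.0:
            raise ValueError("inactive terms must carry lr_value == 0")


@dataclass(frozen=True)
class TestResult:
    """Statistics and p-values of all four tests for one SNP."""

    snp_id: str
    stat_gbj: float
    stat_ghc: float
    stat_minp: float
    p_gbj: float
    p_ghc: float
    p_minp: float
    omni_stat: float
    p_omni: float
    flags: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        for name in ("p_gbj", "p_ghc", "p_minp", "p_omni"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0) or math.isnan(v):
                raise ValueError(f"{name}={v} outside [0, 1]")

    def pvalues(self) -> dict[str, float]:
        return {
            "GBJ": self.p_gbj,
            "GHC": self.p_ghc,
            "MinP": self.p_minp,
            "OMNI": self.p_omni,
        }
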