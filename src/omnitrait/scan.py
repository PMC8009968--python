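"""End-to-end genome scan over per-trait summary statistics.

Pipeline: read each trait file, harmonize alleles and intersect SNPs,
obtain the between-trait correlation (supplied or estimated), run the four
tests per SNP, and report a tidy table with per-test genomic inflation
factors and significance flags keyed to the omnibus p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .io import (
    HarmonizedPanel,
    estimate_trait_correlation,
    harmonize,
    read_correlation_matrix,
    read_trait_summary,
)
from .stats import _p0, batch_pvalues
from .types import TraitCorrelation

__all__ = ["ScanResult", "run_scan", "scan_panel", "genomic_inflation", "select_hits"]

logger = logging.getLogger("omnitrait")

#: conventional genome-wide significance threshold
GENOME_WIDE_ALPHA = 5e-8
#: p-values below this are floored (and flagged) rather than reported as 0
P_FLOOR = 1e-300
_CHI2_MEDIAN_1DF = float(chi2.ppf(0.5, 1))


@dataclass
class ScanResult:
    """Per-SNP test results plus per-test genomic inflation factors."""

    table: pd.DataFrame
    lambda_gc: dict[str, float]
    threshold: float = GENOME_WIDE_ALPHA
    sigma: TraitCorrelation | None = None

    def __post_init__(self) -> None:
        if not np.array_equal(
            self.table["significant"].to_numpy(),
            (self.table["p_OMNI"] < self.threshold).to_numpy(),
        ):
            raise ValueError("significance flags must equal p_OMNI < threshold")
        for name, lam in self.lambda_gc.items():
            if not np.isfinite(lam) or lam <= 0:
                raise ValueError(f"lambda_gc[{name}] must be finite and positive")

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())


def genomic_inflation(pvalues) -> float:
    """Genomic inflation factor: median of the implied 1-df chi-squares over
    the null median 0.4549.  Exactly-uniform quantiles give 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    chisq = chi2.isf(p, df=1)
    return float(np.median(chisq) / _CHI2_MEDIAN_1DF)


def scan_panel(
    panel: HarmonizedPanel,
    sigma: TraitCorrelation,
    threshold: float = GENOME_WIDE_ALPHA,
    t0: float = 0.0,
    index_range: str = "auto",
) -> ScanResult:
    """Run all four tests on an already harmonized panel."""
    res = batch_pvalues(panel.z_matrix, sigma, t0=t0, index_range=index_range)
    out = panel.to_frame()
    for j, name in enumerate(panel.trait_names):
        out[f"p_{name}"] = _p0(np.abs(panel.z_matrix[:, j]))
    lambda_gc = {}
    for test in ("GBJ", "GHC", "MinP", "OMNI"):
        p = np.asarray(res[test], dtype=float)
        floored = p < P_FLOOR
        p = np.maximum(p, P_FLOOR)
        out[f"stat_{test}"] = res[f"{test}_stat"]
        out[f"p_{test}"] = p
        if np.any(floored):
            out[f"p_{test}_floored"] = floored
        lambda_gc[test] = genomic_inflation(p)
    out["significant"] = out["p_OMNI"] < threshold
    logger.info(
        "scan: %d SNPs, %d significant at %.3g", len(out), int(out["significant"].sum()), threshold
    )
    return ScanResult(table=out, lambda_gc=lambda_gc, threshold=threshold, sigma=sigma)


def run_scan(trait_files: list, config: dict) -> ScanResult:
    """Full pipeline from summary files to a ScanResult.

    ``config`` keys:
      column_map: dict (shared) or list of dicts per trait  [required]
      trait_names: optional list of labels
      sigma_file: path to a plain-text correlation matrix, or
      estimate_sigma: True to estimate it from the harmonized panel
      whitelist: optional list (or file path) of independent SNP ids used for
        correlation estimation
      null_z_cap: optional |Z| cap for correlation estimation
      threshold, t0, index_range, reference_trait, drop_palindromic: optional.
    """
    if len(trait_files) < 2:
        raise ValueError("need at least 2 trait files")
    cmaps = config["column_map"]
    if isinstance(cmaps, dict):
        cmaps = [cmaps] * len(trait_files)
    names = config.get("trait_names") or [f"trait{i+1}" for i in range(len(trait_files))]
    traits = [
        read_trait_summary(f, cm, trait_name=nm)
        for f, cm, nm in zip(trait_files, cmaps, names)
    ]
    panel = harmonize(
        traits,
        reference_trait=int(config.get("reference_trait", 0)),
        drop_palindromic=bool(config.get("drop_palindromic", True)),
    )
    if config.get("sigma_file"):
        sigma = read_correlation_matrix(config["sigma_file"])
        if sigma.n_traits != len(traits):
            raise ValueError("correlation matrix dimension does not match trait count")
    elif config.get("estimate_sigma"):
        wl = config.get("whitelist")
        if isinstance(wl, str):
            wl = [line.strip() for line in open(wl) if line.strip()]
        sigma = estimate_trait_correlation(
            panel, null_z_cap=config.get("null_z_cap"), snp_whitelist=wl
        )
    else:
        raise ValueError("config must provide 'sigma_file' or set 'estimate_sigma'")
    return scan_panel(
        panel,
        sigma,
        threshold=float(config.get("threshold", GENOME_WIDE_ALPHA)),
        t0=float(config.get("t0", 0.0)),
        index_range=config.get("index_range", "auto"),
    )


def select_hits(result: ScanResult, independent_snps: list[str] | None = None) -> pd.DataFrame:
    """Significant SNPs (p_OMNI below the threshold), optionally restricted to
    an independent-SNP list, sorted by ascending omnibus p-value."""
    tab = result.table
    hits = tab.loc[tab["p_OMNI"] < result.threshold]
    if independent_snps is not None:
        keep = set(independent_snps)
        hits = hits.loc[hits["snp"].isin(keep)]
    return hits.sort_values("p_OMNI", kind="mergesort").reset_index(drop=True)
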