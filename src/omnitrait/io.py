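"""Reading and harmonizing per-trait GWAS summary statistics.

Each trait arrives as a whitespace/tab-delimited text file (optionally
gzip-compressed) with a header.  A column map names the SNP identifier,
chromosome, position and allele columns plus exactly one Z-score encoding:
a ``z`` column, a ``beta``/``se`` pair, or a two-sided ``p`` with an effect
``direction``.  Traits are merged on shared SNPs, effect alleles are aligned
to a reference trait (flipping Z signs where the coding is swapped), and the
between-trait correlation of null Z-scores is estimated as the sample
correlation over (approximately) independent SNPs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .types import TraitCorrelation

__all__ = [
    "TraitSummary",
    "HarmonizedPanel",
    "read_trait_summary",
    "harmonize",
    "estimate_trait_correlation",
    "read_correlation_matrix",
    "write_correlation_matrix",
]

logger = logging.getLogger("omnitrait")

_VALID_ALLELES = {"A", "C", "G", "T"}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class TraitSummary:
    """Parsed summary statistics for one trait: one Z-score per SNP."""

    trait_name: str
    table: pd.DataFrame  # columns: snp, chrom, pos, effect_allele, other_allele, z
    n_skipped: int = 0

    def __post_init__(self) -> None:
        if self.table["snp"].duplicated().any():
            raise ValueError(f"duplicate SNP ids in trait {self.trait_name!r}")


@dataclass
class HarmonizedPanel:
    """SNP x trait matrix of allele-aligned Z-scores (complete cases only)."""

    snp_ids: list[str]
    chrom: list[str]
    pos: np.ndarray
    z_matrix: np.ndarray  # (n_snps, n_traits)
    trait_names: list[str]
    flip_log: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.z_matrix.shape != (len(self.snp_ids), len(self.trait_names)):
            raise ValueError("z_matrix shape inconsistent with snp/trait lists")
        if np.any(~np.isfinite(self.z_matrix)):
            raise ValueError("harmonized panel must have no missing Z entries")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"snp": self.snp_ids, "chrom": self.chrom, "pos": self.pos})
        for j, name in enumerate(self.trait_names):
            out[f"z_{name}"] = self.z_matrix[:, j]
        return out


def read_trait_summary(path, column_map: dict, trait_name: str | None = None) -> TraitSummary:
    """Parse one per-trait summary file into Z-scores.

    ``column_map`` maps the logical names snp, chrom, pos, effect_allele,
    other_allele plus one of: {z}, {beta, se}, {p, direction} to the column
    headers in the file.  Malformed rows (non-numeric scores, se <= 0, p
    outside (0, 1], invalid alleles) are skipped and counted, not fatal.
    """
    mandatory = ["snp", "chrom", "pos", "effect_allele", "other_allele"]
    encodings = [("z",), ("beta", "se"), ("p", "direction")]
    enc = [e for e in encodings if all(k in column_map for k in e)]
    if len(enc) != 1:
        raise ValueError(
            "column_map must declare exactly one score encoding: "
            "'z', 'beta'+'se', or 'p'+'direction'"
        )
    enc = enc[0]
    missing = [k for k in mandatory if k not in column_map]
    if missing:
        raise ValueError(f"column_map missing mandatory keys: {missing}")

    df = pd.read_csv(path, sep=r"\s+", dtype=str, compression="infer")
    need = [column_map[k] for k in mandatory + list(enc)]
    absent = [c for c in need if c not in df.columns]
    if absent:
        raise ValueError(f"{path}: declared columns not in file header: {absent}")

    out = pd.DataFrame(
        {
            "snp": df[column_map["snp"]].astype(str),
            "chrom": df[column_map["chrom"]].astype(str),
            "pos": pd.to_numeric(df[column_map["pos"]], errors="coerce"),
            "effect_allele": df[column_map["effect_allele"]].str.upper(),
            "other_allele": df[column_map["other_allele"]].str.upper(),
        }
    )
    bad = out["pos"].isna() | ~out["effect_allele"].isin(_VALID_ALLELES) | ~out[
        "other_allele"
    ].isin(_VALID_ALLELES)

    if enc == ("z",):
        z = pd.to_numeric(df[column_map["z"]], errors="coerce")
        bad |= ~np.isfinite(z)
    elif enc == ("beta", "se"):
        beta = pd.to_numeric(df[column_map["beta"]], errors="coerce")
        se = pd.to_numeric(df[column_map["se"]], errors="coerce")
        bad |= ~np.isfinite(beta) | ~np.isfinite(se) | (se <= 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = beta / se
    else:
        pval = pd.to_numeric(df[column_map["p"]], errors="coerce")
        direction = pd.to_numeric(df[column_map["direction"]], errors="coerce")
        bad |= ~np.isfinite(pval) | (pval <= 0) | (pval > 1) | ~np.isfinite(direction)
        with np.errstate(invalid="ignore"):
            z = np.sign(direction) * -ndtri(np.clip(pval, 1e-320, 1.0) / 2.0)

    out["z"] = z
    n_skipped = int(bad.sum())
    if n_skipped:
        logger.info("%s: skipped %d malformed rows", path, n_skipped)
    out = out.loc[~bad].reset_index(drop=True)
    out["pos"] = out["pos"].astype(np.int64)
    name = trait_name if trait_name is not None else str(path)
    return TraitSummary(trait_name=name, table=out, n_skipped=n_skipped)


def _classify_alleles(ref_ea, ref_oa, ea, oa):
    """Allele pair relation to the reference: 'same', 'swap', or 'drop'."""
    if (ea, oa) == (ref_ea, ref_oa):
        return "same"
    if (ea, oa) == (ref_oa, ref_ea):
        return "swap"
    cea, coa = _COMPLEMENT[ea], _COMPLEMENT[oa]
    if (cea, coa) == (ref_ea, ref_oa):
        return "same"  # other strand, same orientation
    if (cea, coa) == (ref_oa, ref_ea):
        return "swap"
    return "drop"


def harmonize(
    traits: list[TraitSummary],
    reference_trait: int = 0,
    drop_palindromic: bool = True,
) -> HarmonizedPanel:
    """Align per-trait Z-scores on shared SNPs with a common effect allele.

    SNPs absent from any trait are dropped (complete-case intersection).
    For non-reference traits whose allele pair is swapped relative to the
    reference (directly or on the opposite strand) the Z-score is negated.
    Strand-ambiguous palindromic SNPs (A/T, C/G) are dropped by default since
    their orientation cannot be resolved without frequencies.  Every flip and
    drop is recorded in ``flip_log``.
    """
    if len(traits) < 2:
        raise ValueError("need at least 2 traits to harmonize")
    ref = traits[reference_trait]
    shared = set(ref.table["snp"])
    for tr in traits:
        shared &= set(tr.table["snp"])
    if not shared:
        raise ValueError("no SNPs shared across all traits")

    ref_tab = ref.table.set_index("snp")
    tabs = [tr.table.set_index("snp") for tr in traits]
    order = [s for s in ref.table["snp"] if s in shared]

    log_rows = []
    keep_ids, chroms, poss, rows = [], [], [], []
    for snp in order:
        ref_ea = ref_tab.at[snp, "effect_allele"]
        ref_oa = ref_tab.at[snp, "other_allele"]
        if drop_palindromic and (ref_ea, ref_oa) in _PALINDROMIC:
            log_rows.append((snp, "*", "palindromic_drop"))
            continue
        zrow = np.empty(len(traits))
        ok = True
        for j, tab in enumerate(tabs):
            ea, oa = tab.at[snp, "effect_allele"], tab.at[snp, "other_allele"]
            rel = _classify_alleles(ref_ea, ref_oa, ea, oa)
            if rel == "drop":
                log_rows.append((snp, traits[j].trait_name, "allele_mismatch_drop"))
                ok = False
                break
            zj = float(tab.at[snp, "z"])
            if rel == "swap":
                zj = -zj
                log_rows.append((snp, traits[j].trait_name, "flip"))
            zrow[j] = zj
        if ok:
            keep_ids.append(snp)
            chroms.append(str(ref_tab.at[snp, "chrom"]))
            poss.append(int(ref_tab.at[snp, "pos"]))
            rows.append(zrow)

    dropped = (len(ref.table) - len(keep_ids))
    logger.info("harmonize: kept %d SNPs, dropped/filtered %d", len(keep_ids), dropped)
    if not keep_ids:
        raise ValueError("harmonization left no usable SNPs")
    flip_log = pd.DataFrame(log_rows, columns=["snp", "trait", "action"])
    return HarmonizedPanel(
        snp_ids=keep_ids,
        chrom=chroms,
        pos=np.asarray(poss, dtype=np.int64),
        z_matrix=np.vstack(rows),
        trait_names=[tr.trait_name for tr in traits],
        flip_log=flip_log,
    )


def estimate_trait_correlation(
    panel: HarmonizedPanel,
    null_z_cap: float | None = None,
    snp_whitelist: list[str] | None = None,
) -> TraitCorrelation:
    """Between-trait correlation from the sample correlation of null Z-scores.

    Under the global null the Z-score vectors are MVN(0, sigma), so the
    Pearson correlation across independent SNPs is a consistent estimate of
    sigma.  ``snp_whitelist`` restricts to a user-supplied independent-SNP
    list (standing in for LD pruning); ``null_z_cap`` optionally excludes
    SNPs whose largest |Z| exceeds the cap, guarding against strong signals
    (default: no cap).  The result is symmetrized with unit diagonal and
    eigenvalue-clipped to the nearest positive semi-definite matrix.
    """
    zm = panel.z_matrix
    mask = np.ones(panel.n_snps, dtype=bool)
    if snp_whitelist is not None:
        wl = set(snp_whitelist)
        mask &= np.fromiter((s in wl for s in panel.snp_ids), bool, panel.n_snps)
    if null_z_cap is not None:
        mask &= np.max(np.abs(zm), axis=1) <= null_z_cap
    zm = zm[mask]
    if zm.shape[0] < 2:
        raise ValueError("fewer than 2 usable SNPs for correlation estimation")
    if zm.shape[0] < 1000:
        warnings.warn(
            f"only {zm.shape[0]} SNPs used for correlation estimation; "
            "estimates below ~1e3 SNPs are unstable",
            RuntimeWarning,
        )
    with np.errstate(invalid="ignore"):
        s = np.corrcoef(zm, rowvar=False)
    s = np.where(np.isfinite(s), s, 0.0)
    s = (s + s.T) / 2.0
    np.fill_diagonal(s, 1.0)
    evals, evecs = np.linalg.eigh(s)
    if evals[0] < 0:
        s = (evecs * np.clip(evals, 0.0, None)) @ evecs.T
        d = np.sqrt(np.clip(np.diag(s), 1e-12, None))
        s = s / np.outer(d, d)
        s = (s + s.T) / 2.0
        np.fill_diagonal(s, 1.0)
    return TraitCorrelation(np.clip(s, -1.0, 1.0))


def read_correlation_matrix(path) -> TraitCorrelation:
    """Plain-text square correlation matrix, optional header row of names."""
    first = pd.read_csv(path, sep=r"\s+", header=None, nrows=1)
    has_header = first.iloc[0].apply(
        lambda v: isinstance(v, str) and not v.replace(".", "").replace("-", "").isdigit()
    ).any()
    mat = pd.read_csv(path, sep=r"\s+", header=0 if has_header else None)
    return TraitCorrelation(mat.to_numpy(dtype=float))


def write_correlation_matrix(corr: TraitCorrelation, path, trait_names=None) -> None:
    df = pd.DataFrame(corr.sigma, columns=trait_names)
    df.to_csv(path, sep="\t", index=False, header=trait_names is not None)
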