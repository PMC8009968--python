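import numpy as np
import pytest
from scipy.stats import norm

from omnitrait import LIPID_CORR, TraitCorrelation


@pytest.fixture(scope="session")
def lipid_corr() -> TraitCorrelation:
    """3-trait HDL/LDL/TG Z-score correlation matrix."""
    return LIPID_CORR


@pytest.fixture(scope="session")
def lipid_snp_z() -> np.ndarray:
    """|Z| vector of the strongest lipid pleiotropy example SNP, derived from
    its per-trait two-sided p-values (5.53e-8, 1.94e-3, 1.01e-7)."""
    p = np.array([5.53e-8, 1.94e-3, 1.01e-7])
    return norm.isf(p / 2)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20210317)


def make_trait_file(tmp_path, name, rows, columns="snp chr pos ea oa beta se"):
    """Write a small whitespace-delimited summary file and return its path."""
    path = tmp_path / f"{name}.txt"
    lines = [columns.replace(" ", "\t")]
    for row in rows:
        lines.append("\t".join(str(v) for v in row))
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture()
def beta_se_map():
    return {
        "snp": "snp", "chrom": "chr", "pos": "pos",
        "effect_allele": "ea", "other_allele": "oa", "beta": "beta", "se": "se",
    }
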