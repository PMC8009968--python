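"""Genome-scan pipeline, inflation factor and CLI plumbing."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import omnitrait.io as oio
from omnitrait import (
    LIPID_CORR,
    SimulationSpec,
    draw_z,
    genomic_inflation,
    run_scan,
    scan_panel,
    select_hits,
)
from omnitrait.cli import main as cli_main
from omnitrait.io import HarmonizedPanel
from tests.conftest import make_trait_file


class TestGenomicInflation:
    def test_uniform_quantiles_give_one(self):
        n = 100_000
        p = (np.arange(n) + 0.5) / n
        assert genomic_inflation(p) == pytest.approx(1.0, abs=1e-3)

    def test_halved_pvalues_inflate(self):
        n = 10_000
        p = (np.arange(n) + 0.5) / n
        assert genomic_inflation(p / 2) > 1.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            genomic_inflation([])


def _null_panel(n_snps, seed=0):
    spec = SimulationSpec(3, LIPID_CORR, 0.0, replicates=n_snps, seed=seed)
    Z = draw_z(spec)
    return HarmonizedPanel(
        snp_ids=[f"rs{i}" for i in range(n_snps)],
        chrom=["1"] * n_snps,
        pos=np.arange(n_snps, dtype=np.int64),
        z_matrix=Z,
        trait_names=["HDL", "LDL", "TG"],
    )


class TestScanPanel:
    def test_null_panel_clean(self):
        res = scan_panel(_null_panel(500, seed=3), LIPID_CORR)
        assert len(res.table) == 500  # no silent drops
        assert res.n_significant == 0
        for lam in res.lambda_gc.values():
            assert 0.8 <= lam <= 1.25

    def test_lipid_example_snp_flagged(self, lipid_snp_z):
        panel = _null_panel(20, seed=4)
        panel.z_matrix[0] = lipid_snp_z
        res = scan_panel(panel, LIPID_CORR)
        row = res.table.iloc[0]
        assert row["significant"]
        assert row["p_OMNI"] == pytest.approx(3.05e-10, rel=0.1)
        hits = select_hits(res)
        assert hits.iloc[0]["snp"] == "rs0"

    def test_deterministic_rerun(self):
        panel = _null_panel(100, seed=5)
        a = scan_panel(panel, LIPID_CORR).table
        b = scan_panel(panel, LIPID_CORR).table
        pd.testing.assert_frame_equal(a, b)


class TestSelectHits:
    def test_threshold_one_returns_sorted_all(self):
        res = scan_panel(_null_panel(50, seed=6), LIPID_CORR, threshold=1.1)
        hits = select_hits(res)
        assert len(hits) == 50
        assert hits["p_OMNI"].is_monotonic_increasing

    def test_whitelist_restriction(self):
        res = scan_panel(_null_panel(50, seed=7), LIPID_CORR, threshold=1.1)
        hits = select_hits(res, independent_snps=["rs1", "rs2"])
        assert set(hits["snp"]) == {"rs1", "rs2"}

    def test_empty_hits(self):
        res = scan_panel(_null_panel(50, seed=8), LIPID_CORR)
        assert select_hits(res).empty


def _write_trait_files(tmp_path, panel):
    paths = []
    for j, name in enumerate(panel.trait_names):
        rows = [
            (snp, c, p, "A", "G", f"{z * 0.1:.10g}", 0.1)
            for snp, c, p, z in zip(
                panel.snp_ids, panel.chrom, panel.pos, panel.z_matrix[:, j]
            )
        ]
        paths.append(make_trait_file(tmp_path, name, rows))
    return paths


class TestRunScan:
    def test_pipeline_from_files(self, tmp_path, beta_se_map):
        panel = _null_panel(80, seed=9)
        paths = _write_trait_files(tmp_path, panel)
        sigma_path = tmp_path / "sigma.txt"
        oio.write_correlation_matrix(LIPID_CORR, sigma_path)
        res = run_scan(
            paths,
            {
                "column_map": beta_se_map,
                "trait_names": ["HDL", "LDL", "TG"],
                "sigma_file": str(sigma_path),
            },
        )
        assert len(res.table) == 80
        np.testing.assert_allclose(
            res.table[["z_HDL", "z_LDL", "z_TG"]].to_numpy(), panel.z_matrix, atol=1e-8
        )

    def test_single_shared_snp(self, tmp_path, beta_se_map):
        rows1 = [("rs1", 1, 100, "A", "G", 0.2, 0.1), ("rs2", 1, 200, "C", "A", 0.1, 0.1)]
        rows2 = [("rs1", 1, 100, "A", "G", 0.1, 0.1)]
        p1 = make_trait_file(tmp_path, "x", rows1)
        p2 = make_trait_file(tmp_path, "y", rows2)
        sigma_path = tmp_path / "s.txt"
        sigma_path.write_text("1.0 0.1\n0.1 1.0\n")
        res = run_scan([p1, p2], {"column_map": beta_se_map, "sigma_file": str(sigma_path)})
        assert len(res.table) == 1


class TestCli:
    def test_test_one_matches_library(self, tmp_path, capsys, lipid_snp_z):
        sigma_path = tmp_path / "sigma.txt"
        oio.write_correlation_matrix(LIPID_CORR, sigma_path)
        pstr = "5.53e-8,1.94e-3,1.01e-7"
        rc = cli_main(["test-one", "--p", pstr, "--sigma", str(sigma_path),
                       "--snp", "rs7307053", "--json"])
        assert rc == 0
        import json

        out = json.loads(capsys.readouterr().out)
        assert out["p_OMNI"] == pytest.approx(3.05e-10, rel=0.1)

    def test_inflation_command(self, tmp_path, capsys):
        p = (np.arange(1000) + 0.5) / 1000
        pfile = tmp_path / "p.txt"
        np.savetxt(pfile, p)
        assert cli_main(["inflation", str(pfile)]) == 0
        lam = float(capsys.readouterr().out.strip())
        assert lam == pytest.approx(1.0, abs=0.02)

    def test_simulate_command(self, tmp_path):
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text(
            "n_traits: [2]\nrho: [0.1]\nn_nonzero: [0]\nreplicates: 100\nseed: 1\n"
        )
        out = tmp_path / "rates.tsv"
        assert cli_main(["simulate", "--config", str(cfg), "--out", str(out)]) == 0
        table = pd.read_csv(out, sep="\t")
        assert len(table) == 4

    def test_scan_command(self, tmp_path, beta_se_map):
        panel = _null_panel(30, seed=11)
        paths = _write_trait_files(tmp_path, panel)
        sigma_path = tmp_path / "sigma.txt"
        oio.write_correlation_matrix(LIPID_CORR, sigma_path)
        import yaml

        cfg = tmp_path / "scan.yaml"
        cfg.write_text(yaml.safe_dump({"column_map": beta_se_map,
                                       "trait_names": ["HDL", "LDL", "TG"]}))
        out = tmp_path / "scan.tsv"
        rc = cli_main([
            "scan", "--trait", str(paths[0]), "--trait", str(paths[1]),
            "--trait", str(paths[2]), "--config", str(cfg),
            "--sigma", str(sigma_path), "--out", str(out),
        ])
        assert rc == 0
        assert len(pd.read_csv(out, sep="\t")) == 30
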