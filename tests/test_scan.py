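import numpy as np
import pytest
import yaml
from click.testing import CliRunner

from sweepscan.cli import main as cli_main
from sweepscan.config import RunConfig
from sweepscan.evidence import EvidenceRuleSet, classify_all, query_region
from sweepscan.io import sample_pop_map_for, write_regions, write_vcf
from sweepscan.panel import RegionSpec
from sweepscan.ranking import RankConfig, neglog_rank, top_cutoff, window_proportion
from sweepscan.scan import scan_panel
from sweepscan.simulate import SweepSimConfig, simulate_panel
from sweepscan.stats_table import SnpStatTable


@pytest.fixture(scope="module")
def two_pop_panel():
    cfg = SweepSimConfig(n_haploid=120, length_bp=400_000, mu=2e-7,
                         n_pops=2, split_time=120, sample_size=60, seed=21)
    panel, _ = simulate_panel(cfg)
    return panel


@pytest.fixture(scope="module")
def two_pop_table(two_pop_panel):
    return scan_panel(two_pop_panel)


class TestScanPanel:
    def test_expected_columns_present(self, two_pop_table):
        cols = set(two_pop_table.df.columns)
        for pop in ("POP1", "POP2"):
            for c in (f"freq_{pop}", f"tajd_{pop}", f"neglogq_tajd_{pop}",
                      f"ihs_std_{pop}", f"wprop_ihs_{pop}",
                      f"neglogq_ihs_{pop}", f"neglogp_ihs_{pop}"):
                assert c in cols, c
        for c in ("fst_POP1_POP2", "wprop_fst_POP1_POP2",
                  "neglogq_fst_POP1_POP2", "neglogp_fst_POP1_POP2",
                  "fst_top1_POP1_POP2", "xpehh_POP1_POP2",
                  "neglogp_xpehh_POP1_POP2"):
            assert c in cols, c

    def test_row_count_matches_panel(self, two_pop_panel, two_pop_table):
        assert len(two_pop_table) == two_pop_panel.n_variants

    def test_rank_scores_consistent_with_direct_recompute(self, two_pop_table):
        df = two_pop_table.df
        np.testing.assert_allclose(
            df["neglogq_tajd_POP1"].to_numpy(),
            neglog_rank(df["tajd_POP1"].to_numpy(), "low"), equal_nan=True)
        np.testing.assert_allclose(
            df["neglogp_fst_POP1_POP2"].to_numpy(),
            neglog_rank(df["fst_POP1_POP2"].to_numpy(), "high"),
            equal_nan=True)

    def test_window_proportion_consistent(self, two_pop_table):
        df = two_pop_table.df
        std = df["ihs_std_POP1"].to_numpy()
        exp = window_proportion(std, 25, threshold=2.0, absolute=True)
        np.testing.assert_allclose(df["wprop_ihs_POP1"].to_numpy(), exp,
                                   equal_nan=True)

    def test_top1_flags_match_cutoff(self, two_pop_table):
        df = two_pop_table.df
        fst = df["fst_POP1_POP2"].to_numpy()
        cut = top_cutoff(fst, 0.01)
        with np.errstate(invalid="ignore"):
            exp = np.isfinite(fst) & (fst > cut)
        np.testing.assert_array_equal(
            df["fst_top1_POP1_POP2"].to_numpy().astype(bool), exp)
        frac = exp.sum() / np.isfinite(fst).sum()
        assert frac <= 0.01

    def test_statistic_subset_skips_others(self, two_pop_panel):
        t = scan_panel(two_pop_panel, statistics=("tajd",))
        cols = set(t.df.columns)
        assert "tajd_POP1" in cols and "ihs_std_POP1" not in cols

    def test_single_pop_skips_xpehh(self, two_pop_panel, caplog):
        sub = two_pop_panel.subset_pop("POP1")
        import logging
        with caplog.at_level(logging.INFO):
            t = scan_panel(sub, statistics=("xpehh",))
        assert not any(c.startswith("xpehh") for c in t.df.columns)
        assert any("XP-EHH" in r.message for r in caplog.records)

    def test_table_round_trips_through_tsv(self, two_pop_table, tmp_path):
        p = tmp_path / "stats.tsv"
        two_pop_table.to_tsv(p)
        back = SnpStatTable.from_tsv(p)
        for col in two_pop_table.df.columns:
            a = two_pop_table.df[col]
            b = back.df[col]
            if a.dtype.kind == "f":
                np.testing.assert_allclose(a, b, equal_nan=True)
            else:
                assert (a == b).all()

    def test_region_query_on_scan_output(self, two_pop_table):
        ev = query_region(two_pop_table, RegionSpec("R", "1", 0.2),
                          width_bp=400_000)
        assert ev.n_snps > 0
        assert set(ev.max_neglogq) <= {"ihs", "tajd", "fst"}
        classify_all([ev], EvidenceRuleSet(family="HAPMAP_STYLE"))


class TestRunConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = RunConfig(vcf="x.vcf", sample_pop_map={"S0": "A"},
                        statistics=["fst", "tajd"], out_dir="out", seed=3)
        path = tmp_path / "run.yaml"
        cfg.to_yaml(path)
        back = RunConfig.from_yaml(path)
        assert back.vcf == "x.vcf"
        assert back.sample_pop_map == {"S0": "A"}
        assert back.statistics == ["fst", "tajd"]
        assert back.rank == RankConfig()

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "run.yaml"
        path.write_text(yaml.safe_dump({"vcf": "x.vcf", "bogus": 1}))
        with pytest.raises(ValueError, match="bogus"):
            RunConfig.from_yaml(path)


class TestCli:
    def _write_inputs(self, tmp_path):
        cfg = SweepSimConfig(n_haploid=80, length_bp=150_000, mu=2e-7,
                             n_pops=2, split_time=80, sample_size=40, seed=33)
        panel, _ = simulate_panel(cfg)
        vcf = tmp_path / "panel.vcf"
        write_vcf(panel, vcf)
        pop_map = tmp_path / "pops.tsv"
        with open(pop_map, "w") as fh:
            for s, p in sample_pop_map_for(panel).items():
                fh.write(f"{s}\t{p}\n")
        return vcf, pop_map

    def test_scan_then_regions(self, tmp_path):
        vcf, pop_map = self._write_inputs(tmp_path)
        runner = CliRunner()
        stats = tmp_path / "stats.tsv"
        r = runner.invoke(cli_main, ["scan", "--vcf", str(vcf),
                                     "--pop-map", str(pop_map),
                                     "--out", str(stats)])
        assert r.exit_code == 0, r.output
        assert stats.exists()
        regions = tmp_path / "regions.tsv"
        write_regions([RegionSpec("MID", "1", 0.075)], regions)
        r2 = runner.invoke(cli_main, ["regions", "--stats", str(stats),
                                      "--regions", str(regions),
                                      "--width-bp", "150000",
                                      "--out-dir", str(tmp_path / "rep")])
        assert r2.exit_code == 0, r2.output
        assert (tmp_path / "rep" / "evidence_hapmap_style.tsv").exists()

    def test_simulate_command_writes_vcf_and_truth(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "sim.vcf"
        r = runner.invoke(cli_main, ["simulate", "--seed", "2",
                                     "--n-haploid", "60",
                                     "--length-bp", "80000",
                                     "--s", "0.05",
                                     "--sample-size", "40",
                                     "--out", str(out)])
        assert r.exit_code == 0, r.output
        assert out.exists()
        truth = (tmp_path / "sim.truth.tsv").read_text()
        assert "focal_position" in truth

    def test_report_command_concordance(self, tmp_path):
        from sweepscan.io import (load_hapmap_evidence, load_hgdp_evidence,
                                  write_evidence_tsv)
        hap = classify_all(load_hapmap_evidence(),
                           EvidenceRuleSet(family="HAPMAP_STYLE"))
        hgdp = classify_all(load_hgdp_evidence(),
                            EvidenceRuleSet(family="HGDP_STYLE"))
        a, b = tmp_path / "hap.tsv", tmp_path / "hgdp.tsv"
        write_evidence_tsv(hap, a)
        write_evidence_tsv(hgdp, b)
        runner = CliRunner()
        r = runner.invoke(cli_main, ["report", "--hapmap", str(a),
                                     "--hgdp", str(b),
                                     "--out-dir", str(tmp_path / "rep")])
        assert r.exit_code == 0, r.output
        assert (tmp_path / "rep" / "concordance.tsv").exists()
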