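"""File formats, the pipeline driver and the command-line layer."""

import numpy as np
import pandas as pd
import pytest

from gsmrpipe import PipelineConfig, SimConfig, build_grm, run_pipeline
from gsmrpipe import io
from gsmrpipe.io import FormatError


class TestPlinkRoundTrip:
    def test_bed_round_trip_exact(self, tiny_panel, tmp_path):
        io.write_plink(tiny_panel, tmp_path / "p")
        back = io.read_plink(tmp_path / "p", x_chrom=tiny_panel.x_chrom)
        np.testing.assert_array_equal(back.dosages, tiny_panel.dosages)
        assert back.samples == tiny_panel.samples
        pd.testing.assert_frame_equal(
            back.markers[["id", "chrom", "bp", "a1", "a2"]],
            tiny_panel.markers[["id", "chrom", "bp", "a1", "a2"]],
        )

    def test_truncated_bed_raises_format_error(self, tiny_panel, tmp_path):
        io.write_plink(tiny_panel, tmp_path / "p")
        raw = (tmp_path / "p.bed").read_bytes()
        (tmp_path / "p.bed").write_bytes(raw[:-10])
        with pytest.raises(FormatError):
            io.read_plink(tmp_path / "p")

    def test_bad_magic_raises(self, tiny_panel, tmp_path):
        io.write_plink(tiny_panel, tmp_path / "p")
        raw = bytearray((tmp_path / "p.bed").read_bytes())
        raw[0] = 0x00
        (tmp_path / "p.bed").write_bytes(bytes(raw))
        with pytest.raises(FormatError):
            io.read_plink(tmp_path / "p")

    def test_maf_filter_removes_rare_snp(self, tmp_path):
        from conftest import make_panel

        dos = np.array([[1] + [0] * 9, *[[0] * 10] * 99], dtype=np.int8).reshape(100, -1)
        dos = np.zeros((100, 2), dtype=np.int8)
        dos[0, 0] = 1                       # MAF 0.5% at SNP 0
        dos[:50, 1] = 1                     # MAF 25% at SNP 1
        panel = make_panel(dos)
        io.write_plink(panel, tmp_path / "rare")
        back = io.read_plink(tmp_path / "rare", maf_filter=0.01)
        assert list(back.markers["id"]) == ["s1"]

    def test_missing_genotypes_mean_imputed(self, tmp_path):
        from conftest import make_panel

        dos = np.tile([0, 1, 2, 1], (1, 1)).T.astype(np.int8)
        panel = make_panel(dos)
        io.write_plink(panel, tmp_path / "m")
        raw = bytearray((tmp_path / "m.bed").read_bytes())
        raw[3] = (raw[3] & ~0b11) | 0b01    # first sample of SNP 0 -> missing
        (tmp_path / "m.bed").write_bytes(bytes(raw))
        back = io.read_plink(tmp_path / "m")
        assert back.dosages[0, 0] == 1      # mean of (1, 2, 1) rounds to 1


def test_panel_tsv_round_trip(tiny_panel, tmp_path):
    io.write_panel_tsv(tiny_panel, tmp_path / "panel.tsv.gz")
    back = io.read_panel_tsv(tmp_path / "panel.tsv.gz", x_chrom=tiny_panel.x_chrom)
    np.testing.assert_array_equal(back.dosages, tiny_panel.dosages)
    assert back.samples == tiny_panel.samples


def test_phenotype_and_truth_round_trip(tiny_panel, tiny_config, tmp_path):
    from gsmrpipe import simulate_traits

    phenos, truth = simulate_traits(tiny_panel, tiny_config)
    io.write_phenotype(phenos["exposure"], tmp_path / "e.tsv")
    back = io.read_phenotype(tmp_path / "e.tsv", "exposure")
    np.testing.assert_allclose(back.to_numpy(), phenos["exposure"].to_numpy())
    io.write_truth(truth, tmp_path / "truth.tsv")
    tf = io.read_truth(tmp_path / "truth.tsv")
    assert tf.attrs["b_xy_true"] == truth.b_xy_true
    assert set(tf.loc[tf["role"] == "pleiotropic", "id"]) == set(truth.pleiotropic["id"])


def test_ma_round_trip_with_position_merge(tiny_panel, tmp_path):
    mk = tiny_panel.markers
    tab = pd.DataFrame({
        "SNP": mk["id"], "A1": mk["a1"], "A2": mk["a2"], "freq": mk["freq"],
        "b": 0.01, "se": 0.005, "p": 0.5, "n": 100,
    })
    io.write_ma(tab, tmp_path / "x.ma")
    back = io.read_ma(tmp_path / "x.ma", tiny_panel)
    assert {"Chr", "bp", "n"} <= set(back.columns)
    assert (back["Chr"].to_numpy() == mk["chrom"].to_numpy()).all()


def test_grm_gcta_round_trip(tiny_panel, tmp_path):
    grm = build_grm(tiny_panel)
    io.write_grm_gcta(grm, tmp_path / "g")
    back = io.read_grm_gcta(tmp_path / "g")
    np.testing.assert_allclose(back.matrix, grm.matrix, atol=1e-6)
    assert back.sample_ids == grm.sample_ids
    assert back.n_snps_used == grm.n_snps_used


GFF3 = """##gff-version 3
1\tensembl\tgene\t4000\t6000\t.\t+\t.\tID=gene:X1;Name=ABCA1
1\tensembl\tmRNA\t4000\t6000\t.\t+\t.\tID=tx:X1.1;Parent=gene:X1
2\tensembl\tgene\t100\t900\t.\t-\t.\tID=gene:X2;gene_name=CASP8
2\tensembl\tgene\t5000\t5600\t.\t-\t.\tID=gene:X3
"""


def test_gff3_reader_extracts_named_genes(tmp_path):
    p = tmp_path / "genes.gff3"
    p.write_text(GFF3)
    genes = io.read_genes(p)
    assert len(genes) == 3                     # mRNA line skipped
    named = genes[genes["symbol"] != ""]
    assert set(named["symbol"]) == {"ABCA1", "CASP8"}
    row = genes.set_index("symbol").loc["ABCA1"]
    assert (row["start"], row["end"]) == (4000, 6000)


def test_bed_reader_converts_to_one_based(tmp_path):
    p = tmp_path / "genes.bed"
    p.write_text("1\t3999\t6000\tABCA1\n2\t99\t900\tCASP8\n")
    genes = io.read_genes(p)
    assert genes.iloc[0]["start"] == 4000
    assert genes.iloc[0]["end"] == 6000


class TestPipeline:
    @pytest.fixture(scope="class")
    def small_run(self):
        cfg = PipelineConfig(
            sim=SimConfig(n_individuals=1200, n_chromosomes=3, snps_per_chrom=150,
                          n_causal_exposure=25, n_pleiotropic=2, seed=61),
            min_snps=3,      # small cohort: accept fewer instruments
            gwas_p=1e-4,
        )
        return cfg, run_pipeline(cfg)

    def test_manifest_lists_all_stages(self, small_run):
        _, result = small_run
        counts = result.manifest["stage_counts"]
        for stage in ("genotypes", "samples", "grm_snps", "meta_snps", "gsmr_pairs"):
            assert counts[stage] > 0, stage
        assert result.manifest["hash"]

    def test_rerun_is_deterministic(self, small_run):
        cfg, result = small_run
        again = run_pipeline(cfg)
        pd.testing.assert_frame_equal(result.gsmr_table, again.gsmr_table)
        for trait in result.meta_tables:
            pd.testing.assert_frame_equal(result.meta_tables[trait],
                                          again.meta_tables[trait])
        assert result.manifest_hash == again.manifest_hash

    def test_typed_failures_recorded_not_raised(self):
        cfg = PipelineConfig(
            sim=SimConfig(n_individuals=400, n_chromosomes=2, snps_per_chrom=80,
                          n_causal_exposure=5, n_pleiotropic=0, h2_exposure=0.05,
                          seed=62),
        )
        result = run_pipeline(cfg)
        assert all(p.status in ("not_testable", "non_estimable", "ok")
                   for p in result.pairs)
        assert any(p.status == "not_testable" for p in result.pairs)

    def test_written_tables_carry_manifest_hash(self, small_run, tmp_path):
        from gsmrpipe.pipeline import write_table

        _, result = small_run
        write_table(result.gsmr_table, tmp_path / "gsmr.tsv", result.manifest_hash)
        first = (tmp_path / "gsmr.tsv").read_text().splitlines()[0]
        assert result.manifest_hash in first


class TestCli:
    def test_simulate_and_annotate_commands(self, tmp_path):
        from click.testing import CliRunner

        from gsmrpipe.cli import main

        runner = CliRunner()
        cfg = tmp_path / "sim.yaml"
        cfg.write_text(
            "n_individuals: 120\nn_chromosomes: 2\nsnps_per_chrom: 40\n"
            "n_causal_exposure: 5\nn_pleiotropic: 0\nseed: 63\n"
        )
        out = tmp_path / "cohort"
        r = runner.invoke(main, ["simulate", "--config", str(cfg), "--out", str(out)])
        assert r.exit_code == 0, r.output
        assert (tmp_path / "cohort.bed").exists()
        assert (tmp_path / "cohort.truth.tsv").exists()

        ivs = tmp_path / "ivs.tsv"
        pd.DataFrame({"SNP": ["rs1"], "Chr": [1], "bp": [5000]}).to_csv(
            ivs, sep="\t", index=False)
        genes = tmp_path / "genes.bed"
        genes.write_text("1\t3999\t6000\tABCA1\n")
        hits = tmp_path / "hits.tsv"
        r = runner.invoke(main, ["annotate", "--ivs", str(ivs), "--genes", str(genes),
                                 "--window", "1000", "--out", str(hits)])
        assert r.exit_code == 0, r.output
        assert "ABCA1" in hits.read_text()
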