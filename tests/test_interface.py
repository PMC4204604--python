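"""Config validation, file-format round trips, end-to-end pipeline, CLI."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

import methylbias as mb
from methylbias import io
from methylbias.cli import main as cli_main
from methylbias.pipeline import RunConfig, run_pipeline


class TestRunConfig:
    def test_invalid_fdr_rejected_before_any_stage(self, tmp_path):
        cfg = RunConfig(fdr=0.0, outdir=str(tmp_path / "out"))
        with pytest.raises(mb.ParameterError):
            run_pipeline(cfg)
        assert not (tmp_path / "out" / "genome.fasta").exists()

    @pytest.mark.parametrize("field,value", [
        ("scaling", "median"), ("cycles", ()), ("non_conversion_rate", 1.0),
        ("enzyme", "taq"), ("n_regions", 1)])
    def test_field_validation(self, field, value):
        cfg = RunConfig(**{field: value})
        with pytest.raises((mb.ParameterError, ValueError)):
            cfg.validate()

    def test_yaml_round_trip(self, tmp_path):
        cfg = RunConfig(depth=1234, cycles=(2, 6), seed=42)
        cfg.to_yaml(tmp_path / "c.yaml")
        back = RunConfig.from_yaml(tmp_path / "c.yaml")
        assert back == cfg

    def test_unknown_config_key_rejected(self, tmp_path):
        (tmp_path / "c.yaml").write_text("depht: 5\n")
        with pytest.raises(mb.ParameterError):
            RunConfig.from_yaml(tmp_path / "c.yaml")


class TestFormats:
    def test_tsv_round_trip_preserves_values(self, tmp_path):
        frame = pd.DataFrame({"contig": ["chr1", "chr1"], "start": [0, 500],
                              "scaled_count": [1.0, 0.123456789012345],
                              "weighted_mC": [0.5, np.nan]})
        io.write_tsv(tmp_path / "t.tsv", frame)
        back = io.read_tsv(tmp_path / "t.tsv")
        pd.testing.assert_frame_equal(back, frame)

    def test_tsv_header_line_starts_with_hash(self, tmp_path):
        io.write_tsv(tmp_path / "t.tsv", pd.DataFrame({"a": [1]}))
        assert (tmp_path / "t.tsv").read_text().startswith("#a\n")

    def test_bed_zero_based_half_open(self, tmp_path):
        (tmp_path / "w.bed").write_text("chr1\t0\t10000\n")
        windows = io.read_bed(tmp_path / "w.bed")
        assert windows.iloc[0].tolist() == ["chr1", 0, 10000]

    def test_malformed_bed_names_line(self, tmp_path):
        (tmp_path / "w.bed").write_text("chr1\t100\n")
        with pytest.raises(mb.FormatError, match="line 1"):
            io.read_bed(tmp_path / "w.bed")

    def test_fastq_round_trip(self, tmp_path):
        lib = mb.SimulatedLibrary(
            [mb.SimRead("r1", "ACGT", "m", 0, "+"),
             mb.SimRead("r2", "GGTA", "m", 4, "-")], 4, "pfu-like", 0.0, 1)
        io.write_fastq(tmp_path / "r.fastq", lib)
        assert io.read_fastq(tmp_path / "r.fastq") == [("r1", "ACGT"),
                                                       ("r2", "GGTA")]

    def test_fastq_bad_alphabet_rejected_with_line_number(self, tmp_path):
        (tmp_path / "r.fastq").write_text("@r1\nACXT\n+\nIIII\n")
        with pytest.raises(mb.FormatError, match="line 2"):
            io.read_fastq(tmp_path / "r.fastq")

    def test_fasta_round_trip(self, tmp_path, gradient_genome):
        io.write_fasta(tmp_path / "g.fasta", gradient_genome)
        back = io.read_fasta(tmp_path / "g.fasta",
                             gradient_genome.control_contig)
        assert back.contigs == gradient_genome.contigs


@pytest.fixture(scope="module")
def demo_runs(tmp_path_factory):
    """The demo scenario (100 kb genome, 3 cycle conditions, depth 20,000),
    run twice with the same config into different directories."""
    outs = []
    for name in ("run_a", "run_b"):
        outdir = tmp_path_factory.mktemp("pipeline") / name
        cfg = RunConfig(seed=1, outdir=str(outdir))
        run_pipeline(cfg)
        outs.append(outdir)
    return outs


class TestPipeline:
    EXPECTED = ["genome.fasta", "methylome_truth.tsv", "windows.bed",
                "gc_profile.tsv", "bias_report.tsv", "cycle_correlations.tsv",
                "run_config.yaml", "run.log"] + [
        f"{stem}_cycles{c}.{ext}"
        for c in (4, 8, 15)
        for stem, ext in [("reads", "fastq"), ("origins", "tsv"),
                          ("placements", "tsv"), ("cytosine_counts", "tsv"),
                          ("methylation_calls", "tsv"),
                          ("window_summary", "tsv"), ("enrichment", "tsv"),
                          ("enrichment", "bedGraph"),
                          ("weighted_mC", "bedGraph")]]

    def test_demo_scenario_writes_all_artifacts(self, demo_runs):
        for name in self.EXPECTED:
            assert (demo_runs[0] / name).exists(), name

    def test_rerun_is_byte_identical(self, demo_runs):
        a, b = demo_runs
        data = [f for f in sorted(a.glob("*"))
                # run.log carries timestamps, run_config.yaml its own outdir
                if f.suffix in (".tsv", ".fastq", ".fasta", ".bed",
                                ".bedGraph")]
        assert len(data) > 20
        for f in data:
            assert f.read_bytes() == (b / f.name).read_bytes(), f.name

    def test_coordinates_consistent_across_files(self, demo_runs):
        out = demo_runs[0]
        genome = io.read_fasta(out / "genome.fasta", "ctrl")
        windows = io.read_bed(out / "windows.bed")
        summary = io.read_tsv(out / "window_summary_cycles4.tsv")
        assert windows[["contig", "start", "end"]].equals(
            summary[["contig", "start", "end"]])
        placements = io.read_tsv(out / "placements_cycles4.tsv")
        for contig, grp in placements.groupby("contig"):
            assert grp.start.min() >= 0
            assert grp.start.max() < genome.length(contig)
        counts = io.read_tsv(out / "cytosine_counts_cycles4.tsv")
        for contig, grp in counts.groupby("contig"):
            arr = genome.contigs[contig]
            plus = grp[grp.strand == "+"]
            assert all(arr[p] == "C" for p in plus.pos.head(50))

    def test_bias_report_recovers_gc_bias_direction(self, demo_runs):
        """On the demo genome (modest GC contrast, strong methylation
        contrast) the coverage-vs-methylation slope grows with PCR cycles."""
        report = io.read_tsv(demo_runs[0] / "bias_report.tsv")
        by_cycles = report.set_index("cycles").slope
        assert by_cycles[4] < by_cycles[8] < by_cycles[15]
        assert by_cycles[15] > 0


class TestCli:
    def test_stagewise_cli_chain(self, tmp_path):
        runner = CliRunner()
        sim = tmp_path / "sim"
        cfg = RunConfig(n_regions=3, region_length=300, control_length=200,
                        depth=500, n_fragments=400, fragment_length=80,
                        cycles=(4,), window_size=200, seed=3)
        cfg.to_yaml(tmp_path / "cfg.yaml")
        res = runner.invoke(cli_main, ["simulate", "--config",
                                       str(tmp_path / "cfg.yaml"),
                                       "--outdir", str(sim)])
        assert res.exit_code == 0, res.output
        res = runner.invoke(cli_main, [
            "place", str(sim / "reads_cycles4.fastq"),
            str(sim / "genome.fasta"), "--control-contig", "ctrl",
            "--placements-out", str(tmp_path / "pl.tsv"),
            "--counts-out", str(tmp_path / "ct.tsv")])
        assert res.exit_code == 0, res.output
        res = runner.invoke(cli_main, [
            "call", str(tmp_path / "ct.tsv"), "--control-contig", "ctrl",
            "--calls-out", str(tmp_path / "calls.tsv")])
        assert res.exit_code == 0, res.output
        res = runner.invoke(cli_main, [
            "coverage", str(tmp_path / "pl.tsv"), str(tmp_path / "ct.tsv"),
            str(sim / "genome.fasta"), str(sim / "methylome_truth.tsv"),
            "--control-contig", "ctrl", "--window-size", "200",
            "--scaling", "total",
            "--summary-out", str(tmp_path / "summary.tsv")])
        assert res.exit_code == 0, res.output
        res = runner.invoke(cli_main, [
            "bias-report", str(tmp_path / "summary.tsv"),
            str(tmp_path / "summary.tsv"),
            "--report-out", str(tmp_path / "report.tsv"),
            "--correlations-out", str(tmp_path / "corr.tsv")])
        assert res.exit_code == 0, res.output
        report = io.read_tsv(tmp_path / "report.tsv")
        assert len(report) == 2
        calls = io.read_tsv(tmp_path / "calls.tsv")
        assert {"p_value", "q_value", "called"} <= set(calls.columns)
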