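"""End-to-end pipeline: config validation, stage composition, artifacts.

``run_pipeline`` turns a validated :class:`RunConfig` into a directory of
plain-text artifacts, per cycle condition: reference FASTA, methylome
truth, reads FASTQ with read-origin table, placements, per-cytosine counts,
methylation calls, window summaries, enrichment against a fully-converted
genomic baseline, and the bias report (trimmed regression per condition
plus the cross-cycle correlation matrix).  The whole run is a pure function
of the config, seeds included; a resolved copy of the config and a run log
are written into the output directory.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .calling import call_methylation, estimate_nonconversion
from .coverage import (apply_reference_methylome, count_reads_in_windows,
                       enrichment_vs_genomic, make_windows, scale_by_first_tile,
                       scale_by_total, summarize_windows)
from .conversion import window_gc_profile
from .errors import ParameterError
from .placement import build_converted_index, pileup_cytosines, place_library
from .scenarios import methylation_triples, resolve_enzyme, _spawn
from .simulate import (amplify_and_sample, bisulfite_convert_pool,
                       generate_genome, generate_methylome, simulate_fragments)
from .stats import cycle_correlation_matrix, trimmed_regression

log = logging.getLogger("methylbias")


@dataclass
class RunConfig:
    """Everything a pipeline run depends on; validated before any stage runs."""

    scenario: str = "demo"
    # genome
    n_regions: int = 20
    region_length: int = 5000
    gc_gradient: tuple[float, float] = (0.38, 0.32)
    control_length: int = 8000
    control_gc: float = 0.36
    # methylome: region-level gradient scaled per context (CG, CHG, CHH)
    meth_gradient: tuple[float, float] = (0.10, 0.90)
    context_factors: tuple[float, float, float] = (1.0, 0.7, 0.3)
    # library
    enzyme: str = "pfu-like"
    cycles: tuple[int, ...] = (4, 8, 15)
    depth: int = 20000
    n_fragments: int = 12000
    fragment_length: int = 150
    non_conversion_rate: float = 0.005
    # analysis
    window_size: int = 2000
    fdr: float = 0.05
    min_coverage: int = 1
    scaling: str = "first-tile"
    alpha: float = 0.05
    max_outlier_fraction: float = 0.05
    seed: int = 1
    outdir: str = "methylbias_run"

    def validate(self) -> None:
        if self.n_regions < 2:
            raise ParameterError("n_regions must be >= 2")
        if self.region_length < 100:
            raise ParameterError("region_length must be >= 100")
        for g in (*self.gc_gradient, self.control_gc):
            if not 0.0 < g < 1.0:
                raise ParameterError(f"GC fraction {g} outside (0, 1)")
        for m in (*self.meth_gradient, *self.context_factors):
            if not 0.0 <= m <= 1.0:
                raise ParameterError(f"methylation level {m} outside [0, 1]")
        if not self.cycles or any(c < 0 for c in self.cycles):
            raise ParameterError("cycles must be non-negative integers")
        if self.depth < 1 or self.n_fragments < 1:
            raise ParameterError("depth and n_fragments must be positive")
        if self.fragment_length < 1:
            raise ParameterError("fragment_length must be positive")
        if not 0.0 <= self.non_conversion_rate < 1.0:
            raise ParameterError("non_conversion_rate must be in [0, 1)")
        if self.window_size < 1:
            raise ParameterError("window_size must be >= 1")
        if not 0.0 < self.fdr < 1.0:
            raise ParameterError("fdr must be in (0, 1)")
        if self.min_coverage < 1:
            raise ParameterError("min_coverage must be >= 1")
        if self.scaling not in ("first-tile", "total"):
            raise ParameterError("scaling must be 'first-tile' or 'total'")
        if not 0.0 < self.alpha < 1.0:
            raise ParameterError("alpha must be in (0, 1)")
        if not 0.0 <= self.max_outlier_fraction <= 1.0:
            raise ParameterError("max_outlier_fraction must be in [0, 1]")
        resolve_enzyme(self.enzyme)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        for key in ("gc_gradient", "meth_gradient", "context_factors", "cycles"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        for key, val in data.items():
            if isinstance(val, tuple):
                data[key] = list(val)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def _scale(counts, scaling: str) -> np.ndarray:
    return (scale_by_first_tile(counts) if scaling == "first-tile"
            else scale_by_total(counts))


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage, write all artifacts, return the output directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, outdir)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, outdir: Path) -> Path:
    log.info("methylbias %s scenario=%s seed=%d", __version__,
             config.scenario, config.seed)
    config.to_yaml(outdir / "run_config.yaml")
    seeds = _spawn(config.seed, 4 + len(config.cycles))
    s_genome, s_frag, s_conv, s_genomic, *s_amp = seeds
    log.info("stage seeds: genome=%d fragments=%d conversion=%d genomic=%d "
             "amplify=%s", s_genome, s_frag, s_conv, s_genomic, s_amp)

    genome = generate_genome(config.n_regions, config.region_length,
                             config.gc_gradient, config.control_length,
                             s_genome, control_gc=config.control_gc)
    truth = generate_methylome(
        genome, methylation_triples(config.n_regions, config.meth_gradient,
                                    config.context_factors))
    io.write_fasta(outdir / "genome.fasta", genome)
    io.write_tsv(outdir / "methylome_truth.tsv", truth.to_frame())

    windows = make_windows(genome, config.window_size)
    io.write_bed(outdir / "windows.bed", windows)
    io.write_tsv(outdir / "gc_profile.tsv",
                 window_gc_profile(genome, truth, config.window_size))

    pool = simulate_fragments(genome, config.n_fragments,
                              config.fragment_length, s_frag)
    conv = bisulfite_convert_pool(pool, truth, config.non_conversion_rate,
                                  s_conv)
    index = build_converted_index(genome)
    profile = resolve_enzyme(config.enzyme)

    # genomic baseline: raw (untreated) fragments, unbiased sampling,
    # fully C->T converted at placement time (mappability baseline)
    genomic_lib = amplify_and_sample(pool, profile, 0, config.depth, s_genomic)
    genomic_placements, genomic_tally = place_library(genomic_lib, index)
    log.info("genomic baseline: %s", dict(genomic_tally))
    genomic_scaled = _scale(
        count_reads_in_windows(genomic_placements, windows), config.scaling)

    reference_summary = None
    scaled_by_cycle: dict[str, np.ndarray] = {}
    report_rows = []
    for c, s in zip(config.cycles, s_amp):
        tag = f"cycles{c}"
        lib = amplify_and_sample(conv, profile, c, config.depth, s,
                                 non_conversion_rate=config.non_conversion_rate)
        io.write_fastq(outdir / f"reads_{tag}.fastq", lib)
        io.write_origins(outdir / f"origins_{tag}.tsv", lib)

        placements, tally = place_library(lib, index)
        log.info("%s placement: %s", tag, dict(tally))
        io.write_tsv(outdir / f"placements_{tag}.tsv",
                     placements.drop(columns="sequence"))

        counts = pileup_cytosines(placements, genome)
        io.write_tsv(outdir / f"cytosine_counts_{tag}.tsv", counts)

        control = counts[counts["contig"] == genome.control_contig]
        rate = estimate_nonconversion(control)
        log.info("%s non-conversion estimate: %.5f (%d/%d)", tag, rate.rate,
                 rate.n_meth_control, rate.n_total_control)
        calls = call_methylation(
            counts[counts["contig"] != genome.control_contig], rate,
            fdr=config.fdr, min_coverage=config.min_coverage)
        io.write_tsv(outdir / f"methylation_calls_{tag}.tsv", calls)

        summary = summarize_windows(placements, counts, genome, truth,
                                    config.window_size,
                                    scaling=config.scaling)
        if reference_summary is None:
            reference_summary = summary
        else:
            summary = apply_reference_methylome(summary, reference_summary)
        io.write_tsv(outdir / f"window_summary_{tag}.tsv", summary)
        io.write_bedgraph(outdir / f"weighted_mC_{tag}.bedGraph", windows,
                          summary["weighted_mC"], track_name=f"mC_{tag}")

        scaled = summary["scaled_count"].to_numpy()
        scaled_by_cycle[str(c)] = scaled
        enr = enrichment_vs_genomic(scaled, genomic_scaled, windows)
        io.write_tsv(outdir / f"enrichment_{tag}.tsv", enr)
        io.write_bedgraph(outdir / f"enrichment_{tag}.bedGraph", windows,
                          enr["enrichment"], track_name=f"enrichment_{tag}")

        main = summary["contig"] != genome.control_contig
        ok = main & np.isfinite(summary["weighted_mC"])
        fit = trimmed_regression(summary.loc[ok, "weighted_mC"],
                                 summary.loc[ok, "scaled_count"],
                                 alpha=config.alpha,
                                 max_fraction=config.max_outlier_fraction)
        log.info("%s fit: slope=%.4g r2=%.4f n_used=%d", tag, fit.slope,
                 fit.r_squared, fit.n_used)
        report_rows.append({
            "cycles": c, "slope": fit.slope, "intercept": fit.intercept,
            "r": fit.r, "r_squared": fit.r_squared, "slope_t": fit.slope_t,
            "n_input": fit.n_input, "n_used": fit.n_used,
            "n_outliers": len(fit.outlier_indices)})

    io.write_tsv(outdir / "bias_report.tsv", pd.DataFrame(report_rows))
    if len(scaled_by_cycle) >= 2:
        corr = cycle_correlation_matrix(scaled_by_cycle)
        io.write_tsv(outdir / "cycle_correlations.tsv",
                     corr.reset_index(names="cycles"))
    log.info("done: %s", outdir)
    return outdir
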