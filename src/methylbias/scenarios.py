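"""Preset study-condition scenarios and per-seed experiment runners.

These compose the simulator and the analysis stack into the three
experiment designs the package exists to quantify:

* ``run_cycle_experiment`` — one fragment pool amplified at several PCR
  cycle counts under a chosen enzyme profile, then the coverage-versus-
  methylation regression per condition and the cross-cycle correlation
  matrix.  The genome holds base composition fixed and varies methylation
  across regions (the epiallele design: identical-composition sequence,
  different methylation), so any coverage trend is attributable to the
  amplification model.
* ``run_at_depletion_experiment`` — an unmethylated genome with a GC
  gradient (a genomic-DNA stand-in), amplified at a low and a high cycle
  count; reports the per-window log2 coverage ratio against %GC and its
  least-squares slope (positive slope = AT-rich depletion).
* ``run_calibration_experiment`` — a small end-to-end run with known
  methylation strata and non-conversion rate, for estimator-recovery
  checks (non-conversion estimate, per-stratum weighted methylation).

Each runner is a pure function of its seed; internal stage seeds are
spawned from it.
"""

from __future__ import annotations

import numpy as np

from .calling import estimate_nonconversion, weighted_methylation
from .coverage import apply_reference_methylome, summarize_windows
from .placement import build_converted_index, pileup_cytosines, place_library
from .simulate import (ENZYME_PRESETS, EnzymeProfile, amplify_and_sample,
                       bisulfite_convert_pool, generate_genome,
                       generate_methylome, simulate_fragments)
from .stats import cycle_correlation_matrix, trimmed_regression

#: CG : CHG : CHH scaling of a region's methylation level, approximating
#: the context hierarchy of plant heterochromatin.
CONTEXT_FACTORS = (1.0, 0.7, 0.3)


def resolve_enzyme(enzyme: str | EnzymeProfile) -> EnzymeProfile:
    if isinstance(enzyme, EnzymeProfile):
        return enzyme
    try:
        return ENZYME_PRESETS[enzyme]
    except KeyError:
        raise ValueError(f"unknown enzyme preset {enzyme!r}; "
                         f"choose from {sorted(ENZYME_PRESETS)}") from None


def methylation_triples(n_regions: int, gradient: tuple[float, float],
                        factors: tuple[float, float, float] = CONTEXT_FACTORS):
    """Per-region (CG, CHG, CHH) probability triples interpolating a
    region-level methylation gradient."""
    levels = np.linspace(gradient[0], gradient[1], n_regions)
    return [tuple(np.clip(m * np.asarray(factors), 0, 1)) for m in levels]


def _spawn(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def run_cycle_experiment(enzyme: str | EnzymeProfile = "pfu-like",
                         seed: int = 0, cycles: tuple[int, ...] = (4, 8, 15), *,
                         n_regions: int = 20, region_length: int = 5000,
                         gc: float = 0.35, control_length: int = 8000,
                         meth_gradient: tuple[float, float] = (0.05, 0.95),
                         window_size: int = 500, depth: int = 40000,
                         n_fragments: int = 12000, fragment_length: int = 150,
                         non_conversion_rate: float = 0.005,
                         scaling: str = "first-tile") -> dict:
    """Amplify one converted pool at each cycle count and regress scaled
    window coverage on weighted methylation (fixed axis from the first
    cycle condition).  Returns regression results per cycle, the pairwise
    correlation matrix and the per-cycle window summaries."""
    profile = resolve_enzyme(enzyme)
    s_genome, s_frag, s_conv, *s_amp = _spawn(seed, 3 + len(cycles))
    genome = generate_genome(n_regions, region_length, (gc, gc),
                             control_length, s_genome)
    truth = generate_methylome(
        genome, methylation_triples(n_regions, meth_gradient))
    pool = simulate_fragments(genome, n_fragments, fragment_length, s_frag)
    conv = bisulfite_convert_pool(pool, truth, non_conversion_rate, s_conv)
    index = build_converted_index(genome)
    main = [c for c in genome.contigs if c != genome.control_contig]

    summaries, scaled, fits = {}, {}, {}
    reference = None
    for c, s in zip(cycles, s_amp):
        lib = amplify_and_sample(conv, profile, c, depth, s,
                                 non_conversion_rate=non_conversion_rate)
        placements, _ = place_library(lib, index)
        counts = pileup_cytosines(placements, genome)
        summary = summarize_windows(placements, counts, genome, truth,
                                    window_size, scaling=scaling,
                                    contigs=main)
        if reference is None:
            reference = summary
        else:
            summary = apply_reference_methylome(summary, reference)
        summaries[c] = summary
        scaled[c] = summary["scaled_count"].to_numpy()
        ok = np.isfinite(summary["weighted_mC"])
        fits[c] = trimmed_regression(summary.loc[ok, "weighted_mC"],
                                     summary.loc[ok, "scaled_count"])
    corr = cycle_correlation_matrix({str(c): v for c, v in scaled.items()})
    return {"genome": genome, "truth": truth, "summaries": summaries,
            "fits": fits, "correlations": corr}


def run_at_depletion_experiment(enzyme: str | EnzymeProfile = "pfu-like",
                                seed: int = 0,
                                cycles: tuple[int, int] = (4, 15), *,
                                n_regions: int = 20, region_length: int = 5000,
                                gc_gradient: tuple[float, float] = (0.25, 0.55),
                                control_length: int = 8000,
                                window_size: int = 500, depth: int = 25000,
                                n_fragments: int = 12000,
                                fragment_length: int = 150,
                                non_conversion_rate: float = 0.005) -> dict:
    """Unmethylated GC-gradient genome at a low vs high cycle count; the
    least-squares slope of per-window log2(high/low) coverage against raw
    %GC quantifies AT-rich depletion."""
    from .coverage import (count_reads_in_windows, log2_cycle_ratio,
                           make_windows, scale_by_total)
    from .conversion import window_gc_profile

    profile = resolve_enzyme(enzyme)
    s_genome, s_frag, s_conv, s_a, s_b = _spawn(seed, 5)
    genome = generate_genome(n_regions, region_length, gc_gradient,
                             control_length, s_genome)
    truth = generate_methylome(genome, [(0.0, 0.0, 0.0)] * n_regions)
    pool = simulate_fragments(genome, n_fragments, fragment_length, s_frag)
    conv = bisulfite_convert_pool(pool, truth, non_conversion_rate, s_conv)
    index = build_converted_index(genome)
    main = [c for c in genome.contigs if c != genome.control_contig]
    windows = make_windows(genome, window_size, contigs=main)
    gc = window_gc_profile(genome, truth, window_size)
    gc = gc[gc["contig"].isin(main)].reset_index(drop=True)

    scaled = {}
    for c, s in zip(cycles, (s_a, s_b)):
        lib = amplify_and_sample(conv, profile, c, depth, s,
                                 non_conversion_rate=non_conversion_rate)
        placements, _ = place_library(lib, index)
        scaled[c] = scale_by_total(count_reads_in_windows(placements, windows))
    ratio = log2_cycle_ratio(scaled[cycles[0]], scaled[cycles[1]], windows,
                             gc["gc_raw"].to_numpy())
    ok = np.isfinite(ratio["log2_ratio"])
    fit = trimmed_regression(ratio.loc[ok, "gc"], ratio.loc[ok, "log2_ratio"],
                             max_fraction=0.0)
    return {"ratio": ratio, "fit": fit, "scaled": scaled}


def run_calibration_experiment(seed: int = 0, *,
                               strata: tuple[float, ...] = (0.0, 0.3, 0.7, 1.0),
                               region_length: int = 2500,
                               control_length: int = 5000, gc: float = 0.40,
                               n_fragments: int = 20000, depth: int = 2500,
                               fragment_length: int = 150,
                               non_conversion_rate: float = 0.01) -> dict:
    """Known methylation strata and non-conversion rate, run end-to-end.

    Returns the pooled non-conversion estimate with its binomial SE and,
    per stratum p, the observed weighted methylation, the expected value
    p + (1 − p)·r and its binomial SE.
    """
    s_genome, s_frag, s_conv, s_amp = _spawn(seed, 4)
    n_regions = len(strata)
    genome = generate_genome(n_regions, region_length, (gc, gc),
                             control_length, s_genome)
    truth = generate_methylome(genome, [(p, p, p) for p in strata])
    pool = simulate_fragments(genome, n_fragments, fragment_length, s_frag)
    conv = bisulfite_convert_pool(pool, truth, non_conversion_rate, s_conv)
    index = build_converted_index(genome)
    lib = amplify_and_sample(conv, ENZYME_PRESETS["kapa-like"], 8, depth,
                             s_amp, non_conversion_rate=non_conversion_rate)
    placements, _ = place_library(lib, index)
    counts = pileup_cytosines(placements, genome)

    control = counts[counts["contig"] == genome.control_contig]
    est = estimate_nonconversion(control)
    rate_se = float(np.sqrt(non_conversion_rate * (1 - non_conversion_rate)
                            / est.n_total_control))

    main = [c for c in genome.contigs if c != genome.control_contig][0]
    per_stratum = []
    for i, p in enumerate(strata):
        lo, hi = i * region_length, (i + 1) * region_length
        sites = counts[(counts["contig"] == main)
                       & (counts["pos"] >= lo) & (counts["pos"] < hi)]
        n_basecalls = int(sites["n_total"].sum())
        expected = p + (1 - p) * non_conversion_rate
        se = float(np.sqrt(expected * (1 - expected) / n_basecalls)) \
            if n_basecalls else float("nan")
        per_stratum.append({
            "p": p, "observed": weighted_methylation(sites),
            "expected": expected, "se": se, "n_basecalls": n_basecalls})
    return {"rate_estimate": est, "rate_se": rate_se,
            "true_rate": non_conversion_rate, "strata": per_stratum}
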