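"""Normalized read coverage, window summaries, enrichment and log2 ratios.

Coverage statistics mirror a WGBS enrichment analysis: a region-level
normalized coverage (reads in region / library total × 10⁵), tiled window
counts placed on a common scale by dividing by the first tile (or by the
library total, the robust alternative when the first tile is empty or
atypical), the bisulfite-minus-genomic enrichment against a mappability
baseline (genomic reads fully C→T converted and run through the same
placement pipeline), and per-window log2 coverage ratios between PCR-cycle
conditions paired with window GC.

A read belongs to the window containing its start coordinate — the simplest
rule that conserves the total count.  When cycle conditions are compared,
the methylation axis can be pinned to a designated reference library so
points move only vertically between panels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calling import weighted_methylation
from .conversion import window_gc_profile
from .errors import ParameterError
from .simulate import GenomeSequence, MethylomeTruth

NORMALIZATION_SCALE = 1e5


def region_normalized_coverage(reads_in_region: int, total_reads: int) -> float:
    """(reads in region / total library reads) × 10⁵."""
    if total_reads < 1:
        raise ParameterError("total_reads must be >= 1")
    if not 0 <= reads_in_region <= total_reads:
        raise ParameterError("reads_in_region must be in [0, total_reads]")
    return reads_in_region / total_reads * NORMALIZATION_SCALE


def make_windows(genome: GenomeSequence, window_size: int,
                 contigs=None) -> pd.DataFrame:
    """0-based half-open tiling windows; last partial window included."""
    if window_size < 1:
        raise ParameterError("window_size must be >= 1")
    names = list(genome.contigs) if contigs is None else list(contigs)
    rows = []
    for contig in names:
        n = genome.length(contig)
        for start in range(0, n, window_size):
            rows.append({"contig": contig, "start": start,
                         "end": min(start + window_size, n)})
    return pd.DataFrame(rows)


def count_reads_in_windows(placements: pd.DataFrame,
                           windows: pd.DataFrame) -> np.ndarray:
    """Per-window read counts; a read counts in the window containing its
    start coordinate (exactly one window per read for a tiling)."""
    counts = np.zeros(len(windows), dtype=np.int64)
    if not len(placements):
        return counts
    for contig, wgrp in windows.groupby("contig", sort=False):
        starts = wgrp["start"].to_numpy()
        ends = wgrp["end"].to_numpy()
        order = np.argsort(starts)
        reads = placements.loc[placements["contig"] == contig, "start"].to_numpy()
        if not reads.size:
            continue
        slot = np.searchsorted(starts[order], reads, side="right") - 1
        ok = (slot >= 0) & (reads < ends[order][np.clip(slot, 0, None)])
        np.add.at(counts, wgrp.index.to_numpy()[order][slot[ok]], 1)
    return counts


def scale_by_first_tile(read_counts) -> np.ndarray:
    """Divide every window count by the first window's count (first tile = 1)."""
    c = np.asarray(read_counts, dtype=float)
    if c.size == 0:
        raise ParameterError("no windows")
    if c[0] == 0:
        raise ParameterError(
            "first tile has zero reads; use total-reads scaling "
            "(scaling='total') instead")
    return c / c[0]


def scale_by_total(read_counts, total_reads: int | None = None) -> np.ndarray:
    """Alternative scaling by the library total (×10⁵), robust to an empty
    or atypical first tile."""
    c = np.asarray(read_counts, dtype=float)
    total = int(c.sum()) if total_reads is None else total_reads
    if total < 1:
        raise ParameterError("total_reads must be >= 1")
    return c / total * NORMALIZATION_SCALE


def enrichment_vs_genomic(bis_scaled, genomic_scaled,
                          windows: pd.DataFrame) -> pd.DataFrame:
    """Per-window scaled bisulfite count minus scaled genomic count.

    The genomic library must have been fully C→T converted before placement
    so that the subtraction isolates bisulfite/PCR effects from mappability.
    """
    b = np.asarray(bis_scaled, dtype=float)
    g = np.asarray(genomic_scaled, dtype=float)
    if not (len(b) == len(g) == len(windows)):
        raise ParameterError("scaled counts and windows must align")
    out = windows.copy()
    out["bis_scaled"] = b
    out["genomic_scaled"] = g
    out["enrichment"] = b - g
    return out


def log2_cycle_ratio(scaled_a, scaled_b, windows: pd.DataFrame,
                     gc_per_window, pseudocount: float = 0.0) -> pd.DataFrame:
    """Per-window log2(B/A) of scaled counts, paired with window %GC.

    Windows where either library has zero (post-pseudocount) coverage are
    emitted with NaN — missing is data, not an error.  ``pseudocount``
    (e.g. 0.5 on raw counts) is available but off by default.
    """
    a = np.asarray(scaled_a, dtype=float) + pseudocount
    b = np.asarray(scaled_b, dtype=float) + pseudocount
    gc = np.asarray(gc_per_window, dtype=float)
    if not (len(a) == len(b) == len(windows) == len(gc)):
        raise ParameterError("inputs must align with windows")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where((a > 0) & (b > 0), np.log2(b / a), np.nan)
    out = windows.copy()
    out["log2_ratio"] = ratio
    out["gc"] = gc
    return out


def summarize_windows(placements: pd.DataFrame, counts: pd.DataFrame,
                      genome: GenomeSequence, truth: MethylomeTruth,
                      window_size: int, scaling: str = "first-tile",
                      contigs=None) -> pd.DataFrame:
    """Per-window read count, scaled count, weighted methylation (all
    contexts combined) and the three GC fractions.

    Windows with no covered cytosines report NaN weighted_mC but still carry
    their read count.
    """
    windows = make_windows(genome, window_size, contigs=contigs)
    read_count = count_reads_in_windows(placements, windows)
    if scaling == "first-tile":
        scaled = scale_by_first_tile(read_count)
    elif scaling == "total":
        scaled = scale_by_total(read_count)
    else:
        raise ParameterError(f"unknown scaling {scaling!r}")

    gc = window_gc_profile(genome, truth, window_size)
    gc = gc[gc["contig"].isin(set(windows["contig"]))].reset_index(drop=True)

    wmc = np.full(len(windows), np.nan)
    if len(counts):
        widx = {(c, s): i for i, (c, s) in
                enumerate(zip(windows["contig"], windows["start"]))}
        key_start = (counts["pos"] // window_size * window_size)
        grouped = counts.groupby([counts["contig"], key_start], sort=False)
        for (contig, wstart), grp in grouped:
            i = widx.get((contig, int(wstart)))
            if i is not None:
                wmc[i] = weighted_methylation(grp)

    out = windows.copy()
    out["read_count"] = read_count
    out["scaled_count"] = scaled
    out["weighted_mC"] = wmc
    out["gc_raw"] = gc["gc_raw"].to_numpy()
    out["gc_converted"] = gc["gc_converted"].to_numpy()
    out["gc_full"] = gc["gc_full"].to_numpy()
    return out


def apply_reference_methylome(summary: pd.DataFrame,
                              reference: pd.DataFrame) -> pd.DataFrame:
    """Pin the methylation axis to a designated reference library so that,
    across compared cycle conditions, points differ only in coverage."""
    if not (summary["contig"].tolist() == reference["contig"].tolist()
            and summary["start"].tolist() == reference["start"].tolist()):
        raise ParameterError("summary and reference windows differ")
    out = summary.copy()
    out["weighted_mC"] = reference["weighted_mC"].to_numpy()
    return out
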