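"""Bisulfite-aware read placement in fully-converted sequence space.

A desk-scale stand-in for a WGBS aligner: both the reference strands and
each read are reduced to the three-letter alphabet by converting every
C → T, and reads are placed by exact full-length match only — the simulated
reads are error-free, so anything an aligner's mismatch tolerance buys is
out of scope.  Reads hitting zero or multiple loci are discarded (the
unique-alignment filter of standard WGBS practice); discards are data, not
errors.

Placements feed the cytosine pileup: at every covered reference C on the
placed strand, a read C is a methylated basecall, a read T an unmethylated
one, anything else is ignored.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import sequtils as sq
from .errors import ConsistencyError, ParameterError
from .simulate import GenomeSequence, SimRead, SimulatedLibrary

_TO_T = str.maketrans("C", "T")


@dataclass(frozen=True, slots=True)
class Placement:
    read_id: str
    contig: str
    start: int
    strand: str
    unique: bool = True


class ConvertedIndex:
    """Exact-substring lookup against both fully-converted strands.

    Hash tables keyed by the converted substring are built lazily per query
    length (simulated libraries are fixed-length), mapping to every
    (contig, start, strand) occurrence.  ``start`` is always the leftmost
    + strand coordinate of the hit.
    """

    def __init__(self, genome: GenomeSequence):
        self.genome = genome
        self._plus = {c: genome.contigs[c].translate(_TO_T)
                      for c in genome.contigs}
        self._minus = {c: sq.revcomp(genome.contigs[c]).translate(_TO_T)
                       for c in genome.contigs}
        self._tables: dict[int, dict[str, list[tuple[str, int, str]]]] = {}

    def _table(self, length: int) -> dict[str, list[tuple[str, int, str]]]:
        if length not in self._tables:
            table: dict[str, list[tuple[str, int, str]]] = {}
            for contig in self.genome.contigs:
                n = self.genome.length(contig)
                plus, minus = self._plus[contig], self._minus[contig]
                for q in range(n - length + 1):
                    table.setdefault(plus[q:q + length], []).append(
                        (contig, q, "+"))
                    # position q in the reversed strand starts at n - q - length
                    table.setdefault(minus[q:q + length], []).append(
                        (contig, n - q - length, "-"))
            self._tables[length] = table
        return self._tables[length]

    def lookup(self, converted_query: str) -> list[tuple[str, int, str]]:
        """All (contig, start, strand) exact hits of an already-converted query."""
        if not converted_query:
            raise ParameterError("empty query")
        return self._table(len(converted_query)).get(converted_query, [])


def build_converted_index(genome: GenomeSequence) -> ConvertedIndex:
    return ConvertedIndex(genome)


def place_read(read: str | SimRead, index: ConvertedIndex,
               read_id: str = "read") -> tuple[Placement | None, str]:
    """Place one read; returns (placement, reason) where reason is one of
    ``placed`` / ``unplaced`` / ``ambiguous``."""
    if isinstance(read, SimRead):
        read_id, read = read.read_id, read.sequence
    hits = index.lookup(read.translate(_TO_T))
    if len(hits) == 1:
        contig, start, strand = hits[0]
        return Placement(read_id, contig, start, strand), "placed"
    return None, ("unplaced" if not hits else "ambiguous")


def place_library(library: SimulatedLibrary | list[SimRead],
                  index: ConvertedIndex) -> tuple[pd.DataFrame, Counter]:
    """Place every read of a library.

    Returns (placements, discard counter).  Placements is a DataFrame with
    columns read_id, contig, start, strand, sequence — the sequence column
    carries the original (unconverted) read for the pileup.
    """
    reads = library.reads if isinstance(library, SimulatedLibrary) else library
    rows = {"read_id": [], "contig": [], "start": [], "strand": [],
            "sequence": []}
    tally: Counter = Counter()
    for r in reads:
        hits = index.lookup(r.sequence.translate(_TO_T))
        if len(hits) == 1:
            contig, start, strand = hits[0]
            rows["read_id"].append(r.read_id)
            rows["contig"].append(contig)
            rows["start"].append(start)
            rows["strand"].append(strand)
            rows["sequence"].append(r.sequence)
            tally["placed"] += 1
        else:
            tally["unplaced" if not hits else "ambiguous"] += 1
    return pd.DataFrame(rows), tally


def pileup_cytosines(placements: pd.DataFrame,
                     genome: GenomeSequence) -> pd.DataFrame:
    """Count methylated / total basecalls at every covered reference cytosine.

    For each unique placement and each reference C on the placed strand
    under the read: read base C → methylated basecall, T → unmethylated,
    anything else ignored.  Returns a CX-report-like frame with columns
    contig, pos, strand, context, n_meth, n_total, covered sites only.
    """
    meth = {(c, s): np.zeros(genome.length(c), dtype=np.int64)
            for c in genome.contigs for s in "+-"}
    total = {(c, s): np.zeros(genome.length(c), dtype=np.int64)
             for c in genome.contigs for s in "+-"}
    if len(placements):
        grouped = placements.groupby(["contig", "strand",
                                      placements["sequence"].str.len()],
                                     sort=True)
        for (contig, strand, length), grp in grouped:
            arr = genome.array(contig)
            starts = grp["start"].to_numpy()
            if (starts < 0).any() or (starts + length > arr.size).any():
                raise ConsistencyError(f"placement out of bounds on {contig}")
            offs = np.arange(length)
            if strand == "+":
                pos = starts[:, None] + offs
                ref = arr[pos]
                ref_is_c = ref == sq.C
            else:
                pos = starts[:, None] + (length - 1 - offs)
                ref = arr[pos]
                ref_is_c = ref == sq.G  # G on + strand is C on − strand
            reads = np.vstack([sq.encode(s) for s in grp["sequence"]])
            is_meth = ref_is_c & (reads == sq.C)
            is_unmeth = ref_is_c & (reads == sq.T)
            informative = is_meth | is_unmeth
            np.add.at(total[(contig, strand)], pos[informative], 1)
            np.add.at(meth[(contig, strand)], pos[is_meth], 1)

    frames = []
    for contig in genome.contigs:
        ctx_p, ctx_m = genome.contexts(contig)
        for strand, ctx in (("+", ctx_p), ("-", ctx_m)):
            tot = total[(contig, strand)]
            covered = np.flatnonzero(tot > 0)
            if covered.size == 0:
                continue
            frames.append(pd.DataFrame({
                "contig": contig,
                "pos": covered,
                "strand": strand,
                "context": sq.CONTEXT_LABELS[ctx[covered]],
                "n_meth": meth[(contig, strand)][covered],
                "n_total": tot[covered],
            }))
    if not frames:
        return pd.DataFrame(columns=["contig", "pos", "strand", "context",
                                     "n_meth", "n_total"])
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["contig", "pos", "strand"], ignore_index=True)
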