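"""In-silico bisulfite conversion and windowed GC profiles.

Bisulfite chemistry collapses unmethylated C to T, so GC content is a
property of the conversion state: raw (untreated), methylation-aware
(methylated C retained) and computed full conversion (every C → T).  The
windowed profile reports all three per tiling window together with their
difference, the quantity that localises where conversion reshapes base
composition the most (C-dense, lowly methylated sequence).

``gc_converted`` is the *expected* post-conversion GC — each cytosine
contributes its methylation probability — because the profile describes the
methylome, not one realised library; realised conversion lives in
:mod:`methylbias.simulate`.  GC is computed on the + strand: the raw GC
fraction is strand-symmetric, the post-conversion one is not, and the
asymmetry is documented rather than averaged away.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import sequtils as sq
from .errors import ConsistencyError, ParameterError
from .simulate import GenomeSequence, MethylomeTruth


def gc_content(sequence: str) -> float:
    """(G + C) / length of a nonempty {A,C,G,T} sequence."""
    if not sequence:
        raise ParameterError("empty sequence")
    sq.validate_alphabet(sequence)
    return sq.gc_fraction(sequence)


def convert_full(sequence: str) -> str:
    """Replace every C with T (computed full conversion); idempotent."""
    sq.validate_alphabet(sequence)
    return sequence.replace("C", "T")


def convert_methylation_aware(sequence: str, methylated_positions) -> str:
    """Retain C at the listed (0-based) positions, convert all other C → T."""
    sq.validate_alphabet(sequence)
    keep = set(int(p) for p in methylated_positions)
    for p in keep:
        if p < 0 or p >= len(sequence) or sequence[p] != "C":
            raise ConsistencyError(f"position {p} is not a C")
    return "".join(
        b if b != "C" or i in keep else "T" for i, b in enumerate(sequence))


def window_gc_profile(genome: GenomeSequence, truth: MethylomeTruth,
                      window_size: int) -> pd.DataFrame:
    """Per-window GC in the three conversion states.

    Windows are 0-based half-open tiles of ``window_size`` bp per contig,
    the last partial tile included with its true length as denominator.
    Columns: contig, start, end, gc_raw, gc_converted, gc_full, gc_delta
    (= gc_raw − gc_full).  Invariant: gc_full ≤ gc_converted ≤ gc_raw.
    """
    if window_size < 1:
        raise ParameterError("window_size must be >= 1")
    rows = []
    for contig in genome.contigs:
        arr = genome.array(contig)
        n = arr.size
        is_g = (arr == sq.G).astype(float)
        is_c = (arr == sq.C).astype(float)
        p = truth.probs[(contig, "+")]
        c_weighted = np.where(is_c == 1.0, np.nan_to_num(p), 0.0)
        for start in range(0, n, window_size):
            end = min(start + window_size, n)
            length = end - start
            g = is_g[start:end].sum()
            c = is_c[start:end].sum()
            rows.append({
                "contig": contig, "start": start, "end": end,
                "gc_raw": (g + c) / length,
                "gc_converted": (g + c_weighted[start:end].sum()) / length,
                "gc_full": g / length,
            })
    out = pd.DataFrame(rows)
    out["gc_delta"] = out["gc_raw"] - out["gc_full"]
    return out
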