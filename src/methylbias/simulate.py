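"""Synthetic bisulfite-library simulator with full ground truth.

The simulator emulates the data behind a WGBS amplification-bias study at
desk scale: a small multi-contig reference with a GC/methylation gradient
(AT-rich highly methylated, heterochromatin-like blocks at one end,
gene-like blocks at the other), an unmethylated control contig standing in
for the chloroplast genome, per-cytosine methylation states in the CG /
CHG / CHH contexts, stochastic bisulfite conversion with a small
non-conversion rate, and PCR amplification whose per-cycle efficiency
depends on the *post-conversion* GC fraction of each fragment.

PCR is modelled at the level of expected copy number: a fragment with
per-cycle efficiency ``e`` acquires weight ``(1 + e)^cycles`` and reads are
drawn multinomially with replacement in proportion to those weights.
Per-cycle branching stochasticity is deliberately left out — the bias under
study is an expectation-level phenomenon and the multinomial read draw
reintroduces sampling variance.  Reads are whole fragments with no
sequencing error; error models are orthogonal to the amplification bias and
are an extension point, not a feature.

Everything is a pure function of its seed: identical parameters and seeds
give byte-identical genomes, methylomes and libraries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import sequtils as sq
from .errors import ConsistencyError, ParameterError


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GenomeSequence:
    """A small reference genome plus a designated unmethylated control contig.

    ``contigs`` preserves insertion order (genome order).  ``regions``
    optionally records the homogeneous blocks laid down by
    :func:`generate_genome`; methylome generation assigns probabilities per
    region.
    """

    contigs: dict[str, str]
    control_contig: str
    regions: list[tuple[str, int, int]] | None = None
    _arrays: dict = field(default_factory=dict, repr=False, compare=False)
    _contexts: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        if not self.contigs:
            raise ParameterError("genome must contain at least one contig")
        for name, seq in self.contigs.items():
            if not seq:
                raise ParameterError(f"contig {name!r} is empty")
            sq.validate_alphabet(seq, what=f"contig {name!r}")
        if self.control_contig not in self.contigs:
            raise ParameterError(
                f"control contig {self.control_contig!r} not among contigs")

    def array(self, contig: str) -> np.ndarray:
        if contig not in self._arrays:
            self._arrays[contig] = sq.encode(self.contigs[contig])
        return self._arrays[contig]

    def contexts(self, contig: str) -> tuple[np.ndarray, np.ndarray]:
        """(ctx_plus, ctx_minus) context-code arrays for a contig."""
        if contig not in self._contexts:
            self._contexts[contig] = sq.context_codes(self.array(contig))
        return self._contexts[contig]

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())


class MethylomeTruth:
    """Simulator ground truth: per-cytosine methylation probability.

    Stored as dense per-(contig, strand) probability arrays (NaN at
    non-cytosine positions) so fragment conversion and pileup oracles can be
    vectorised; :meth:`to_frame` materialises the record view
    (contig, pos, strand, context, probability).
    """

    def __init__(self, genome: GenomeSequence,
                 probs: dict[tuple[str, str], np.ndarray]):
        self.genome = genome
        self.probs = probs
        for (contig, strand), arr in probs.items():
            ctx_p, ctx_m = genome.contexts(contig)
            ctx = ctx_p if strand == "+" else ctx_m
            has_c = ctx != sq.CTX_NONE
            if np.isnan(arr[has_c]).any():
                raise ConsistencyError(
                    f"cytosines without a probability on {contig} {strand}")
            if not np.isnan(arr[~has_c]).all():
                raise ConsistencyError(
                    f"probabilities at non-cytosine positions on {contig} {strand}")
            if contig == genome.control_contig and np.nanmax(arr, initial=0.0) > 0:
                raise ConsistencyError("control contig must be fully unmethylated")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for contig in self.genome.contigs:
            ctx_p, ctx_m = self.genome.contexts(contig)
            for strand, ctx in (("+", ctx_p), ("-", ctx_m)):
                pos = np.flatnonzero(ctx != sq.CTX_NONE)
                rows.append(pd.DataFrame({
                    "contig": contig,
                    "pos": pos,
                    "strand": strand,
                    "context": sq.CONTEXT_LABELS[ctx[pos]],
                    "probability": self.probs[(contig, strand)][pos],
                }))
        out = pd.concat(rows, ignore_index=True)
        return out.sort_values(["contig", "pos", "strand"], ignore_index=True)

    @classmethod
    def from_frame(cls, genome: GenomeSequence, frame: pd.DataFrame) -> "MethylomeTruth":
        probs = {}
        for contig in genome.contigs:
            n = genome.length(contig)
            for strand in "+-":
                probs[(contig, strand)] = np.full(n, np.nan)
        for contig, strand, pos, p in zip(frame["contig"], frame["strand"],
                                          frame["pos"], frame["probability"]):
            probs[(contig, strand)][int(pos)] = float(p)
        return cls(genome, probs)


@dataclass(frozen=True)
class EnzymeProfile:
    """GC-dependent per-cycle amplification efficiency.

    ``efficiency(g) = clamp(e0 + γ·(g − 0.5), 0, 1)`` for post-conversion GC
    fraction ``g``; above ``saturation_gc`` the efficiency is held flat at
    its value there.  A mechanistic stand-in for polymerase behaviour — the
    functional form is the simplest monotone model and is documented as
    replaceable.
    """

    name: str
    base_efficiency: float = 0.5
    gc_coefficient: float = 0.0
    saturation_gc: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.base_efficiency <= 1.0:
            raise ParameterError("base_efficiency must be in [0, 1]")

    def efficiency(self, gc):
        g = np.asarray(gc, dtype=float)
        if self.saturation_gc is not None:
            g = np.minimum(g, self.saturation_gc)
        e = self.base_efficiency + self.gc_coefficient * (g - 0.5)
        return np.clip(e, 0.0, 1.0)


#: Desk-scale presets spanning the three qualitative behaviours seen with
#: uracil-insensitive polymerases: strong GC bias (Pfu-Turbo-Cx-like), flat
#: (Kapa-HiFi-U+-like) and bias saturating at high GC (EpiMark-like).
#: Modelling choices, not measurements.
ENZYME_PRESETS: dict[str, EnzymeProfile] = {
    "pfu-like": EnzymeProfile("pfu-like", 0.5, 0.8),
    "kapa-like": EnzymeProfile("kapa-like", 0.5, 0.0),
    "epimark-like": EnzymeProfile("epimark-like", 0.5, 0.4, saturation_gc=0.6),
}


@dataclass(frozen=True, slots=True)
class Fragment:
    """An origin-tagged genomic fragment (sequence given in its own strand's
    5'→3' orientation; ``start`` is the leftmost + strand coordinate)."""

    contig: str
    start: int
    strand: str
    sequence: str


@dataclass(frozen=True, slots=True)
class SimRead:
    read_id: str
    sequence: str
    contig: str
    start: int
    strand: str


@dataclass
class SimulatedLibrary:
    reads: list[SimRead]
    cycles: int
    enzyme: str
    non_conversion_rate: float
    seed: int


# ---------------------------------------------------------------------------
# genome & methylome generation
# ---------------------------------------------------------------------------

def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    # iid bases: P(G)=P(C)=gc/2, P(A)=P(T)=(1-gc)/2
    bases = np.array([sq.A, sq.T, sq.G, sq.C], dtype=np.uint8)
    p = np.array([(1 - gc) / 2, (1 - gc) / 2, gc / 2, gc / 2])
    return sq.decode(rng.choice(bases, size=length, p=p))


def generate_genome(n_regions: int, region_length: int,
                    gc_gradient: tuple[float, float], control_length: int,
                    seed: int, *, control_gc: float = 0.36,
                    main_name: str = "chr1",
                    control_name: str = "ctrl") -> GenomeSequence:
    """One main contig of ``n_regions`` homogeneous blocks whose expected GC
    interpolates ``gc_gradient`` linearly, plus an unmethylated control
    contig (chloroplast stand-in, GC ≈ 0.36 by default)."""
    if n_regions < 2:
        raise ParameterError("need at least 2 regions")
    if region_length < 100:
        raise ParameterError("region_length must be >= 100 bp")
    if control_length <= 0:
        raise ParameterError("control_length must be positive")
    for g in (*gc_gradient, control_gc):
        if not 0.0 < g < 1.0:
            raise ParameterError(f"GC fraction {g} outside (0, 1)")
    rng = np.random.default_rng(seed)
    lo, hi = gc_gradient
    targets = np.linspace(lo, hi, n_regions)
    blocks = [_random_dna(rng, region_length, g) for g in targets]
    contigs = {main_name: "".join(blocks),
               control_name: _random_dna(rng, control_length, control_gc)}
    regions = [(main_name, i * region_length, (i + 1) * region_length)
               for i in range(n_regions)]
    return GenomeSequence(contigs, control_name, regions=regions)


def generate_methylome(genome: GenomeSequence,
                       methylation_by_region: list[tuple[float, float, float]],
                       seed: int = 0, *,
                       regions: list[tuple[str, int, int]] | None = None,
                       site_jitter_sd: float = 0.0) -> MethylomeTruth:
    """Assign one (CG, CHG, CHH) methylation-probability triple per region.

    Every cytosine on both strands of a region receives its region/context
    probability; the control contig is forced to 0 everywhere, as are
    cytosines outside any region.  With ``site_jitter_sd`` > 0 the seed
    drives per-site Gaussian jitter (clipped to [0, 1]); by default the
    assignment is deterministic and the seed is inert.
    """
    regions = regions if regions is not None else genome.regions
    if regions is None:
        raise ParameterError("genome carries no regions; pass them explicitly")
    if len(methylation_by_region) != len(regions):
        raise ParameterError(
            f"{len(methylation_by_region)} probability triples for "
            f"{len(regions)} regions")
    for triple in methylation_by_region:
        if len(triple) != 3 or any(not 0.0 <= p <= 1.0 for p in triple):
            raise ParameterError(f"invalid probability triple {triple!r}")

    rng = np.random.default_rng(seed)
    probs: dict[tuple[str, str], np.ndarray] = {}
    for contig in genome.contigs:
        n = genome.length(contig)
        ctx_p, ctx_m = genome.contexts(contig)
        for strand, ctx in (("+", ctx_p), ("-", ctx_m)):
            arr = np.full(n, np.nan)
            arr[ctx != sq.CTX_NONE] = 0.0
            probs[(contig, strand)] = arr

    for (contig, start, end), triple in zip(regions, methylation_by_region):
        if contig == genome.control_contig:
            raise ParameterError("control contig cannot carry a methylated region")
        ctx_p, ctx_m = genome.contexts(contig)
        for strand, ctx in (("+", ctx_p), ("-", ctx_m)):
            arr = probs[(contig, strand)]
            window = slice(start, end)
            for code, p in zip((sq.CTX_CG, sq.CTX_CHG, sq.CTX_CHH), triple):
                sites = np.flatnonzero(ctx[window] == code) + start
                vals = np.full(sites.size, float(p))
                if site_jitter_sd > 0:
                    vals = np.clip(vals + rng.normal(0, site_jitter_sd, sites.size),
                                   0.0, 1.0)
                arr[sites] = vals
    return MethylomeTruth(genome, probs)


# ---------------------------------------------------------------------------
# fragmentation, conversion, amplification
# ---------------------------------------------------------------------------

def simulate_fragments(genome: GenomeSequence, n_fragments: int,
                       fragment_length: int, seed: int) -> list[Fragment]:
    """Uniform fragment origins over valid start positions and both strands,
    contigs weighted by their number of valid starts."""
    if fragment_length <= 0:
        raise ParameterError("fragment_length must be positive")
    shortest = min(genome.length(c) for c in genome.contigs)
    if fragment_length > shortest:
        raise ParameterError(
            f"fragment_length {fragment_length} exceeds shortest contig ({shortest} bp)")
    names = list(genome.contigs)
    starts_per = np.array([genome.length(c) - fragment_length + 1 for c in names])
    rng = np.random.default_rng(seed)
    if n_fragments == 0:
        return []
    contig_idx = rng.choice(len(names), size=n_fragments,
                            p=starts_per / starts_per.sum())
    starts = rng.integers(0, starts_per[contig_idx])
    strands = rng.choice(np.array(["+", "-"]), size=n_fragments)
    frags = []
    for ci, s, st in zip(contig_idx, starts, strands):
        name = names[ci]
        piece = genome.contigs[name][s:s + fragment_length]
        if st == "-":
            piece = sq.revcomp(piece)
        frags.append(Fragment(name, int(s), str(st), piece))
    return frags


def _fragment_positions(frag_len: int, starts: np.ndarray, strand: str) -> np.ndarray:
    """Genome + strand coordinates of each fragment base, read in fragment
    orientation (− strand fragments run right-to-left over the reference)."""
    offs = np.arange(frag_len)
    if strand == "+":
        return starts[:, None] + offs
    return starts[:, None] + (frag_len - 1 - offs)


def _convert_matrix(bases: np.ndarray, probs: np.ndarray, rate: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Vectorised bisulfite chemistry on a (n_frags × L) byte matrix.

    A cytosine is retained as C with probability p + (1 − p)·rate (methylated
    and protected, or unmethylated but unconverted); otherwise it reads T.
    """
    is_c = bases == sq.C
    if np.isnan(probs[is_c]).any():
        raise ConsistencyError("fragment cytosine without a methylome truth record")
    retain = np.where(is_c, probs + (1.0 - probs) * rate, 0.0)
    u = rng.random(bases.shape)
    out = bases.copy()
    out[is_c & (u >= retain)] = sq.T
    return out


def bisulfite_convert_fragment(fragment: Fragment, truth: MethylomeTruth,
                               non_conversion_rate: float, seed: int) -> str:
    """Convert a single fragment; see :func:`bisulfite_convert_pool` for the
    batch form used by the pipeline."""
    if not 0.0 <= non_conversion_rate < 1.0:
        raise ParameterError("non_conversion_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    arr = sq.encode(fragment.sequence)[None, :]
    pos = _fragment_positions(arr.shape[1], np.array([fragment.start]),
                              fragment.strand)
    probs = truth.probs[(fragment.contig, fragment.strand)][pos]
    return sq.decode(_convert_matrix(arr, probs, non_conversion_rate, rng)[0])


def bisulfite_convert_pool(pool: list[Fragment], truth: MethylomeTruth,
                           non_conversion_rate: float, seed: int) -> list[Fragment]:
    """Bisulfite-convert a fragment pool; returns origin-tagged converted
    fragments in the input order.  Deterministic given seed and pool order."""
    if not 0.0 <= non_conversion_rate < 1.0:
        raise ParameterError("non_conversion_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    out: list[Fragment | None] = [None] * len(pool)
    groups: dict[tuple[str, str, int], list[int]] = {}
    for i, f in enumerate(pool):
        groups.setdefault((f.contig, f.strand, len(f.sequence)), []).append(i)
    for key in sorted(groups):
        contig, strand, frag_len = key
        idx = groups[key]
        starts = np.array([pool[i].start for i in idx])
        bases = np.vstack([sq.encode(pool[i].sequence) for i in idx])
        pos = _fragment_positions(frag_len, starts, strand)
        probs = truth.probs[(contig, strand)][pos]
        conv = _convert_matrix(bases, probs, non_conversion_rate, rng)
        for row, i in enumerate(idx):
            f = pool[i]
            out[i] = Fragment(f.contig, f.start, f.strand, sq.decode(conv[row]))
    return out  # type: ignore[return-value]


def amplify_and_sample(pool: list[Fragment], enzyme: EnzymeProfile, cycles: int,
                       depth: int, seed: int,
                       non_conversion_rate: float = 0.0) -> SimulatedLibrary:
    """Draw ``depth`` reads with replacement, fragment f weighted by
    ``(1 + e(g_f))^cycles`` where g_f is the GC fraction of its (converted)
    sequence.  Reads are the full fragment sequences."""
    if not pool:
        raise ParameterError("cannot amplify an empty fragment pool")
    if depth < 1:
        raise ParameterError("depth must be >= 1")
    if cycles < 0:
        raise ParameterError("cycles must be >= 0")
    gc = np.array([sq.gc_fraction(f.sequence) for f in pool])
    w = (1.0 + enzyme.efficiency(gc)) ** cycles
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=depth, p=w / w.sum())
    reads = [SimRead(f"read{i}", pool[j].sequence, pool[j].contig,
                     pool[j].start, pool[j].strand)
             for i, j in enumerate(idx)]
    return SimulatedLibrary(reads, cycles, enzyme.name, non_conversion_rate, seed)
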