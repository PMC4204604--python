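"""Format layer: FASTA, FASTQ, BED, TSV and bedGraph.

Conventions shared by every emitted file: 0-based half-open coordinates,
``+``/``-`` strands, tab-separated tables whose single header line starts
with ``#`` (greppable, diffable), and full-precision floating point
(``repr`` round-trip).  FASTA/FASTQ go through Biopython; simulated reads
are written with the constant dummy quality ``I``.
"""

from __future__ import annotations

import io as _io

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError
from .sequtils import validate_alphabet
from .simulate import GenomeSequence, SimRead, SimulatedLibrary


# -- FASTA ------------------------------------------------------------------

def write_fasta(path, genome: GenomeSequence) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in genome.contigs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path, control_contig: str) -> GenomeSequence:
    contigs = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        contigs[rec.id] = str(rec.seq).upper()
    if not contigs:
        raise FormatError("no FASTA records", path=path)
    return GenomeSequence(contigs, control_contig)


# -- FASTQ ------------------------------------------------------------------

def write_fastq(path, library: SimulatedLibrary) -> None:
    with open(path, "w") as fh:
        for r in library.reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def read_fastq(path) -> list[tuple[str, str]]:
    """(read id, sequence) pairs; any base outside ACGTN is rejected with
    the offending line number."""
    out = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    for i in range(0, len(lines) - 3, 4):
        header, seq = lines[i], lines[i + 1]
        if not header.startswith("@"):
            raise FormatError("FASTQ header must start with '@'",
                              path=path, line=i + 1)
        try:
            validate_alphabet(seq, allow_n=True, what="read")
        except Exception as exc:
            raise FormatError(str(exc), path=path, line=i + 2) from exc
        out.append((header[1:].split()[0], seq))
    return out


# -- generic '#'-headed TSV -------------------------------------------------

def write_tsv(path, frame: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(map(str, frame.columns)) + "\n")
        buf = _io.StringIO()
        frame.to_csv(buf, sep="\t", header=False, index=False,
                     float_format=None)
        fh.write(buf.getvalue())


def read_tsv(path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise FormatError("missing '#' header line", path=path, line=1)
        names = header[1:].rstrip("\n").split("\t")
        body = fh.read()
    if not body.strip():
        return pd.DataFrame(columns=names)
    return pd.read_csv(_io.StringIO(body), sep="\t", names=names)


# -- BED / bedGraph ---------------------------------------------------------

def write_bed(path, windows: pd.DataFrame) -> None:
    windows[["contig", "start", "end"]].to_csv(path, sep="\t", header=False,
                                               index=False)


def read_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError("BED line needs contig, start, end",
                                  path=path, line=i)
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError("non-integer BED coordinate",
                                  path=path, line=i, field=str(exc)) from exc
            if not 0 <= start < end:
                raise FormatError("BED interval must satisfy 0 <= start < end",
                                  path=path, line=i)
            rows.append({"contig": parts[0], "start": start, "end": end})
    return pd.DataFrame(rows, columns=["contig", "start", "end"])


def write_bedgraph(path, windows: pd.DataFrame, values,
                   track_name: str = "track") -> None:
    vals = np.asarray(values, dtype=float)
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{track_name}"\n')
        for (_, w), v in zip(windows.iterrows(), vals):
            if np.isfinite(v):
                fh.write(f"{w['contig']}\t{w['start']}\t{w['end']}\t{v!r}\n")


# -- simulator truth tables -------------------------------------------------

def write_origins(path, library: SimulatedLibrary) -> None:
    frame = pd.DataFrame({
        "read_id": [r.read_id for r in library.reads],
        "contig": [r.contig for r in library.reads],
        "start": [r.start for r in library.reads],
        "strand": [r.strand for r in library.reads],
    })
    write_tsv(path, frame)


def library_from_files(fastq_path, origins_path=None, *, cycles: int = 0,
                       enzyme: str = "unknown",
                       non_conversion_rate: float = 0.0,
                       seed: int = 0) -> SimulatedLibrary:
    reads = read_fastq(fastq_path)
    if origins_path is not None:
        org = read_tsv(origins_path).set_index("read_id")
        sim = [SimRead(rid, seq, str(org.loc[rid, "contig"]),
                       int(org.loc[rid, "start"]), str(org.loc[rid, "strand"]))
               for rid, seq in reads]
    else:
        sim = [SimRead(rid, seq, "", -1, ".") for rid, seq in reads]
    return SimulatedLibrary(sim, cycles, enzyme, non_conversion_rate, seed)
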