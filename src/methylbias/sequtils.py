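"""Byte-level DNA sequence utilities shared across modules.

Sequences are plain Python strings at every public API boundary; internally
they are handled as ``numpy`` uint8 arrays of ASCII codes, which keeps the
fragment-level simulation and the pileup vectorised.

Coordinates are 0-based, intervals half-open, strands ``+``/``-``.
Cytosine contexts follow the plant convention: CG, CHG and CHH with
H ∈ {A, C, T}, read 5'→3' on the strand carrying the cytosine.  A cytosine
too close to the contig end for its context to be resolved is classified
CHH (the absent neighbour cannot be a G).
"""

from __future__ import annotations

import numpy as np

from .errors import AlphabetError, ParameterError

A, C, G, T, N = 65, 67, 71, 84, 78

_COMPLEMENT = np.zeros(256, dtype=np.uint8)
_COMPLEMENT[A], _COMPLEMENT[C], _COMPLEMENT[G], _COMPLEMENT[T] = T, G, C, A
_COMPLEMENT[N] = N

#: context codes used in packed arrays; 0 marks "not a cytosine here"
CTX_NONE, CTX_CG, CTX_CHG, CTX_CHH = 0, 1, 2, 3
CONTEXT_LABELS = np.array(["", "CG", "CHG", "CHH"])

_ACGT = frozenset(b"ACGT")
_ACGTN = frozenset(b"ACGTN")


def encode(seq: str) -> np.ndarray:
    """String → uint8 ASCII array (no copy of semantics, just representation)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def validate_alphabet(seq: str, *, allow_n: bool = False, what: str = "sequence") -> None:
    allowed = _ACGTN if allow_n else _ACGT
    bad = set(seq.encode("ascii", errors="replace")) - allowed
    if bad:
        chars = ", ".join(sorted(chr(b) for b in bad))
        raise AlphabetError(f"{what} contains characters outside the DNA alphabet: {chars}")


def revcomp(seq: str) -> str:
    return decode(_COMPLEMENT[encode(seq)][::-1])


def revcomp_arr(arr: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[arr][::-1]


def complement_arr(arr: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[arr]


def gc_fraction(seq: str | np.ndarray) -> float:
    """(G + C) / length; empty input is a parameter error, not NaN."""
    arr = encode(seq) if isinstance(seq, str) else seq
    if arr.size == 0:
        raise ParameterError("GC content of an empty sequence is undefined")
    return float(np.count_nonzero((arr == G) | (arr == C)) / arr.size)


def context_codes(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-position context codes for both strands of a contig.

    Returns ``(ctx_plus, ctx_minus)`` int8 arrays the length of the contig.
    ``ctx_plus[i] != 0`` iff position i is a C on the + strand; ``ctx_minus``
    marks C's on the − strand (i.e. G's on the + strand), with the context
    read 5'→3' along the − strand.
    """
    n = arr.size
    ctx_p = np.zeros(n, dtype=np.int8)
    is_c = arr == C
    nxt1 = np.zeros(n, dtype=np.uint8)
    nxt1[:-1] = arr[1:]
    nxt2 = np.zeros(n, dtype=np.uint8)
    if n >= 2:
        nxt2[:-2] = arr[2:]
    ctx_p[is_c] = CTX_CHH
    ctx_p[is_c & (nxt2 == G)] = CTX_CHG
    ctx_p[is_c & (nxt1 == G)] = CTX_CG

    ctx_m = np.zeros(n, dtype=np.int8)
    is_cm = arr == G
    prv1 = np.zeros(n, dtype=np.uint8)
    prv1[1:] = arr[:-1]
    prv2 = np.zeros(n, dtype=np.uint8)
    if n >= 2:
        prv2[2:] = arr[:-2]
    ctx_m[is_cm] = CTX_CHH
    ctx_m[is_cm & (prv2 == C)] = CTX_CHG
    ctx_m[is_cm & (prv1 == C)] = CTX_CG
    return ctx_p, ctx_m
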