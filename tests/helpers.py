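"""Shared test helpers: hand-built methylomes and independent brute-force
oracles (kept deliberately naive — summation, sorting and two-pass formulas
— so they stay independent of the implementation paths they check)."""

from __future__ import annotations

import math

import numpy as np

from methylbias import sequtils as sq
from methylbias.simulate import GenomeSequence, MethylomeTruth


def make_truth(genome: GenomeSequence, probs=None, default=0.0) -> MethylomeTruth:
    """MethylomeTruth with ``default`` at every cytosine, overridden by
    ``probs`` = {(contig, strand): {pos: probability}}; control forced 0."""
    probs = probs or {}
    arrays = {}
    for contig in genome.contigs:
        ctx_p, ctx_m = genome.contexts(contig)
        for strand, ctx in (("+", ctx_p), ("-", ctx_m)):
            arr = np.full(genome.length(contig), np.nan)
            base = 0.0 if contig == genome.control_contig else default
            arr[ctx != sq.CTX_NONE] = base
            for pos, p in probs.get((contig, strand), {}).items():
                arr[pos] = p
            arrays[(contig, strand)] = arr
    return MethylomeTruth(genome, arrays)


def binom_upper_tail_bruteforce(k: int, n: int, p: float) -> float:
    """P(X >= k) by direct summation of the binomial pmf."""
    q = 1.0 - p
    return sum(math.comb(n, j) * p**j * q**(n - j) for j in range(k, n + 1))


def bh_bruteforce(pvals, fdr):
    """Step-up BH from its definition: largest k with p_(k) <= (k/m)·fdr
    rejected along with everything smaller; q_(i) = min_{j>=i} (m/j)·p_(j)."""
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    k_star = 0
    for rank, i in enumerate(order, start=1):
        if p[i] <= rank / m * fdr:
            k_star = rank
    q_sorted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        q_sorted[rank - 1] = running
    q = [0.0] * m
    reject = [False] * m
    for rank, i in enumerate(order, start=1):
        q[i] = q_sorted[rank - 1]
        reject[i] = rank <= k_star
    return np.array(q), np.array(reject)


def pearson_twopass(x, y):
    """Two-pass product-moment formula."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)
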