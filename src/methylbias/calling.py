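"""Binomial methylation calling with BH-FDR and weighted methylation levels.

The null hypothesis for each cytosine is the bisulfite *non-conversion*
rate: the fraction of methylated basecalls observed on a known-unmethylated
control contig (the chloroplast stand-in), since an unmethylated C can only
read as C when conversion failed.  Each covered site is tested one-sided
(upper tail — failed conversion can only inflate methylated basecalls) with
the exact binomial tail, and the p-values are corrected with the
Benjamini–Hochberg step-up procedure at a configurable FDR (default 5%).

Weighted methylation of a region is Σ n_meth / Σ n_total over its sites —
coverage-weighted, which is *not* the mean of per-site fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError


@dataclass(frozen=True)
class NonConversionRate:
    """Pooled control-contig methylated-basecall fraction."""

    rate: float
    n_meth_control: int
    n_total_control: int


def estimate_nonconversion(control_counts: pd.DataFrame) -> NonConversionRate:
    """Pool basecalls over every control-contig site and strand.

    ``control_counts`` must already be restricted to the control contig and
    must contain at least one basecall — without control coverage the null
    cannot be formed and calling must not proceed.
    """
    n_meth = int(control_counts["n_meth"].sum())
    n_total = int(control_counts["n_total"].sum())
    if n_total == 0:
        raise ParameterError(
            "no basecalls on the control contig; cannot estimate the "
            "non-conversion rate")
    return NonConversionRate(n_meth / n_total, n_meth, n_total)


def binomial_pvalue(n_meth: int, n_total: int, rate: float) -> float:
    """Exact one-sided upper tail P(X >= n_meth), X ~ Binomial(n_total, rate)."""
    if not 0 <= n_meth <= n_total or n_total < 1:
        raise ParameterError(f"invalid counts {n_meth}/{n_total}")
    if not 0.0 <= rate < 1.0:
        raise ParameterError("rate must be in [0, 1)")
    # sf(k-1) is the exact survival sum P(X >= k)
    return float(stats.binom.sf(n_meth - 1, n_total, rate))


def bh_adjust(p_values, fdr: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: (q_values, reject flags) in input order.

    q_(i) = min_{j >= i} (m/j)·p_(j) capped at 1; the site is rejected iff it
    is at or below the largest k with p_(k) <= (k/m)·fdr.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if ((p < 0) | (p > 1)).any():
        raise ParameterError("p-values must lie in [0, 1]")
    if not 0.0 < fdr < 1.0:
        raise ParameterError("fdr must be in (0, 1)")
    reject, q, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
    return q, reject


def call_methylation(counts: pd.DataFrame, rate: NonConversionRate | float,
                     fdr: float = 0.05, min_coverage: int = 1,
                     by_context: bool = False) -> pd.DataFrame:
    """Per-site binomial tests with joint BH correction.

    Sites with ``n_total >= min_coverage`` are tested; BH runs over all
    tested sites in one batch by default (``by_context=True`` stratifies the
    correction per context instead — the batching convention is a config
    choice, not a property of the data).  Sites below the coverage floor
    carry ``called=False`` and NaN p/q.
    """
    if not 0.0 < fdr < 1.0:
        raise ParameterError("fdr must be in (0, 1)")
    if min_coverage < 1:
        raise ParameterError("min_coverage must be >= 1")
    r = rate.rate if isinstance(rate, NonConversionRate) else float(rate)
    out = counts.copy()
    out["p_value"] = np.nan
    out["q_value"] = np.nan
    out["called"] = False
    tested = out["n_total"] >= min_coverage
    if tested.any():
        k = out.loc[tested, "n_meth"].to_numpy()
        n = out.loc[tested, "n_total"].to_numpy()
        p = stats.binom.sf(k - 1, n, r)
        out.loc[tested, "p_value"] = p
        if by_context:
            for _, idx in out.index[tested].groupby(
                    out.loc[tested, "context"].to_numpy()).items():
                q, rej = bh_adjust(out.loc[idx, "p_value"].to_numpy(), fdr)
                out.loc[idx, "q_value"] = q
                out.loc[idx, "called"] = rej
        else:
            q, rej = bh_adjust(p, fdr)
            out.loc[tested, "q_value"] = q
            out.loc[tested, "called"] = rej
    return out


def weighted_methylation(counts: pd.DataFrame,
                         contexts=None) -> float:
    """Σ n_meth / Σ n_total over the given sites (optionally one or more
    contexts); NaN — missing, never 0 — when there are no basecalls."""
    df = counts
    if contexts is not None:
        wanted = {contexts} if isinstance(contexts, str) else set(contexts)
        df = df[df["context"].isin(wanted)]
    total = df["n_total"].sum()
    if total == 0:
        return float("nan")
    return float(df["n_meth"].sum() / total)
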