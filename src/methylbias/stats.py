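"""Correlation, Bonferroni outlier screening and trimmed regression.

The headline statistic of a coverage-bias analysis is the linear fit of
normalized window coverage against window methylation (or GC): Pearson r,
its square, and an OLS slope computed after removing gross outliers.
Outliers are screened with the standard Bonferroni outlier test on
externally studentized residuals (two-sided t with n−3 df for a simple
regression, p multiplied by n), removing the worst point and refitting
until nothing is flagged or a cap — by default 5% of the points — is
reached.  A one-shot (no refit) mode is available; with the cap at 0 the
procedure reduces to plain OLS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import ParameterError


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r: float
    r_squared: float
    slope_se: float
    slope_t: float
    n_input: int
    n_used: int
    outlier_indices: tuple[int, ...]


def pearson_r(x, y) -> float:
    """Product-moment correlation; NaN (missing) when either input is
    degenerate (zero variance)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be equal-length vectors")
    if x.size < 3:
        raise ParameterError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(sps.pearsonr(x, y).statistic)


def _residual_flags(x: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    if fit.ssr <= 1e-12 * max(1.0, float(np.dot(y, y))):
        # (near-)perfect fit: studentized residuals are 0/0, nothing to flag
        return pd.DataFrame({"student_resid": np.zeros(len(x)),
                             "bonf(p)": np.ones(len(x))})
    test = pd.DataFrame(np.asarray(fit.outlier_test(method="bonf")),
                        columns=["student_resid", "unadj_p", "bonf(p)"])
    return test.fillna({"student_resid": 0.0, "bonf(p)": 1.0})


def bonferroni_outliers(x, y, alpha: float = 0.05,
                        max_fraction: float = 0.05,
                        one_shot: bool = False) -> set[int]:
    """Indices of Bonferroni-significant regression outliers.

    Iterates largest-residual-first with a refit after each removal until no
    point is flagged or ceil(max_fraction·n) points have been removed.
    ``one_shot=True`` flags from the initial fit only, still capped and in
    residual order.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be equal-length vectors")
    n = x.size
    if n < 5:
        raise ParameterError("need at least 5 points for outlier screening")
    if not 0.0 < alpha < 1.0:
        raise ParameterError("alpha must be in (0, 1)")
    if not 0.0 <= max_fraction <= 1.0:
        raise ParameterError("max_fraction must be in [0, 1]")
    cap = math.ceil(max_fraction * n)
    outliers: set[int] = set()
    if cap == 0:
        return outliers
    if one_shot:
        test = _residual_flags(x, y)
        order = np.argsort(-np.abs(test["student_resid"].to_numpy()))
        for i in order[:cap]:
            if test["bonf(p)"].iloc[i] < alpha:
                outliers.add(int(i))
        return outliers
    active = np.arange(n)
    while len(outliers) < cap and active.size >= 5:
        test = _residual_flags(x[active], y[active])
        worst = int(np.argmax(np.abs(test["student_resid"].to_numpy())))
        if test["bonf(p)"].iloc[worst] >= alpha:
            break
        outliers.add(int(active[worst]))
        active = np.delete(active, worst)
    return outliers


def trimmed_regression(x, y, alpha: float = 0.05,
                       max_fraction: float = 0.05,
                       one_shot: bool = False) -> RegressionResult:
    """OLS after Bonferroni outlier removal.

    With ``max_fraction=0`` this is exactly plain OLS on all points.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be equal-length vectors")
    keep = np.isfinite(x) & np.isfinite(y)
    idx = np.flatnonzero(keep)
    n_input = x.size
    xs, ys = x[idx], y[idx]
    if xs.size < 3:
        raise ParameterError("need at least 3 finite points")
    if max_fraction > 0 and xs.size >= 5:
        local_out = bonferroni_outliers(xs, ys, alpha=alpha,
                                        max_fraction=max_fraction,
                                        one_shot=one_shot)
    else:
        local_out = set()
    outlier_indices = tuple(sorted(int(idx[i]) for i in local_out))
    mask = np.ones(xs.size, dtype=bool)
    mask[list(local_out)] = False
    xr, yr = xs[mask], ys[mask]
    fit = sps.linregress(xr, yr)
    r = float(fit.rvalue)
    slope_se = float(fit.stderr)
    slope_t = float(fit.slope / slope_se) if slope_se > 0 else float("nan")
    return RegressionResult(
        slope=float(fit.slope), intercept=float(fit.intercept),
        r=r, r_squared=r * r, slope_se=slope_se, slope_t=slope_t,
        n_input=n_input, n_used=int(xr.size),
        outlier_indices=outlier_indices)


def cycle_correlation_matrix(libraries: dict[str, np.ndarray | pd.Series]) -> pd.DataFrame:
    """Pairwise Pearson r of per-window scaled counts over shared
    non-missing windows; all libraries must share one window set."""
    names = list(libraries)
    if len(names) < 2:
        raise ParameterError("need at least two libraries")
    arrays = {k: np.asarray(v, dtype=float) for k, v in libraries.items()}
    n = {a.size for a in arrays.values()}
    if len(n) != 1:
        raise ParameterError("libraries cover different window sets")
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            va, vb = arrays[a], arrays[b]
            ok = np.isfinite(va) & np.isfinite(vb)
            r = pearson_r(va[ok], vb[ok])
            out.loc[a, b] = out.loc[b, a] = r
    return out
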