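"""Rank correlation between windowed light exposure and sleep outcomes.

Spearman's rho is computed as the product-moment correlation of average
ranks (which reduces to 1 - 6*sum(d^2) / (n(n^2-1)) in the tie-free case).
For small samples of tie-free ranks (n <= 10) the p-value comes from full
enumeration of the exact permutation null distribution of rho (n!
arrangements, observed configuration included in the count); larger n, or
tied data, fall back to the usual t approximation and are flagged.

Sidedness: the one-sided p is taken in the direction of the observed
coefficient (sign reflection for negative rho). Multiple comparisons over
the seven light time frames are handled per outcome column with the
Bonferroni-Holm step-down correction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from math import factorial

import numpy as np
import pandas as pd
from scipy import stats

from . import light

EXACT_MAX_N = 10
ALPHA = 0.05

#: Table-3 outcome columns (polarity times in hours after sleep onset)
OUTCOME_COLUMNS = (
    "n2_min",
    "sws_min",
    "sws_polarity_time_h",
    "sws_polarity_strength",
    "rems_min",
    "rems_latency_min",
    "rem_polarity_time_h",
    "rem_polarity_strength",
)
FRAME_LABELS = tuple(w.label for w in light.ASSOCIATION_FRAMES)


@dataclass
class RankCorrelation:
    rho: float
    n: int
    d_sq_sum: int | None  # sum of squared rank differences; None when tied
    p_raw: float
    sided: str  # "one" | "two"
    method: str  # "exact" | "t-approx"
    flags: tuple[str, ...] = ()


def spearman_rho(x, y) -> tuple[float, int | None]:
    """(rho, sum d^2). ``d_sq_sum`` is None when either vector has ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: rho undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    tied = (np.unique(rx).size < n) or (np.unique(ry).size < n)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if tied:
        return rho, None
    dsq = int(round(np.sum((rx - ry) ** 2)))
    return rho, dsq


@lru_cache(maxsize=None)
def null_dsq_distribution(n: int) -> np.ndarray:
    """Sorted sum-of-d^2 values over all n! rank permutations."""
    if n > EXACT_MAX_N:
        raise ValueError(f"enumeration capped at n={EXACT_MAX_N}")
    base = np.arange(n)
    perms = np.array(list(itertools.permutations(range(n))), dtype=np.int16)
    dsq = ((perms - base) ** 2).sum(axis=1)
    dsq.sort()
    return dsq


def _dsq_of_rho(rho: float, n: int) -> float:
    return (1.0 - rho) * n * (n * n - 1) / 6.0


def exact_perm_p(rho_obs: float, n: int, sided: str = "one") -> float:
    """Exact permutation p-value for a tie-free Spearman coefficient.

    One-sided: proportion of permutations with rho >= rho_obs (reflected
    for negative rho_obs). Two-sided: proportion with |rho| >= |rho_obs|.
    The observed configuration is always counted.
    """
    null = null_dsq_distribution(n)
    total = factorial(n)
    d_obs = _dsq_of_rho(rho_obs, n)
    d_max = n * (n * n - 1) / 3.0  # rho = -1
    # sum-of-d^2 lattice points are even integers; a half-unit tolerance
    # absorbs float error in rho (including 3-d.p.-rounded coefficients)
    eps = 0.5
    upper = int(np.searchsorted(null, d_obs + eps, side="left"))  # rho >= obs
    lower = total - int(np.searchsorted(null, d_obs - eps,
                                        side="right"))  # rho <= obs
    if sided == "one":
        return (upper if rho_obs >= 0 else lower) / total
    if sided == "two":
        if abs(rho_obs) < 1e-12:
            return 1.0
        lo_d, hi_d = min(d_obs, d_max - d_obs), max(d_obs, d_max - d_obs)
        p = (int(np.searchsorted(null, lo_d + eps, side="left"))
             + total - int(np.searchsorted(null, hi_d - eps, side="right")))
        return min(1.0, p / total)
    raise ValueError("sided must be 'one' or 'two'")


def t_approx_p(rho: float, n: int, sided: str = "one") -> float:
    """Student-t approximation t = rho * sqrt((n-2)/(1-rho^2))."""
    if abs(rho) >= 1.0:
        return 0.0
    tstat = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    sf = float(stats.t.sf(abs(tstat), df=n - 2))
    return sf if sided == "one" else min(1.0, 2.0 * sf)


def rank_correlation(x, y, sided: str = "one",
                     exact_max_n: int = EXACT_MAX_N) -> RankCorrelation:
    """Spearman rho with exact (n <= exact_max_n, tie-free) or t p-value."""
    rho, dsq = spearman_rho(x, y)
    n = len(x)
    flags: list[str] = []
    if dsq is not None and n <= exact_max_n:
        p = exact_perm_p(rho, n, sided)
        method = "exact"
    else:
        if dsq is None:
            flags.append("ties")
        if n > exact_max_n:
            flags.append("n_above_exact_limit")
        p = t_approx_p(rho, n, sided)
        method = "t-approx"
    return RankCorrelation(rho, n, dsq, p, sided, method, tuple(flags))


def holm_adjust(p_values) -> np.ndarray:
    """Bonferroni-Holm step-down adjustment, returned in the input order.

    The k-th smallest of m p-values is multiplied by (m - k + 1); a running
    maximum enforces monotonicity and results are capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("need a non-empty 1-d p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * (m - np.arange(m))
    adj = np.minimum(np.maximum.accumulate(adj), 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def build_table(
    light_medians: pd.DataFrame,
    outcomes: pd.DataFrame,
    sided: str = "one",
    exact_max_n: int = EXACT_MAX_N,
    holm_scope: str = "column",
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Frames x outcomes grid of Spearman rho with Holm-adjusted p-values.

    ``light_medians``: subjects x frame labels (median lux per frame);
    ``outcomes``: subjects x outcome labels, aligned on the same index.
    Missing pairs are dropped per cell; cells with n < 3 are flagged and
    excluded from the Holm family. ``holm_scope`` is "column" (the default:
    the seven frames per outcome, as the study frames multiplicity) or
    "table" (all cells at once).
    """
    frames = [c for c in FRAME_LABELS if c in light_medians.columns] or \
        list(light_medians.columns)
    cols = [c for c in OUTCOME_COLUMNS if c in outcomes.columns] or \
        list(outcomes.columns)
    idx = light_medians.index.intersection(outcomes.index)
    rows = []
    for out_col in cols:
        for fr in frames:
            x = light_medians.loc[idx, fr].to_numpy(dtype=float)
            y = outcomes.loc[idx, out_col].to_numpy(dtype=float)
            keep = np.isfinite(x) & np.isfinite(y)
            cell = {"frame": fr, "outcome": out_col, "n": int(keep.sum())}
            if cell["n"] < 3:
                cell.update(rho=np.nan, p_raw=np.nan, method="",
                            flags="insufficient_n")
            else:
                rc = rank_correlation(x[keep], y[keep], sided, exact_max_n)
                cell.update(rho=rc.rho, p_raw=rc.p_raw, method=rc.method,
                            flags=";".join(rc.flags))
            rows.append(cell)
    table = pd.DataFrame(rows)
    table["p_adj"] = np.nan
    if holm_scope == "column":
        groups = [g.index for _, g in table.groupby("outcome", sort=False)]
    elif holm_scope == "table":
        groups = [table.index]
    else:
        raise ValueError("holm_scope must be 'column' or 'table'")
    for g in groups:
        defined = table.loc[g, "p_raw"].notna()
        sub = table.loc[g][defined]
        if len(sub):
            table.loc[sub.index, "p_adj"] = holm_adjust(sub["p_raw"].to_numpy())
    table["significant"] = table["p_adj"] <= alpha
    return table
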