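"""Spearman rho, exact permutation inference, Holm correction."""

import itertools
from math import factorial

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from luxsleep import association
from luxsleep.association import (build_table, exact_perm_p, holm_adjust,
                                  null_dsq_distribution, rank_correlation,
                                  spearman_rho, t_approx_p)

X9 = np.arange(1, 10)


def test_monotone_link_gives_rho_one():
    x = np.array([3.0, 1.0, 7.5, 2.0, 9.0, 5.0])
    rho, dsq = spearman_rho(x, np.exp(x))
    assert rho == pytest.approx(1.0)
    assert dsq == 0


@pytest.mark.parametrize("y, dsq_expect, rho_3dp", [
    ([4, 2, 1, 3, 6, 5, 8, 9, 7], 22, 0.817),
    ([8, 9, 6, 7, 3, 4, 5, 1, 2], 226, -0.883),
])
def test_printed_rank_configurations(y, dsq_expect, rho_3dp):
    rho, dsq = spearman_rho(X9, np.array(y))
    assert dsq == dsq_expect
    assert round(rho, 3) == rho_3dp
    # cross-check against the reference implementation
    assert rho == pytest.approx(sps.spearmanr(X9, y).statistic, abs=1e-12)


def test_rho_matches_scipy_with_ties(rng):
    for _ in range(30):
        x = rng.integers(0, 6, 10).astype(float)
        y = rng.integers(0, 6, 10).astype(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        rho, dsq = spearman_rho(x, y)
        assert rho == pytest.approx(sps.spearmanr(x, y).statistic, abs=1e-12)


def test_antisymmetry(rng):
    for _ in range(20):
        x = rng.permutation(9).astype(float)
        y = rng.permutation(9).astype(float)
        assert spearman_rho(x, -y)[0] == pytest.approx(
            -spearman_rho(x, y)[0], abs=1e-12)


def test_constant_vector_rejected():
    with pytest.raises(ValueError, match="constant"):
        spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_exact_p_small_cases():
    # n = 3, rho = 1: a single permutation of 3! = 6 attains it
    assert exact_perm_p(1.0, 3, "one") == pytest.approx(1 / 6)
    # full-enumeration oracle at n = 6, independent code path
    n = 6
    for rho_obs in (0.6, -0.7714285714285715, 0.2):
        count = 0
        for perm in itertools.permutations(range(n)):
            r = np.corrcoef(np.arange(n), perm)[0, 1]
            if (rho_obs >= 0 and r >= rho_obs - 1e-9) or \
               (rho_obs < 0 and r <= rho_obs + 1e-9):
                count += 1
        assert exact_perm_p(rho_obs, n, "one") == pytest.approx(
            count / factorial(n))


def test_exact_p_headline_value():
    """One-sided exact p for the strongest printed coefficient at n = 9.

    The value 0.0053847 was independently verified with R's
    cor.test(..., method="spearman", alternative="greater", exact=TRUE).
    """
    rho, _ = spearman_rho(X9, np.array([4, 2, 1, 3, 6, 5, 8, 9, 7]))
    assert exact_perm_p(rho, 9, "one") == pytest.approx(0.0053847, abs=5e-8)
    assert exact_perm_p(rho, 9, "two") == pytest.approx(0.0107694, abs=1e-7)


def test_exact_p_uniformity_at_n7():
    """Each attainable one-sided p equals its own exceedance probability.

    Over all 5040 rank permutations at n = 7 the upper-tail p-values form
    the exact attainable discrete uniform (p = P(rho' >= rho) = its own
    CDF value); the reflected (negative-rho) side mirrors it exactly.
    """
    null = null_dsq_distribution(7)
    total = factorial(7)
    values, counts = np.unique(null, return_counts=True)
    cum = np.cumsum(counts)
    center = 7 * 48 / 6.0  # sum d^2 at rho = 0
    for d, c, n_at in zip(values, cum, counts):
        rho = 1.0 - 6.0 * d / (7 * 48)
        p = exact_perm_p(rho, 7, "one")
        if rho >= 0:
            # upper tail: P(d' <= d), the discrete uniform CDF value
            assert p == pytest.approx(c / total)
        else:
            # sign reflection: lower tail P(d' >= d)
            assert p == pytest.approx((total - c + n_at) / total)
        # null symmetry: the mirrored coefficient has the same p
        assert p == pytest.approx(exact_perm_p(-rho, 7, "one"))
    # the null distribution is symmetric about rho = 0
    assert np.count_nonzero(null <= center - 2) \
        == np.count_nonzero(null >= center + 2)


def test_exact_p_monotone_in_rho_at_n7():
    """Tail probabilities shrink as the coefficient grows in magnitude."""
    d_max = 7 * 48 // 3  # rho = -1
    lattice = [1.0 - 6.0 * d / (7 * 48) for d in range(0, d_max + 1, 2)]
    pos = sorted(r for r in lattice if r >= 0)
    ps = [exact_perm_p(r, 7, "one") for r in pos]
    assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))
    neg = sorted((r for r in lattice if r < 0), reverse=True)
    ps = [exact_perm_p(r, 7, "one") for r in neg]
    assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))
    two = [exact_perm_p(r, 7, "two") for r in pos]
    assert all(a >= b - 1e-15 for a, b in zip(two, two[1:]))


def test_t_approximation_close_to_exact_for_moderate_rho():
    null = null_dsq_distribution(9)
    for d in np.unique(null):
        rho = 1.0 - 6.0 * d / (9 * 80)
        if abs(rho) > 0.5:
            continue
        assert abs(t_approx_p(rho, 9, "one")
                   - exact_perm_p(rho, 9, "one")) < 0.01


def test_rank_correlation_fallbacks():
    rc = rank_correlation([1, 2, 2, 4, 5], [2, 1, 4, 3, 5])
    assert rc.method == "t-approx" and "ties" in rc.flags
    rc = rank_correlation(np.arange(12.0), np.arange(12.0) ** 2)
    assert rc.method == "t-approx" and "n_above_exact_limit" in rc.flags
    rc = rank_correlation(X9, [4, 2, 1, 3, 6, 5, 8, 9, 7])
    assert rc.method == "exact" and rc.d_sq_sum == 22


def holm_oracle(p):
    """Definitional step-down: reject smallest p at alpha/m, then alpha/(m-1)..."""
    m = len(p)
    idx = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 0.0
    for k, i in enumerate(idx):
        running = max(running, (m - k) * p[i])
        adj[i] = min(1.0, running)
    return adj


def test_holm_examples_and_oracle(rng):
    assert holm_adjust([0.01, 0.04, 0.03]) == pytest.approx(
        [0.03, 0.06, 0.06])
    assert holm_adjust([0.2]) == pytest.approx([0.2])
    with pytest.raises(ValueError):
        holm_adjust([0.5, 1.5])
    for _ in range(200):
        p = rng.random(int(rng.integers(1, 12)))
        assert holm_adjust(p) == pytest.approx(holm_oracle(list(p)))


def test_holm_matches_statsmodels(rng):
    from statsmodels.stats.multitest import multipletests

    for _ in range(20):
        p = rng.random(7)
        got = holm_adjust(p)
        expect = multipletests(p, method="holm")[1]
        assert got == pytest.approx(expect)


def test_holm_rejection_bracketing(rng):
    alpha = 0.05
    for _ in range(100):
        p = rng.random(7) ** 2
        adj = holm_adjust(p)
        n_holm = int(np.sum(adj <= alpha))
        n_raw = int(np.sum(p <= alpha))
        n_bonf = int(np.sum(p * len(p) <= alpha))
        assert n_bonf <= n_holm <= n_raw


def _planted_tables(rng):
    frames = list(association.FRAME_LABELS)
    med = pd.DataFrame(rng.lognormal(3, 1, (9, 7)), columns=frames,
                       index=[f"S{i}" for i in range(9)])
    out = pd.DataFrame(rng.normal(size=(9, 8)),
                       columns=list(association.OUTCOME_COLUMNS),
                       index=med.index)
    # plant a perfect monotone link: midday frame -> REM latency
    out["rems_latency_min"] = np.argsort(np.argsort(med["11:00-13:00"])) * 7.0
    return med, out


def test_build_table_planted_link_and_holm_rank1(rng):
    med, out = _planted_tables(rng)
    table = build_table(med, out)
    assert len(table) == 56
    col = table[table.outcome == "rems_latency_min"].set_index("frame")
    assert abs(col.loc["11:00-13:00", "rho"]) == col["rho"].abs().max()
    assert col.loc["11:00-13:00", "rho"] == pytest.approx(1.0)
    # the planted cell is Holm rank 1 among its seven frames
    assert col.loc["11:00-13:00", "p_adj"] == pytest.approx(
        7 * col.loc["11:00-13:00", "p_raw"])
    assert bool(col.loc["11:00-13:00", "significant"])
    # per-column family: p_adj never smaller than p_raw, never above 1
    assert (table.p_adj >= table.p_raw - 1e-15).all()
    assert (table.p_adj <= 1.0).all()


def test_build_table_pairwise_missing(rng):
    med, out = _planted_tables(rng)
    med.loc["S0", "07:00-09:00"] = np.nan
    out.loc["S1", "sws_min"] = np.nan
    table = build_table(med, out).set_index(["frame", "outcome"])
    assert table.loc[("07:00-09:00", "sws_min"), "n"] == 7
    assert table.loc[("09:00-11:00", "sws_min"), "n"] == 8
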