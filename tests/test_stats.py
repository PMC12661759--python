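"""Brute-force oracles for the nonparametric primitives."""

import itertools
import math

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

from csfbench.stats import (
    bh_adjust,
    fisher_2x2,
    spearman,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def signed_rank_exact_oracle(diffs):
    """Two-sided exact p by enumerating every sign assignment."""
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    ranks = scipy.stats.rankdata(np.abs(d))
    observed = ranks[d > 0].sum()
    stats = [
        np.asarray(ranks)[np.array(signs, dtype=bool)].sum()
        for signs in itertools.product([0, 1], repeat=len(d))
    ]
    stats = np.asarray(stats)
    lower = np.mean(stats <= observed + 1e-9)
    upper = np.mean(stats >= observed - 1e-9)
    return min(1.0, 2 * min(lower, upper)), observed


def rank_sum_exact_oracle(x, y):
    """Two-sided exact p by enumerating every group labeling."""
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    nx = len(x)
    observed = ranks[:nx].sum() - nx * (nx + 1) / 2
    stats = [
        ranks[list(idx)].sum() - nx * (nx + 1) / 2
        for idx in itertools.combinations(range(len(pooled)), nx)
    ]
    stats = np.asarray(stats)
    lower = np.mean(stats <= observed + 1e-9)
    upper = np.mean(stats >= observed - 1e-9)
    return min(1.0, 2 * min(lower, upper))


def bh_oracle(p):
    """Hand step-up: q_(i) = min_{j>=i} m p_(j) / j, in input order."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for pos, i in enumerate(order):
        q[i] = min(min(1.0, m * p[order[j]] / (j + 1)) for j in range(pos, m))
    return q.tolist()


def fisher_oracle_p(a, b, c, d):
    """Sum of hypergeometric point masses <= the observed one."""
    m1, m2, n = a + b, c + d, a + c
    rv = scipy.stats.hypergeom(m1 + m2, m1, n)
    support = np.arange(max(0, n - m2), min(n, m1) + 1)
    pmf = rv.pmf(support)
    observed = rv.pmf(a)
    return float(pmf[pmf <= observed * (1 + 1e-7)].sum())


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def test_signed_rank_all_positive_n6_exact():
    result = wilcoxon_signed_rank([1, 2, 3, 4, 5, 6])
    assert result.method_note == "exact"
    assert result.p_value == pytest.approx(2 / 64)
    assert result.n_effective == 6


def test_signed_rank_symmetric_pairs_centered():
    result = wilcoxon_signed_rank([1, -1, 2, -2])
    assert result.p_value == pytest.approx(1.0)


def test_signed_rank_zero_handling_and_errors():
    # zeros are dropped before ranking
    assert wilcoxon_signed_rank([0.0, 1.0, 2.0, -0.5]).n_effective == 3
    with pytest.raises(ValueError):
        wilcoxon_signed_rank([0.0, 0.0])
    with pytest.raises(ValueError):
        wilcoxon_signed_rank([])


@settings(max_examples=150, deadline=None, derandomize=True)
@given(
    st.lists(
        st.integers(min_value=-50, max_value=50).filter(lambda v: v != 0),
        min_size=1,
        max_size=10,
        unique_by=abs,
    )
)
def test_signed_rank_exact_matches_enumeration(diffs):
    """Exact mode reproduces the full sign-assignment null for n <= 10."""
    expected_p, expected_w = signed_rank_exact_oracle(diffs)
    result = wilcoxon_signed_rank(diffs)
    assert result.method_note == "exact"
    assert result.statistic == pytest.approx(expected_w)
    assert result.p_value == pytest.approx(expected_p)


def test_signed_rank_approximation_close_to_monte_carlo():
    """Tie-corrected normal approximation vs a permutation oracle, n=20."""
    rng = np.random.default_rng(5)
    diffs = np.round(rng.normal(0.3, 1.0, size=20), 1)  # rounding makes ties
    diffs = diffs[diffs != 0]
    result = wilcoxon_signed_rank(diffs)
    ranks = scipy.stats.rankdata(np.abs(diffs))
    signs = rng.random((100_000, len(diffs))) < 0.5
    w = (ranks[None, :] * signs).sum(axis=1)
    observed = ranks[diffs > 0].sum()
    p_mc = min(
        1.0,
        2 * min(np.mean(w <= observed + 1e-9), np.mean(w >= observed - 1e-9)),
    )
    assert result.p_value == pytest.approx(p_mc, abs=0.01)


def test_signed_rank_matches_scipy_exact():
    d = [3.0, -1.0, 4.5, 2.0, -0.5, 6.0, 1.5]
    ours = wilcoxon_signed_rank(d)
    ref = scipy.stats.wilcoxon(d, mode="exact")
    assert ours.p_value == pytest.approx(ref.pvalue)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def test_rank_sum_spec_example():
    result = wilcoxon_rank_sum([1, 2], [3, 4])
    assert result.statistic == 0
    assert result.p_value == pytest.approx(1 / 3)


def test_rank_sum_identical_groups_p_one():
    assert wilcoxon_rank_sum([5.0, 1.0, 2.0], [1.0, 2.0, 5.0]).p_value == 1.0


def test_rank_sum_empty_group_errors():
    with pytest.raises(ValueError):
        wilcoxon_rank_sum([], [1.0])


@settings(max_examples=150, deadline=None, derandomize=True)
@given(
    st.lists(st.integers(-30, 30), min_size=2, max_size=10, unique=True),
    st.integers(1, 9),
)
def test_rank_sum_exact_matches_enumeration(values, split):
    if split >= len(values):
        split = len(values) - 1
    x, y = values[:split], values[split:]
    result = wilcoxon_rank_sum(x, y)
    assert result.method_note == "exact"
    assert result.p_value == pytest.approx(rank_sum_exact_oracle(x, y))


def test_rank_sum_approximation_close_to_permutation_oracle():
    rng = np.random.default_rng(11)
    x = np.round(rng.normal(0.0, 1.0, 15), 1)
    y = np.round(rng.normal(0.6, 1.0, 12), 1)
    result = wilcoxon_rank_sum(x, y)
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    observed = ranks[: len(x)].sum() - len(x) * (len(x) + 1) / 2
    draws = np.array(
        [
            ranks[rng.permutation(len(pooled))[: len(x)]].sum()
            - len(x) * (len(x) + 1) / 2
            for _ in range(100_000)
        ]
    )
    p_mc = min(
        1.0,
        2
        * min(
            np.mean(draws <= observed + 1e-9), np.mean(draws >= observed - 1e-9)
        ),
    )
    assert result.p_value == pytest.approx(p_mc, abs=0.01)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def test_bh_spec_examples():
    assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
        [0.04, 0.04, 0.04, 0.04]
    )
    assert bh_adjust([0.5]) == [0.5]
    assert bh_adjust([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.1, 1.5])


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40)
)
def test_bh_matches_oracle_and_is_monotone(p):
    q = bh_adjust(p)
    assert q == pytest.approx(bh_oracle(p))
    assert all(0 <= v <= 1 for v in q)
    for (pi, qi), (pj, qj) in itertools.combinations(zip(p, q), 2):
        if pi <= pj:
            assert qi <= qj + 1e-12


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

def test_fisher_spec_examples():
    low = fisher_2x2(1, 9, 11, 3)
    assert low.p_value == pytest.approx(fisher_oracle_p(1, 9, 11, 3))
    assert low.odds_ratio < 1
    mid = fisher_2x2(5, 5, 5, 5)
    assert mid.p_value == pytest.approx(1.0)
    assert mid.odds_ratio == pytest.approx(1.0, abs=1e-6)
    assert mid.log2_odds_ratio == pytest.approx(0.0, abs=1e-6)
    extreme = fisher_2x2(10, 0, 0, 10)
    assert extreme.odds_ratio == math.inf
    assert extreme.p_value == pytest.approx(fisher_oracle_p(10, 0, 0, 10))


def test_fisher_degenerate_margin_errors():
    with pytest.raises(ValueError):
        fisher_2x2(0, 0, 3, 4)


def test_fisher_matches_brute_force_small_tables():
    """p equals the hypergeometric-tail sum on a sweep of small tables."""
    for a, b, c, d in itertools.product(range(6), repeat=4):
        if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
            continue
        result = fisher_2x2(a, b, c, d)
        assert result.p_value == pytest.approx(
            fisher_oracle_p(a, b, c, d), abs=1e-10
        ), (a, b, c, d)


def test_fisher_odds_ratio_is_conditional_mle():
    """OR matches scipy's conditional-MLE estimator on assorted tables."""
    tables = [(3, 7, 9, 2), (12, 4, 5, 9), (1, 9, 11, 3), (8, 8, 8, 9)]
    for a, b, c, d in tables:
        ours = fisher_2x2(a, b, c, d)
        ref = scipy.stats.contingency.odds_ratio(
            [[a, b], [c, d]], kind="conditional"
        )
        assert ours.odds_ratio == pytest.approx(ref.statistic, rel=1e-4)
        ref_p = scipy.stats.fisher_exact([[a, b], [c, d]])[1]
        assert ours.p_value == pytest.approx(ref_p, rel=1e-9)


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

def test_spearman_rank_invariance_and_reversal():
    x = [1.0, 2.0, 5.0, 9.0]
    assert spearman(x, np.exp(x)) == pytest.approx(1.0)
    assert spearman(x, [-v for v in x]) == pytest.approx(-1.0)


def test_spearman_missing_and_degenerate():
    assert math.isnan(spearman([1, 2], [1, 2]))
    assert math.isnan(spearman([1, 1, 1], [1, 2, 3]))
    # pairwise-complete removal
    x = [1.0, 2.0, np.nan, 4.0, 5.0]
    y = [2.0, 4.0, 9.0, 8.0, 10.0]
    assert spearman(x, y) == pytest.approx(1.0)


def test_spearman_ties_match_midrank_pearson_oracle(rng):
    for _ in range(25):
        x = rng.integers(0, 5, size=12).astype(float)
        y = rng.integers(0, 5, size=12).astype(float)
        rx = scipy.stats.rankdata(x)
        ry = scipy.stats.rankdata(y)
        if np.std(rx) == 0 or np.std(ry) == 0:
            continue
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y) == pytest.approx(expected, abs=1e-12)
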