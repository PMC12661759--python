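"""Elementary nonparametric statistics used throughout the pipeline.

Every routine here is implemented from first principles so that it can be
checked against brute-force enumeration oracles: exact Wilcoxon tests by
enumerating sign assignments / group labelings at small n, Fisher's exact
test by summing hypergeometric point probabilities, and the conditional
maximum-likelihood odds ratio by solving the noncentral hypergeometric
score equation.

Conventions
-----------
* Wilcoxon signed-rank drops zero differences (the classic convention,
  matching the default of ``wilcox.test`` in R).
* Both Wilcoxon tests switch from exact enumeration to a normal
  approximation (tie-corrected, with continuity correction) when the
  sample size exceeds :data:`EXACT_N_MAX` or ties are present; the mode
  used is recorded in ``TestResult.method_note``.
* Odds ratios for tables with a zero off-diagonal cell are reported as
  ``inf``/``0`` rather than clamped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.special import gammaln

__all__ = [
    "TestResult",
    "OddsRatioResult",
    "wilcoxon_signed_rank",
    "wilcoxon_rank_sum",
    "bh_adjust",
    "fisher_2x2",
    "spearman",
]

#: largest total sample size for which the exact null distribution is used
EXACT_N_MAX = 12


@dataclass(frozen=True)
class TestResult:
    """Outcome of a rank test: statistic, two-sided p, and bookkeeping."""

    statistic: float
    p_value: float
    n_effective: int
    method_note: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value outside [0, 1]: {self.p_value}")
        if self.n_effective < 0:
            raise ValueError("n_effective must be >= 0")


@dataclass(frozen=True)
class OddsRatioResult:
    """2x2 association: conditional-MLE odds ratio and exact p-value."""

    table: tuple[int, int, int, int]
    odds_ratio: float
    log2_odds_ratio: float
    p_value: float


def _rankdata(values: np.ndarray) -> np.ndarray:
    """Mid-ranks (average ranks for ties), 1-based."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    sorted_vals = values[order]
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def _two_sided_from_tails(lower: float, upper: float) -> float:
    return min(1.0, 2.0 * min(lower, upper))


def wilcoxon_signed_rank(differences) -> TestResult:
    """Two-tailed Wilcoxon signed-rank test on paired differences.

    Missing values (NaN) and zero differences are dropped before ranking.
    Exact enumeration of all ``2**n`` sign assignments is used when the
    number of nonzero differences is at most :data:`EXACT_N_MAX` and the
    absolute differences are tie-free; otherwise the tie-corrected normal
    approximation with continuity correction is applied.
    """
    d = np.asarray(list(differences), dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise ValueError("no non-missing differences supplied")
    d = d[d != 0.0]
    n = int(d.size)
    if n == 0:
        raise ValueError("all differences are zero: signed-rank test undefined")

    ranks = _rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    has_ties = len(np.unique(np.abs(d))) < n

    if n <= EXACT_N_MAX and not has_ties:
        # exact null: W+ over all sign assignments of ranks 1..n
        counts = np.zeros(n * (n + 1) // 2 + 1, dtype=np.int64)
        counts[0] = 1
        for r in range(1, n + 1):
            counts[r:] = counts[r:] + counts[:-r]
        total = float(counts.sum())
        w = int(round(w_plus))
        lower = counts[: w + 1].sum() / total
        upper = counts[w:].sum() / total
        p = _two_sided_from_tails(lower, upper)
        note = "exact"
    else:
        mu = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        # tie correction on the shared ranks of |d|
        _, tie_counts = np.unique(np.abs(d), return_counts=True)
        var -= float(np.sum(tie_counts**3 - tie_counts)) / 48.0
        if var <= 0:
            return TestResult(w_plus, 1.0, n, "degenerate")
        delta = w_plus - mu
        z = (delta - 0.5 * np.sign(delta)) / math.sqrt(var)
        p = min(1.0, 2.0 * _norm_sf(abs(z)))
        note = "normal approximation, tie and continuity corrected"
    return TestResult(w_plus, p, n, note)


def _norm_sf(z: float) -> float:
    return 0.5 * math.erfc(z / math.sqrt(2.0))


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact p by enumerating all ``C(nx+ny, nx)`` group labelings when the
    pooled size is at most :data:`EXACT_N_MAX` and there are no ties.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    nx, ny = int(x.size), int(y.size)
    pooled = np.concatenate([x, y])
    ranks = _rankdata(pooled)
    rank_sum_x = float(ranks[:nx].sum())
    u = rank_sum_x - nx * (nx + 1) / 2.0  # Mann-Whitney U for x
    has_ties = len(np.unique(pooled)) < nx + ny

    if nx + ny <= EXACT_N_MAX and not has_ties:
        stats = []
        all_ranks = ranks  # distinct, so ranks are a permutation of 1..n
        for idx in combinations(range(nx + ny), nx):
            stats.append(all_ranks[list(idx)].sum() - nx * (nx + 1) / 2.0)
        stats = np.asarray(stats)
        lower = float(np.mean(stats <= u + 1e-9))
        upper = float(np.mean(stats >= u - 1e-9))
        p = _two_sided_from_tails(lower, upper)
        note = "exact"
    else:
        n = nx + ny
        mu = nx * ny / 2.0
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
        var = nx * ny / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            return TestResult(u, 1.0, n, "degenerate")
        delta = u - mu
        z = (delta - 0.5 * np.sign(delta)) / math.sqrt(var)
        p = min(1.0, 2.0 * _norm_sf(abs(z)))
        note = "normal approximation, tie and continuity corrected"
    return TestResult(u, p, nx + ny, note)


def bh_adjust(p_values) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m, dtype=float)
    running_min = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        q = p[i] * m / (rank_idx + 1)
        running_min = min(running_min, q)
        adjusted[i] = running_min
    return [float(min(1.0, q)) for q in adjusted]


def _log_hypergeom_pmf(k: int, m1: int, m2: int, n: int) -> float:
    """log P(K = k) for K ~ Hypergeom(m1+m2, m1, n)."""
    return (
        gammaln(m1 + 1)
        - gammaln(k + 1)
        - gammaln(m1 - k + 1)
        + gammaln(m2 + 1)
        - gammaln(n - k + 1)
        - gammaln(m2 - (n - k) + 1)
        - (gammaln(m1 + m2 + 1) - gammaln(n + 1) - gammaln(m1 + m2 - n + 1))
    )


def _cmle_odds_ratio(a: int, m1: int, m2: int, n: int) -> float:
    """Conditional MLE of the odds ratio given all margins (Fisher's OR)."""
    lo = max(0, n - m2)
    hi = min(n, m1)
    if a == hi:
        return math.inf
    if a == lo:
        return 0.0
    support = np.arange(lo, hi + 1)
    log_base = np.array([_log_hypergeom_pmf(int(k), m1, m2, n) for k in support])

    def mean_minus_a(log_psi: float) -> float:
        logw = log_base + support * log_psi
        logw -= logw.max()
        w = np.exp(logw)
        return float((support * w).sum() / w.sum()) - a

    lo_l, hi_l = -1.0, 1.0
    while mean_minus_a(lo_l) > 0:
        lo_l *= 2.0
    while mean_minus_a(hi_l) < 0:
        hi_l *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo_l + hi_l)
        if mean_minus_a(mid) > 0:
            hi_l = mid
        else:
            lo_l = mid
    return math.exp(0.5 * (lo_l + hi_l))


def fisher_2x2(a: int, b: int, c: int, d: int) -> OddsRatioResult:
    """Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    Two-sided p sums hypergeometric point probabilities not exceeding the
    observed one (with a 1 + 1e-7 relative tolerance, as in R's
    ``fisher.test``); the odds ratio is the conditional maximum-likelihood
    estimate under the noncentral hypergeometric model.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("table entries must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    m1, m2, n = a + b, c + d, a + c
    if m1 == 0 or m2 == 0 or n == 0 or (b + d) == 0:
        raise ValueError("degenerate 2x2 table: a zero margin")

    support = np.arange(max(0, n - m2), min(n, m1) + 1)
    logpmf = np.array([_log_hypergeom_pmf(int(k), m1, m2, n) for k in support])
    pmf = np.exp(logpmf)
    pmf /= pmf.sum()
    observed = pmf[support == a][0]
    p = float(pmf[pmf <= observed * (1.0 + 1e-7)].sum())
    p = min(1.0, p)

    oddsr = _cmle_odds_ratio(a, m1, m2, n)
    if oddsr == 0.0:
        log2_or = -math.inf
    elif math.isinf(oddsr):
        log2_or = math.inf
    else:
        log2_or = math.log2(oddsr)
    return OddsRatioResult((a, b, c, d), oddsr, log2_or, p)


def spearman(x, y) -> float:
    """Spearman rank correlation on pairwise-complete observations.

    Returns NaN when fewer than 3 complete pairs remain or either ranking
    is constant.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        return float("nan")
    rx, ry = _rankdata(x), _rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return float("nan")
    return float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))
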