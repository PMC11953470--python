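"""Rank-test kernels shared by the differential methylation and expression modules.

Two-group comparisons use the two-sided Wilcoxon rank-sum (Mann-Whitney) test
and >2 groups the Kruskal-Wallis test.  Small samples (every group <= 6 and a
tractable number of arrangements) are evaluated by exact enumeration of group
assignments; larger samples use the tie-corrected normal (with continuity
correction) or chi-square approximation.  All approximations are vectorized
across the rows of a values matrix.
"""

from __future__ import annotations

from itertools import combinations
from math import comb, factorial, prod

import numpy as np
from scipy import stats

EXACT_MAX_GROUP = 6
EXACT_MAX_ARRANGEMENTS = 200_000
_EPS = 1e-9


def _tie_term_rows(x: np.ndarray) -> np.ndarray:
    """sum(t^3 - t) over tied groups, per row."""
    p, n = x.shape
    s = np.sort(x, axis=1)
    new = np.ones_like(s, dtype=bool)
    new[:, 1:] = s[:, 1:] != s[:, :-1]
    flat = new.ravel()
    starts = np.flatnonzero(flat)
    lengths = np.diff(np.append(starts, flat.size))
    return np.bincount(starts // n, weights=lengths**3 - lengths, minlength=p)


def mannwhitney_p_rows(x: np.ndarray, idx1: np.ndarray, idx2: np.ndarray) -> np.ndarray:
    """Two-sided Mann-Whitney p per row, normal approximation with tie and
    continuity corrections.  Rows with zero pooled variance get p = 1."""
    cols = np.concatenate([idx1, idx2])
    sub = x[:, cols]
    n1, n2 = len(idx1), len(idx2)
    n = n1 + n2
    ranks = stats.rankdata(sub, axis=1)
    r1 = ranks[:, :n1].sum(axis=1)
    u = r1 - n1 * (n1 + 1) / 2.0
    mean_u = n1 * n2 / 2.0
    tie = _tie_term_rows(sub)
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    dev = np.maximum(np.abs(u - mean_u) - 0.5, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(var_u > 0, dev / np.sqrt(np.maximum(var_u, 1e-300)), 0.0)
    p = np.minimum(2.0 * stats.norm.sf(z), 1.0)
    return np.where(var_u <= 0, 1.0, p)


def kruskal_p_rows(x: np.ndarray, group_idx: list[np.ndarray]) -> np.ndarray:
    """Kruskal-Wallis p per row, chi-square approximation with tie correction."""
    cols = np.concatenate(group_idx)
    sub = x[:, cols]
    n = sub.shape[1]
    ranks = stats.rankdata(sub, axis=1)
    h = np.zeros(sub.shape[0])
    offset = 0
    for idx in group_idx:
        nj = len(idx)
        rj = ranks[:, offset : offset + nj].sum(axis=1)
        h += rj**2 / nj
        offset += nj
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    tie = _tie_term_rows(sub)
    corr = 1.0 - tie / (n**3 - n)
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.where(corr > 0, h / np.maximum(corr, 1e-300), 0.0)
    p = stats.chi2.sf(h, df=len(group_idx) - 1)
    return np.where(corr <= 0, 1.0, p)


def _rank_sum_stat(ranks: np.ndarray, pick: tuple[int, ...]) -> float:
    return float(ranks[list(pick)].sum())


def exact_mannwhitney_p(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided rank-sum p by enumeration of all group-1 assignments.

    The statistic is the group-1 rank sum (average ranks for ties); the
    two-sided p is the proportion of assignments whose deviation from the null
    mean is at least the observed deviation.
    """
    pooled = np.concatenate([a, b])
    n1, n = len(a), len(pooled)
    ranks = stats.rankdata(pooled)
    mean_w = n1 * (n + 1) / 2.0
    obs = abs(ranks[:n1].sum() - mean_w)
    count = 0
    total = 0
    for pick in combinations(range(n), n1):
        total += 1
        if abs(_rank_sum_stat(ranks, pick) - mean_w) >= obs - _EPS:
            count += 1
    return count / total


def _kruskal_h(ranks: np.ndarray, groups: list[tuple[int, ...]], tie_corr: float) -> float:
    n = len(ranks)
    h = sum(ranks[list(g)].sum() ** 2 / len(g) for g in groups)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    return h / tie_corr if tie_corr > 0 else 0.0


def _assignments(indices: tuple[int, ...], sizes: list[int]):
    """Yield all partitions of ``indices`` into ordered groups of given sizes."""
    if len(sizes) == 1:
        yield (indices,)
        return
    first = sizes[0]
    rest = sizes[1:]
    for pick in combinations(indices, first):
        remaining = tuple(i for i in indices if i not in set(pick))
        for tail in _assignments(remaining, rest):
            yield (pick,) + tail


def exact_kruskal_p(samples: list[np.ndarray]) -> float:
    """Exact Kruskal-Wallis p by enumeration of all group assignments
    (upper tail: P(H >= H_obs))."""
    pooled = np.concatenate(samples)
    n = len(pooled)
    sizes = [len(s) for s in samples]
    ranks = stats.rankdata(pooled)
    tie = 0.0
    _, counts = np.unique(pooled, return_counts=True)
    tie = float(np.sum(counts.astype(float) ** 3 - counts))
    tie_corr = 1.0 - tie / (n**3 - n) if n > 1 else 0.0
    if tie_corr <= 0:
        return 1.0
    bounds = np.cumsum([0] + sizes)
    obs_groups = [tuple(range(bounds[i], bounds[i + 1])) for i in range(len(sizes))]
    obs = _kruskal_h(ranks, obs_groups, tie_corr)
    count = 0
    total = 0
    for groups in _assignments(tuple(range(n)), sizes):
        total += 1
        if _kruskal_h(ranks, list(groups), tie_corr) >= obs - _EPS:
            count += 1
    return count / total


def n_arrangements(sizes: list[int]) -> int:
    n = sum(sizes)
    return factorial(n) // prod(factorial(s) for s in sizes)


def use_exact(sizes: list[int]) -> bool:
    return (
        max(sizes) <= EXACT_MAX_GROUP
        and n_arrangements(sizes) <= EXACT_MAX_ARRANGEMENTS
    )


def rank_test_p_rows(x: np.ndarray, group_idx: list[np.ndarray]) -> np.ndarray:
    """Dispatch: exact enumeration for small groups, approximation otherwise.

    Rows whose pooled values are constant get p = 1 regardless of path.
    """
    sizes = [len(g) for g in group_idx]
    cols = np.concatenate(group_idx)
    pooled = x[:, cols]
    constant = np.nanstd(pooled, axis=1) == 0
    if use_exact(sizes):
        p = np.empty(x.shape[0])
        for i in range(x.shape[0]):
            if constant[i]:
                p[i] = 1.0
            elif len(group_idx) == 2:
                p[i] = exact_mannwhitney_p(x[i, group_idx[0]], x[i, group_idx[1]])
            else:
                p[i] = exact_kruskal_p([x[i, g] for g in group_idx])
        return p
    if len(group_idx) == 2:
        p = mannwhitney_p_rows(x, group_idx[0], group_idx[1])
    else:
        p = kruskal_p_rows(x, group_idx)
    return np.where(constant, 1.0, p)
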