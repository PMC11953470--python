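"""Differential methylation between sample groups.

Per CpG, beta values are compared across groups with a two-sided Wilcoxon
rank-sum test (two groups) or Kruskal-Wallis test (more than two); a probe
whose pooled values are constant gets p = 1.  P-values are adjusted across all
tested probes (Bonferroni or Benjamini-Hochberg FDR), and a probe is called
significant when the adjusted p clears the cutoff (if one is set) and the
largest pairwise difference of group mean betas exceeds the effect-size
cutoff.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._stats import rank_test_p_rows
from .purity import classify_methylation_state

MIN_COVERAGE = 0.8


def _adjust(p: np.ndarray, method: str) -> np.ndarray:
    if method == "none":
        return p.copy()
    if method == "bonferroni":
        return np.minimum(p * len(p), 1.0)
    if method == "fdr":
        return multipletests(p, method="fdr_bh")[1]
    raise ValueError(f"unknown adjustment {method!r}")


def diff_meth(
    beta: pd.DataFrame,
    groups: Mapping | pd.Series,
    test: str = "wilcoxon",
    adjust: str = "bonferroni",
    p_cut: float | None = 0.01,
    delta_cut: float = 0.25,
    min_coverage: float = MIN_COVERAGE,
) -> pd.DataFrame:
    """Differential methylation table for a probes x samples beta matrix.

    ``groups`` maps sample id to group label; every group needs >= 2 samples.
    ``test`` is ``wilcoxon`` (2 groups) or ``kruskal`` (>2).  Probes with less
    than ``min_coverage`` non-missing sample fraction are skipped (flagged in
    the ``tested`` column).  Returns a DataFrame indexed by probe with columns
    p, p_adj, mean_<group>..., delta (max pairwise |mean difference|),
    direction (group with highest mean), significant, tested.
    """
    groups = pd.Series(groups)
    groups = groups.loc[groups.index.intersection(beta.columns)]
    names = sorted(pd.unique(groups))
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    sizes = groups.value_counts()
    small = sizes[sizes < 2]
    if len(small):
        raise ValueError(f"group {small.index[0]!r} has fewer than 2 samples")
    if test == "wilcoxon" and len(names) != 2:
        raise ValueError("wilcoxon requires exactly 2 groups; use kruskal")
    if test not in {"wilcoxon", "kruskal"}:
        raise ValueError(f"unknown test {test!r}")

    sub = beta[groups.index]
    x = sub.to_numpy(dtype=float)
    coverage = 1.0 - np.isnan(x).mean(axis=1)
    tested = coverage >= min_coverage

    col_pos = {s: j for j, s in enumerate(sub.columns)}
    group_idx = [
        np.array([col_pos[s] for s in groups.index[groups == g]]) for g in names
    ]

    p = np.full(x.shape[0], np.nan)
    if tested.any():
        # rank tests ignore missing values by imputing the row mean would bias
        # ranks; instead probes passing coverage are tested on their
        # non-missing samples when complete, and on available values
        # otherwise (per-row fallback).
        xt = x[tested]
        if np.isnan(xt).any():
            p_rows = np.empty(xt.shape[0])
            for i in range(xt.shape[0]):
                row = xt[i]
                g_idx = [g[~np.isnan(row[g])] for g in group_idx]
                if any(len(g) < 2 for g in g_idx):
                    p_rows[i] = 1.0
                else:
                    p_rows[i] = rank_test_p_rows(row[None, :], g_idx)[0]
            p[tested] = p_rows
        else:
            p[tested] = rank_test_p_rows(xt, group_idx)

    records = pd.DataFrame(index=beta.index)
    records["p"] = p
    p_adj = np.full_like(p, np.nan)
    if tested.any():
        p_adj[tested] = _adjust(p[tested], adjust)
    records["p_adj"] = p_adj

    means = {}
    with np.errstate(invalid="ignore"):
        for g, idx in zip(names, group_idx):
            means[g] = np.nanmean(x[:, idx], axis=1)
            records[f"mean_{g}"] = means[g]
    mean_mat = np.stack([means[g] for g in names], axis=1)
    deltas = np.zeros(x.shape[0])
    for i, j in combinations(range(len(names)), 2):
        deltas = np.maximum(deltas, np.abs(mean_mat[:, i] - mean_mat[:, j]))
    records["delta"] = deltas
    records["direction"] = np.where(
        deltas > 0, np.array(names, dtype=object)[np.argmax(mean_mat, axis=1)], ""
    )
    records["tested"] = tested
    sig = tested & (deltas > delta_cut)
    if p_cut is not None:
        sig &= p_adj < p_cut
    records["significant"] = sig
    return records


def contrast_with_normal(
    records: pd.DataFrame,
    group_mean_beta: pd.Series,
    inferred_normal_mean: pd.Series,
) -> pd.DataFrame:
    """Annotate records with the tumor-group vs inferred-normal shift.

    ``group_mean_beta`` is the mean adjusted tumor beta of the group of
    interest per probe; ``inferred_normal_mean`` the mean inferred normal beta
    over the same samples.  Adds columns ``normal_mean``, ``normal_shift``
    (tumor minus normal), and ``normal_state`` (hypo/hyper by the <=0.5 rule).
    """
    missing = records.index.difference(inferred_normal_mean.dropna().index)
    if len(missing):
        raise ValueError(
            f"inferred normal values missing for {len(missing)} probes, e.g. {missing[0]!r}"
        )
    out = records.copy()
    normal = inferred_normal_mean.loc[out.index]
    out["normal_mean"] = normal
    out["normal_shift"] = group_mean_beta.loc[out.index] - normal
    out["normal_state"] = normal.map(classify_methylation_state)
    return out
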