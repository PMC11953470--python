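"""Gene expression analyses: differential expression, group-specific calls,
metagene rank scores, and co-expression networks.

FPKM values are offset by 0.1 and log2-transformed before rank tests; effect
sizes (median differences) are taken on the raw FPKM scale.  Group-specific
differential expression for three groups restricts to overall-significant
genes, FDR-adjusts each pairwise test family separately, and calls a gene
specific to group g when both pairwise tests involving g are significant and
the remaining pair is not.  Co-expression networks are connected components
(>= 8 genes) of the graph whose edges are Spearman correlations >= 0.7, each
scored per sample as the median FPKM of its member genes.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from dataclasses import dataclass, field
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._stats import rank_test_p_rows

FPKM_OFFSET = 0.1
SPEARMAN_CUT = 0.7
MIN_NETWORK_GENES = 8


@dataclass
class GeneNetwork:
    """Connected component of the thresholded co-expression graph."""

    genes: list[str]
    edges: list[tuple[str, str, float]] = field(default_factory=list)
    scores: pd.Series | None = None


def transform_fpkm(matrix: pd.DataFrame | np.ndarray):
    """log2(FPKM + 0.1); raises on negative input."""
    arr = np.asarray(matrix, dtype=float)
    if (arr < 0).any():
        raise ValueError("FPKM values must be non-negative")
    out = np.log2(arr + FPKM_OFFSET)
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def _group_indices(columns: pd.Index, groups: pd.Series) -> tuple[list[str], list[np.ndarray]]:
    names = sorted(pd.unique(groups))
    col_pos = {s: j for j, s in enumerate(columns)}
    idx = [np.array([col_pos[s] for s in groups.index[groups == g]]) for g in names]
    return names, idx


def diff_expr(
    matrix: pd.DataFrame,
    groups: Mapping | pd.Series,
    adjust_fdr: float = 0.05,
    min_fpkm_diff: float = 1.0,
) -> pd.DataFrame:
    """Rank-test differential expression with an FDR and median-effect filter.

    Tests run on log2(FPKM + 0.1) (Wilcoxon for 2 groups, Kruskal-Wallis for
    more); a gene is significant when FDR-adjusted p < ``adjust_fdr`` and the
    span of raw-scale group medians exceeds ``min_fpkm_diff``.  Direction is
    the group with the highest median.
    """
    groups = pd.Series(groups)
    groups = groups.loc[groups.index.intersection(matrix.columns)]
    names, group_idx = _group_indices(matrix[groups.index].columns, groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    for g, idx in zip(names, group_idx):
        if len(idx) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")

    sub = matrix[groups.index]
    raw = sub.to_numpy(dtype=float)
    logx = transform_fpkm(sub).to_numpy()
    p = rank_test_p_rows(logx, group_idx)
    p_adj = multipletests(p, method="fdr_bh")[1]

    out = pd.DataFrame(index=matrix.index)
    out["p"] = p
    out["p_adj"] = p_adj
    medians = {g: np.median(raw[:, idx], axis=1) for g, idx in zip(names, group_idx)}
    for g in names:
        out[f"median_{g}"] = medians[g]
    med_mat = np.stack([medians[g] for g in names], axis=1)
    span = med_mat.max(axis=1) - med_mat.min(axis=1)
    out["median_span"] = span
    out["direction"] = np.array(names, dtype=object)[np.argmax(med_mat, axis=1)]
    out["significant"] = (p_adj < adjust_fdr) & (span > min_fpkm_diff)
    return out


def diff_expr_group_specific(
    matrix: pd.DataFrame,
    groups: Mapping | pd.Series,
    adjust_fdr: float = 0.05,
    min_fpkm_diff: float = 1.0,
) -> pd.Series:
    """Group-specific differential expression calls for exactly three groups.

    Returns per gene one of ``{<group>-up, <group>-down, none}``.  The scheme:
    restrict to overall-significant genes (Kruskal-Wallis FDR + median span
    filter), FDR-adjust each of the three pairwise Wilcoxon families over that
    restricted set, and call a gene specific to group g iff both pairwise
    tests involving g are significant and the third is not; direction compares
    g's median with the other groups' medians.
    """
    groups = pd.Series(groups)
    groups = groups.loc[groups.index.intersection(matrix.columns)]
    names = sorted(pd.unique(groups))
    if len(names) != 3:
        raise ValueError("group-specific scheme requires exactly 3 groups")
    overall = diff_expr(matrix, groups, adjust_fdr, min_fpkm_diff)
    restricted = overall.index[overall["significant"]]
    calls = pd.Series("none", index=matrix.index, dtype=object)
    if len(restricted) == 0:
        return calls

    sub = matrix.loc[restricted, groups.index]
    logx = transform_fpkm(sub).to_numpy()
    _, group_idx = _group_indices(sub.columns, groups)
    pair_sig = {}
    for i, j in combinations(range(3), 2):
        p = rank_test_p_rows(logx, [group_idx[i], group_idx[j]])
        pair_sig[(i, j)] = multipletests(p, method="fdr_bh")[1] < adjust_fdr

    medians = np.stack(
        [np.median(sub.to_numpy(dtype=float)[:, idx], axis=1) for idx in group_idx], axis=1
    )
    for g in range(3):
        others = [o for o in range(3) if o != g]
        involving = [pair_sig[tuple(sorted((g, o)))] for o in others]
        rest = pair_sig[tuple(sorted(others))]
        specific = involving[0] & involving[1] & ~rest
        up = medians[:, g] > medians[:, others].max(axis=1)
        label_up = f"{names[g]}-up"
        label_dn = f"{names[g]}-down"
        sel = restricted[specific]
        calls.loc[sel] = np.where(up[specific], label_up, label_dn)
    return calls


def metagene_rank_score(matrix: pd.DataFrame, gene_set: Iterable[str]) -> pd.Series:
    """Per-sample metagene score: mean within-sample expression rank of the
    member genes, divided by the total gene count (ascending ranks, ties
    averaged).  Invariant under monotone transforms of a sample's profile."""
    members = [g for g in gene_set if g in matrix.index]
    if not members:
        raise ValueError("gene set has no overlap with the expression matrix")
    ranks = matrix.rank(axis=0, method="average")
    return ranks.loc[members].mean(axis=0) / matrix.shape[0]


def spearman_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """All pairwise Spearman correlations between gene rows."""
    ranks = stats.rankdata(matrix.to_numpy(dtype=float), axis=1)
    r = np.corrcoef(ranks)
    return pd.DataFrame(r, index=matrix.index, columns=matrix.index)


def build_gene_networks(
    matrix: pd.DataFrame,
    r_cut: float = SPEARMAN_CUT,
    min_genes: int = MIN_NETWORK_GENES,
) -> list[GeneNetwork]:
    """Co-expression networks: connected components (>= ``min_genes``) of the
    graph with edges where pairwise Spearman r >= ``r_cut`` (positive
    correlations only).  Constant genes are dropped with a warning.  Each
    network carries per-sample scores = median raw FPKM over members."""
    import warnings

    if matrix.shape[1] < 10:
        raise ValueError("need at least 10 samples")
    constant = matrix.std(axis=1, ddof=0) == 0
    if constant.any():
        warnings.warn(f"dropping {int(constant.sum())} constant genes", stacklevel=2)
        matrix = matrix.loc[~constant]
    if matrix.shape[0] < min_genes:
        return []
    corr = spearman_matrix(matrix).to_numpy()
    genes = matrix.index.to_numpy()
    iu = np.triu_indices(len(genes), k=1)
    hits = corr[iu] >= r_cut
    g = nx.Graph()
    g.add_nodes_from(genes)
    edge_idx = np.flatnonzero(hits)
    for e in edge_idx:
        i, j = iu[0][e], iu[1][e]
        g.add_edge(genes[i], genes[j], r=float(corr[i, j]))
    networks = []
    for comp in nx.connected_components(g):
        if len(comp) < min_genes:
            continue
        members = sorted(comp)
        edges = [
            (a, b, g.edges[a, b]["r"]) for a, b in g.subgraph(comp).edges
        ]
        net = GeneNetwork(genes=members, edges=edges)
        net.scores = network_score(matrix, net)
        networks.append(net)
    networks.sort(key=lambda n: (-len(n.genes), n.genes[0]))
    return networks


def network_score(matrix: pd.DataFrame, network: GeneNetwork | Iterable[str]) -> pd.Series:
    """Per-sample network metagene score: median raw FPKM over member genes."""
    genes = network.genes if isinstance(network, GeneNetwork) else list(network)
    return matrix.loc[genes].median(axis=0)


def write_sif(networks: list[GeneNetwork], path) -> None:
    """Write network edges as a SIF file (gene <tab> corr <tab> gene)."""
    with open(path, "w") as fh:
        for net in networks:
            for a, b, _ in net.edges:
                fh.write(f"{a}\tcorr\t{b}\n")
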