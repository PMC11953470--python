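"""Unsupervised methylation subtyping (epityping) by NMF.

The workflow selects the most variant CpGs within a genomic context (for
example distal CpGs overlapping ATAC peaks), factorizes the probes x samples
beta matrix with non-negative matrix factorization (multiplicative updates,
Kullback-Leibler objective) over many seeded restarts, keeps the best run by
objective, and assigns each sample to the factor with the largest mixture
coefficient.  Concordance of a two-group split with an external binary label
(e.g. PAM50 Basal vs nonBasal) is the maximum agreement over the two possible
cluster-to-label mappings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning

DEFAULT_SEED = 221027
DEFAULT_NRUN = 100


@dataclass
class FeatureSet:
    """Top-variance probe selection within a context filter."""

    probes: list[str]
    n_top: int
    context: str = ""
    sds: pd.Series | None = None
    exhausted: bool = False


@dataclass
class EpitypeResult:
    """Best-of-nrun NMF factorization and derived sample clusters."""

    k: int
    sample_assignment: pd.Series
    basis: pd.DataFrame
    mixture: pd.DataFrame
    reconstruction_error: float
    nrun: int
    seed: int
    run_errors: list[float] = field(default_factory=list)


def select_top_variant(
    beta: pd.DataFrame,
    annotations: pd.DataFrame | None = None,
    context_filter: Callable[[pd.DataFrame], pd.Series] | pd.Series | None = None,
    n_top: int = 5000,
) -> FeatureSet:
    """Rank probes passing a context filter by beta SD, keep the top ``n_top``.

    ``context_filter`` is either a boolean Series over probes or a callable
    taking the annotation frame and returning one; ``None`` selects
    genome-wide.  Probes with any missing beta are excluded.  Ties in SD break
    by lexical probe id; the result is invariant to sample order.
    """
    if beta.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    eligible = beta.dropna(axis=0)
    if context_filter is not None:
        if callable(context_filter):
            mask = context_filter(annotations)
        else:
            mask = context_filter
        keep = mask[mask].index
        eligible = eligible.loc[eligible.index.intersection(keep)]
    sds = eligible.std(axis=1, ddof=1)
    order = sorted(sds.index, key=lambda p: (-sds[p], p))
    exhausted = len(order) < n_top
    if exhausted:
        warnings.warn(
            f"only {len(order)} eligible probes for n_top={n_top}; returning all",
            stacklevel=2,
        )
    chosen = order[:n_top]
    return FeatureSet(probes=chosen, n_top=n_top, sds=sds.loc[chosen], exhausted=exhausted)


def context_predicate(
    genic: str | None = None, cgi: str | None = None, atac: bool | None = None
) -> Callable[[pd.DataFrame], pd.Series]:
    """Build a boolean annotation filter, e.g. distal CpGs in ATAC peaks."""

    def predicate(ann: pd.DataFrame) -> pd.Series:
        mask = pd.Series(True, index=ann.index)
        if genic is not None:
            mask &= ann["genic_context"] == genic
        if cgi is not None:
            mask &= ann["cgi_context"] == cgi
        if atac is not None:
            mask &= ann["atac_overlap"] == atac
        return mask

    return predicate


def nmf_cluster(
    matrix: pd.DataFrame,
    k: int,
    nrun: int = DEFAULT_NRUN,
    seed: int = DEFAULT_SEED,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> EpitypeResult:
    """Best-of-``nrun`` NMF (multiplicative updates, KL divergence) clustering.

    Restart ``i`` is initialized from random state ``seed + i``; the run with
    the smallest objective is kept and samples are assigned to the factor with
    the largest mixture coefficient.  Deterministic given (matrix, k, nrun,
    seed).
    """
    x = matrix.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("matrix contains missing values")
    if (x < 0).any():
        raise ValueError("matrix must be non-negative")
    if k < 2:
        raise ValueError("k must be >= 2")
    if k >= min(x.shape):
        raise ValueError(f"k={k} must be smaller than both matrix dimensions {x.shape}")
    zero_cols = np.flatnonzero(x.sum(axis=0) == 0)
    if zero_cols.size:
        raise ValueError(f"all-zero column for sample {matrix.columns[zero_cols[0]]!r}")

    best = None
    errors: list[float] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for run in range(nrun):
            model = NMF(
                n_components=k,
                init="random",
                solver="mu",
                beta_loss="kullback-leibler",
                tol=tol,
                max_iter=max_iter,
                random_state=seed + run,
            )
            w = model.fit_transform(x)
            errors.append(float(model.reconstruction_err_))
            if best is None or model.reconstruction_err_ < best[0]:
                best = (float(model.reconstruction_err_), w, model.components_)

    err, w, h = best
    assignment = pd.Series(np.argmax(h, axis=0) + 1, index=matrix.columns, name="cluster")
    return EpitypeResult(
        k=k,
        sample_assignment=assignment,
        basis=pd.DataFrame(w, index=matrix.index, columns=range(1, k + 1)),
        mixture=pd.DataFrame(h, index=range(1, k + 1), columns=matrix.columns),
        reconstruction_error=err,
        nrun=nrun,
        seed=seed,
        run_errors=errors,
    )


def cluster_label_concordance(
    assignment: Mapping | pd.Series, labels: Mapping | pd.Series
) -> float:
    """Best accuracy of a two-cluster assignment against binary labels,
    maximized over the two cluster-to-label mappings."""
    assignment = pd.Series(assignment)
    labels = pd.Series(labels)
    common = assignment.index.intersection(labels.index)
    if len(common) == 0:
        raise ValueError("no shared samples")
    a = assignment.loc[common]
    l = labels.loc[common]
    a_vals = sorted(pd.unique(a))
    l_vals = sorted(pd.unique(l))
    if len(a_vals) > 2 or len(l_vals) > 2:
        raise ValueError("concordance requires binary assignments and labels")
    a_bin = (a == a_vals[-1]).to_numpy()
    l_bin = (l == l_vals[-1]).to_numpy()
    agree = float(np.mean(a_bin == l_bin))
    return max(agree, 1.0 - agree)


def hier_cluster_cpgs(matrix: pd.DataFrame, n_clusters: int) -> pd.Series:
    """Row-cluster probes by Euclidean distance with Ward linkage, cut into
    ``n_clusters`` groups."""
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    if matrix.shape[0] < n_clusters:
        raise ValueError("fewer probes than requested clusters")
    z = linkage(matrix.to_numpy(dtype=float), method="ward", metric="euclidean")
    ids = fcluster(z, t=n_clusters, criterion="maxclust")
    return pd.Series(ids, index=matrix.index, name="row_cluster")
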