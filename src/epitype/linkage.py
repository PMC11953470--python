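"""Methylation-expression linkage (eQTM-style CpG-gene pairs).

Each CpG is mapped to every gene whose consensus TSS lies within a 500 kb
window centered on the probe.  Pairs pass eligibility filters (beta range
> 0.25; FPKM range > 1 and cohort mean FPKM >= 0.5; expression then
log2(x + 0.1)-transformed) before a jackknife Pearson correlation is computed:
the signed value of smallest absolute magnitude among the full-data
correlation and all leave-one-out correlations, damping outlier-driven
associations.  Significance cutoffs are the 2.5th/97.5th percentiles of the
same statistic computed over randomly sampled probes and their own windows
(an empirical null), and candidate epigenetically regulated genes are
filtered by promoter-proximal negative pairs, differential expression, and
group-median effect sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .expression import transform_fpkm

WINDOW_BP = 500_000
BETA_RANGE_MIN = 0.25
FPKM_RANGE_MIN = 1.0
FPKM_MEAN_MIN = 0.5
NULL_PROBES = 50_000
DEFAULT_SEED = 221027


@dataclass
class NullCutoffs:
    """Empirical null correlation band."""

    low: float
    high: float
    n_probes: int
    seed: int
    n_pairs: int = 0

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError("low cutoff exceeds high cutoff")


def map_cpg_to_genes(
    probe_pos: int,
    probe_chrom: str,
    models: Mapping[str, GeneModel] | Sequence[GeneModel],
    window_bp: int = WINDOW_BP,
) -> list[tuple[str, int]]:
    """Genes whose consensus TSS lies within +/- window/2 of the probe
    (inclusive boundary), with signed probe-to-TSS distances."""
    if isinstance(models, Mapping):
        models = list(models.values())
    half = window_bp // 2
    out = []
    for m in models:
        if m.chrom != probe_chrom:
            continue
        d = probe_pos - m.tss
        if m.strand == "-":
            d = -d
        if abs(probe_pos - m.tss) <= half:
            out.append((m.gene_id, d))
    return sorted(out)


def filter_pair_inputs(
    beta_row: np.ndarray | pd.Series, fpkm_row: np.ndarray | pd.Series
) -> tuple[bool, bool]:
    """Pair eligibility: probe needs beta range > 0.25; gene needs FPKM range
    > 1 and cohort mean FPKM >= 0.5."""
    b = np.asarray(beta_row, dtype=float)
    f = np.asarray(fpkm_row, dtype=float)
    probe_ok = bool(np.nanmax(b) - np.nanmin(b) > BETA_RANGE_MIN)
    gene_ok = bool(
        (np.nanmax(f) - np.nanmin(f) > FPKM_RANGE_MIN) and np.nanmean(f) >= FPKM_MEAN_MIN
    )
    return probe_ok, gene_ok


def jackknife_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Conservative jackknife Pearson correlation.

    Computes Pearson r on the full data and on every leave-one-out subsample
    and returns the signed value of minimum absolute magnitude (first
    occurrence on ties, full-data r first).  Raises when any subsample is
    constant (the pair should be dropped).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 observations")
    candidates = _jackknife_candidates(x, y)
    if np.isnan(candidates).any():
        raise ValueError("constant vector in full data or a leave-one-out subsample")
    return float(candidates[np.argmin(np.abs(candidates))])


def _jackknife_candidates(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """r_full followed by all n leave-one-out correlations (NaN if constant)."""
    n = len(x)
    out = np.empty(n + 1)
    out[0] = _pearson(x, y)
    for i in range(n):
        keep = np.arange(n) != i
        out[i + 1] = _pearson(x[keep], y[keep])
    return out


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def jackknife_pearson_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise jackknife Pearson for paired matrices (pairs x samples).

    Vectorized via leave-one-out downdates of the sufficient statistics;
    returns NaN for rows where the full data or any subsample is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    p, n = x.shape
    sx = x.sum(axis=1, keepdims=True)
    sy = y.sum(axis=1, keepdims=True)
    sxx = (x**2).sum(axis=1, keepdims=True)
    syy = (y**2).sum(axis=1, keepdims=True)
    sxy = (x * y).sum(axis=1, keepdims=True)

    def r_from(sx_, sy_, sxx_, syy_, sxy_, m):
        cov = sxy_ - sx_ * sy_ / m
        vx = sxx_ - sx_**2 / m
        vy = syy_ - sy_**2 / m
        vx = np.where(vx < 0, 0.0, vx)
        vy = np.where(vy < 0, 0.0, vy)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = cov / np.sqrt(vx * vy)
        tol_x = 1e-12 * np.maximum(sxx_, 1.0)
        tol_y = 1e-12 * np.maximum(syy_, 1.0)
        return np.where((vx <= tol_x) | (vy <= tol_y), np.nan, r)

    r_full = r_from(sx, sy, sxx, syy, sxy, n)  # (p, 1)
    r_loo = r_from(sx - x, sy - y, sxx - x**2, syy - y**2, sxy - x * y, n - 1)  # (p, n)
    cand = np.concatenate([r_full, r_loo], axis=1)
    bad = np.isnan(cand).any(axis=1)
    idx = np.argmin(np.abs(cand), axis=1)
    out = cand[np.arange(p), idx]
    out[bad] = np.nan
    return out


def build_pairs(
    beta: pd.DataFrame,
    fpkm: pd.DataFrame,
    models: Mapping[str, GeneModel],
    probe_manifest: pd.DataFrame,
    probes: Sequence[str] | None = None,
    window_bp: int = WINDOW_BP,
) -> pd.DataFrame:
    """Enumerate eligible CpG-gene pairs and their jackknife correlations.

    Samples are the intersection of beta and FPKM columns.  Returns a frame
    with columns probe_id, gene_id, tss_distance, jackknife_r (NaN rows —
    constant subsamples — are dropped with a ``dropped_constant`` attribute).
    """
    samples = beta.columns.intersection(fpkm.columns)
    if len(samples) < 4:
        raise ValueError("need at least 4 shared samples")
    beta = beta[samples]
    log_fpkm = transform_fpkm(fpkm[samples])

    manifest = probe_manifest.set_index("probe_id") if "probe_id" in probe_manifest else probe_manifest
    if probes is None:
        probes = [p for p in beta.index if p in manifest.index]

    b_arr = beta.to_numpy(dtype=float)
    b_pos = {p: i for i, p in enumerate(beta.index)}
    f_raw = fpkm[samples]

    probe_ok: dict[str, bool] = {}
    gene_ok: dict[str, bool] = {}

    rows = []
    for probe in probes:
        if probe not in manifest.index or probe not in b_pos:
            continue
        if probe not in probe_ok:
            row = b_arr[b_pos[probe]]
            probe_ok[probe] = (
                not np.isnan(row).any()
                and np.max(row) - np.min(row) > BETA_RANGE_MIN
            )
        if not probe_ok[probe]:
            continue
        pos = int(manifest.loc[probe, "pos"])
        chrom = manifest.loc[probe, "chrom"]
        for gene, dist in map_cpg_to_genes(pos, chrom, models, window_bp):
            if gene not in log_fpkm.index:
                continue
            if gene not in gene_ok:
                fr = f_raw.loc[gene].to_numpy(dtype=float)
                gene_ok[gene] = bool(
                    np.max(fr) - np.min(fr) > FPKM_RANGE_MIN and np.mean(fr) >= FPKM_MEAN_MIN
                )
            if gene_ok[gene]:
                rows.append((probe, gene, dist))

    if not rows:
        return pd.DataFrame(columns=["probe_id", "gene_id", "tss_distance", "jackknife_r"])

    pairs = pd.DataFrame(rows, columns=["probe_id", "gene_id", "tss_distance"])
    xs = b_arr[[b_pos[p] for p in pairs["probe_id"]]]
    ys = log_fpkm.loc[pairs["gene_id"]].to_numpy(dtype=float)
    pairs["jackknife_r"] = jackknife_pearson_rows(xs, ys)
    n_dropped = int(pairs["jackknife_r"].isna().sum())
    pairs = pairs.dropna(subset=["jackknife_r"]).reset_index(drop=True)
    pairs.attrs["dropped_constant"] = n_dropped
    return pairs


def empirical_null(
    beta: pd.DataFrame,
    fpkm: pd.DataFrame,
    models: Mapping[str, GeneModel],
    probe_manifest: pd.DataFrame,
    n_probes: int = NULL_PROBES,
    seed: int = DEFAULT_SEED,
    window_bp: int = WINDOW_BP,
) -> NullCutoffs:
    """Null correlation band from randomly sampled probes.

    Samples ``n_probes`` probes uniformly (with replacement, with a warning,
    when the universe is smaller), computes jackknife correlations for every
    eligible window pair, and returns the 2.5th/97.5th percentiles (linear
    interpolation).  Deterministic given the seed.
    """
    import warnings

    rng = np.random.default_rng(seed)
    universe = np.asarray(beta.index)
    if len(universe) >= n_probes:
        chosen = rng.choice(universe, size=n_probes, replace=False)
    else:
        warnings.warn(
            f"probe universe ({len(universe)}) smaller than n_probes={n_probes}; "
            "sampling with replacement",
            stacklevel=2,
        )
        chosen = rng.choice(universe, size=n_probes, replace=True)
    pairs = build_pairs(beta, fpkm, models, probe_manifest, probes=list(chosen), window_bp=window_bp)
    if pairs.empty:
        raise ValueError("no eligible null pairs")
    low, high = np.percentile(pairs["jackknife_r"], [2.5, 97.5])
    return NullCutoffs(float(low), float(high), n_probes=n_probes, seed=seed, n_pairs=len(pairs))


def call_significant_pairs(pairs: pd.DataFrame, cutoffs: NullCutoffs) -> pd.DataFrame:
    """Flag pairs outside the null band (strict inequalities)."""
    out = pairs.copy()
    out["significant"] = (out["jackknife_r"] < cutoffs.low) | (
        out["jackknife_r"] > cutoffs.high
    )
    return out


def candidate_epigene_filter(
    pairs: pd.DataFrame,
    de_genes: set[str],
    group_median_fpkm: pd.DataFrame,
    tss_kbp: float = 7.0,
    min_cpgs: int = 3,
    min_median_diff: float = 5.0,
    min_fold_change: float | None = None,
) -> list[str]:
    """Candidate epigenetically regulated genes.

    A gene is retained when it has >= ``min_cpgs`` significant negative pairs
    with |TSS distance| < ``tss_kbp`` kb, is differentially expressed, and its
    two group median FPKMs differ by more than ``min_median_diff`` (optionally
    also by more than ``min_fold_change``-fold).  ``group_median_fpkm`` has
    genes as index and exactly two group columns.
    """
    if group_median_fpkm.shape[1] != 2:
        raise ValueError("group_median_fpkm needs exactly two group columns")
    qual = pairs[
        pairs["significant"]
        & (pairs["jackknife_r"] < 0)
        & (pairs["tss_distance"].abs() < tss_kbp * 1000)
    ]
    counts = qual.groupby("gene_id")["probe_id"].nunique()
    out = []
    for gene, n_cpgs in counts.items():
        if n_cpgs < min_cpgs or gene not in de_genes:
            continue
        if gene not in group_median_fpkm.index:
            raise ValueError(f"group medians missing for gene {gene!r}")
        m1, m2 = group_median_fpkm.loc[gene].to_numpy(dtype=float)
        if abs(m1 - m2) <= min_median_diff:
            continue
        if min_fold_change is not None:
            lo, hi = sorted([m1, m2])
            fold = np.inf if lo == 0 else hi / lo
            if fold <= min_fold_change:
                continue
        out.append(gene)
    return sorted(out)
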