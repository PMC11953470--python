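"""Tumor-purity adjustment of methylation beta values.

A bulk tumor sample is a mixture of tumor and normal cells, so the observed
beta value at a CpG is approximately ``purity * beta_tumor +
(1 - purity) * beta_normal``.  For each CpG, samples are partitioned into up
to three methylation populations (1-D k-means on beta, population count chosen
by silhouette), and each population is fitted with a least-squares line
``beta ~ purity``.  Adjustment extrapolates a sample's population line to
purity 1 while preserving the sample's residual, so inter-tumor heterogeneity
survives the correction:

    adjusted = (intercept + slope) + (beta_obs - (intercept + slope * purity))
             = beta_obs + slope * (1 - purity)

The line's intercept (its value at purity 0) is the inferred in-silico normal
estimate for the CpG.  Slopes are confined to [-1, 1] because beta is a
fraction of a two-component mixture; adjusted values are clamped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_SEED = 221027
MIN_FIT_SAMPLES = 10
MIN_POPULATION = 3
SILHOUETTE_THRESHOLD = 0.6
MAX_POPULATIONS = 3
MERGE_GAP = 0.2


@dataclass
class CpGPurityModel:
    """Per-CpG population lines and sample memberships."""

    probe_id: str
    populations: list[dict] = field(default_factory=list)
    population_assignment: dict[str, int] = field(default_factory=dict)
    fitted: bool = False


@dataclass
class PurityModelSet:
    """Vectorized model bank for a probes x samples beta matrix.

    ``slopes``/``intercepts`` are (n_probes, max_pops) with NaN padding;
    ``assignment`` is (n_probes, n_samples) population indices (-1 where the
    sample's beta was missing); ``fitted`` flags probes with enough data.
    """

    probe_ids: pd.Index
    sample_ids: pd.Index
    slopes: np.ndarray
    intercepts: np.ndarray
    assignment: np.ndarray
    n_populations: np.ndarray
    fitted: np.ndarray

    def model_for(self, probe_id: str) -> CpGPurityModel:
        i = self.probe_ids.get_loc(probe_id)
        model = CpGPurityModel(probe_id, fitted=bool(self.fitted[i]))
        for k in range(int(self.n_populations[i])):
            members = [
                s for j, s in enumerate(self.sample_ids) if self.assignment[i, j] == k
            ]
            model.populations.append(
                {
                    "members": members,
                    "slope": float(self.slopes[i, k]),
                    "intercept": float(self.intercepts[i, k]),
                }
            )
        model.population_assignment = {
            s: int(self.assignment[i, j])
            for j, s in enumerate(self.sample_ids)
            if self.assignment[i, j] >= 0
        }
        return model


def _kmeans_1d(values: np.ndarray, valid: np.ndarray, k: int, n_iter: int = 30):
    """Batch 1-D k-means over rows of ``values`` (probes x samples).

    Quantile initialization (deterministic); empty clusters retain their
    previous center.  Returns (labels, centers) with labels -1 where invalid.
    """
    p, s = values.shape
    qs = (2 * np.arange(k) + 1) / (2 * k)
    vals = np.where(valid, values, np.nan)
    centers = np.nanquantile(vals, qs, axis=1).T  # (p, k)
    labels = np.full((p, s), -1, dtype=np.int64)
    for _ in range(n_iter):
        dist = np.abs(vals[:, :, None] - centers[:, None, :])  # (p, s, k)
        new_labels = np.argmin(np.where(np.isnan(dist), np.inf, dist), axis=2)
        new_labels = np.where(valid, new_labels, -1)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for c in range(k):
            mask = labels == c
            cnt = mask.sum(axis=1)
            tot = np.where(mask, vals, 0.0)
            tot = np.nansum(tot, axis=1)
            upd = cnt > 0
            centers[upd, c] = tot[upd] / cnt[upd]
    return labels, centers


def _silhouette_1d(values: np.ndarray, valid: np.ndarray, labels: np.ndarray, k: int,
                   chunk: int = 512) -> np.ndarray:
    """Mean silhouette per row for a 1-D clustering; NaN where undefined."""
    p, s = values.shape
    out = np.full(p, np.nan)
    for lo in range(0, p, chunk):
        hi = min(lo + chunk, p)
        v = values[lo:hi]
        ok = valid[lo:hi]
        lab = labels[lo:hi]
        d = np.abs(v[:, :, None] - v[:, None, :])  # (c, s, s)
        sil_sum = np.zeros(hi - lo)
        sil_cnt = np.zeros(hi - lo)
        # per-cluster mean distance from every point
        mean_to = np.full((hi - lo, s, k), np.inf)
        size = np.zeros((hi - lo, k), dtype=np.int64)
        for c in range(k):
            mask = (lab == c) & ok  # (c, s)
            size[:, c] = mask.sum(axis=1)
            tot = np.einsum("psq,pq->ps", np.nan_to_num(d), mask.astype(float))
            with np.errstate(invalid="ignore", divide="ignore"):
                mean_to[:, :, c] = tot / size[:, None, c]
        for c in range(k):
            mask = (lab == c) & ok
            own = size[:, c][:, None]
            with np.errstate(invalid="ignore", divide="ignore"):
                a = (mean_to[:, :, c] * own - 0.0) / np.maximum(own - 1, 1)
            others = [mean_to[:, :, c2] for c2 in range(k) if c2 != c]
            b = np.min(np.stack(others, axis=2), axis=2)
            with np.errstate(invalid="ignore", divide="ignore"):
                sil = (b - a) / np.maximum(a, b)
            sil = np.where(own > 1, sil, 0.0)  # singleton convention
            sil = np.where(mask, sil, 0.0)
            sil_sum += np.nansum(sil, axis=1)
            sil_cnt += mask.sum(axis=1)
        out[lo:hi] = np.where(sil_cnt > 0, sil_sum / np.maximum(sil_cnt, 1), np.nan)
    return out


def _fit_lines(values, valid, labels, purity, k):
    """Least-squares beta ~ purity per population, slope clipped to [-1, 1]."""
    p = values.shape[0]
    slopes = np.full((p, k), np.nan)
    intercepts = np.full((p, k), np.nan)
    pur = purity[None, :]
    for c in range(k):
        mask = (labels == c) & valid
        n = mask.sum(axis=1)
        w = mask.astype(float)
        sx = (w * pur).sum(axis=1)
        sy = np.nansum(w * values, axis=1)
        sxx = (w * pur**2).sum(axis=1)
        sxy = np.nansum(w * values * pur, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            denom = n * sxx - sx**2
            slope = np.where(denom > 1e-12, (n * sxy - sx * sy) / np.where(denom > 0, denom, 1), 0.0)
        slope = np.clip(slope, -1.0, 1.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            intercept = (sy - slope * sx) / np.maximum(n, 1)
        has = n > 0
        slopes[has, c] = slope[has]
        intercepts[has, c] = intercept[has]
    return slopes, intercepts


def _merge_coincident(labels, n_pops, slopes, intercepts, merge_gap):
    """Merge populations whose lines differ by < merge_gap at both purity 0
    and purity 1; relabel compactly (kmax <= 3)."""
    p, kmax = slopes.shape

    def close(i, j):
        if kmax <= max(i, j):
            return np.zeros(p, dtype=bool)
        d0 = np.abs(intercepts[:, i] - intercepts[:, j])
        d1 = np.abs(
            (intercepts[:, i] + slopes[:, i]) - (intercepts[:, j] + slopes[:, j])
        )
        both = (n_pops > max(i, j)) & ~np.isnan(d0) & ~np.isnan(d1)
        return both & (d0 < merge_gap) & (d1 < merge_gap)

    # remap[c] = merge target of population c, then compacted to 0..k'-1
    remap = np.tile(np.arange(kmax), (p, 1))
    c01 = close(0, 1)
    remap[c01, 1] = 0
    if kmax >= 3:
        c02 = close(0, 2)
        remap[c02, 2] = 0
        c12 = close(1, 2) & ~c02
        remap[c12, 2] = remap[c12, 1]
        # compact: target 2 with a vacated slot 1 slides down
        slide = (remap[:, 1] == 0) & (remap[:, 2] == 2)
        remap[slide, 2] = 1

    safe = np.clip(labels, 0, kmax - 1)
    new_labels = np.take_along_axis(remap, safe, axis=1)
    new_labels[labels < 0] = -1
    new_k = new_labels.max(axis=1) + 1
    new_k = np.maximum(new_k, 1)
    return new_labels, new_k.astype(np.int64)


def fit_purity_models(
    beta: pd.DataFrame,
    purity: pd.Series,
    max_populations: int = MAX_POPULATIONS,
    silhouette_threshold: float = SILHOUETTE_THRESHOLD,
    min_population: int = MIN_POPULATION,
    min_fit_samples: int = MIN_FIT_SAMPLES,
    merge_gap: float = MERGE_GAP,
    seed: int = DEFAULT_SEED,
) -> PurityModelSet:
    """Fit per-CpG purity models for a probes x samples beta matrix.

    Samples are the intersection of beta columns and the purity index.  For
    each probe, candidate partitions with 1..max_populations populations are
    scored by 1-D silhouette; a multi-population split is kept only when every
    population has >= ``min_population`` members and the silhouette clears the
    threshold.  Probes with fewer than ``min_fit_samples`` usable samples are
    flagged unfit; adjustment leaves them unchanged.

    The ``seed`` parameter is accepted for interface stability; the quantile
    initialization used here is deterministic without it.
    """
    samples = beta.columns.intersection(purity.index)
    b = beta[samples].to_numpy(dtype=float)
    pur = purity[samples].to_numpy(dtype=float)
    valid = ~np.isnan(b) & ~np.isnan(pur)[None, :]
    usable = valid.sum(axis=1)
    fitted = usable >= min_fit_samples

    n_probes, n_samples = b.shape
    best_labels = np.where(valid, 0, -1).astype(np.int64)
    best_k = np.ones(n_probes, dtype=np.int64)
    best_sil = np.full(n_probes, -np.inf)

    for k in range(2, max_populations + 1):
        if n_samples < k * min_population:
            break
        labels, _ = _kmeans_1d(b, valid, k)
        labels = np.where(valid, labels, -1)
        sizes = np.stack([(labels == c).sum(axis=1) for c in range(k)], axis=1)
        eligible = fitted & (sizes.min(axis=1) >= min_population)
        if not eligible.any():
            continue
        sil = _silhouette_1d(b, valid, labels, k)
        take = eligible & (sil >= silhouette_threshold) & (sil > best_sil)
        best_labels[take] = labels[take]
        best_k[take] = k
        best_sil[take] = sil[take]

    kmax = int(best_k.max())
    slopes, intercepts = _fit_lines(b, valid, best_labels, pur, kmax)

    # merge populations whose fitted lines coincide: a split of one methylation
    # population along the purity axis produces near-identical lines, which
    # must collapse back to a single population
    if kmax > 1:
        best_labels, best_k = _merge_coincident(
            best_labels, best_k, slopes, intercepts, merge_gap
        )
        kmax = int(best_k.max())
        slopes, intercepts = _fit_lines(b, valid, best_labels, pur, kmax)

    # single-population probes keep only population 0
    for i in range(kmax):
        drop = best_k <= i
        if i > 0:
            slopes[drop, i] = np.nan
            intercepts[drop, i] = np.nan
    return PurityModelSet(
        probe_ids=beta.index,
        sample_ids=pd.Index(samples),
        slopes=slopes,
        intercepts=intercepts,
        assignment=best_labels,
        n_populations=best_k,
        fitted=fitted,
    )


def fit_cpg_model(betas: pd.Series, purities: pd.Series, **kwargs) -> CpGPurityModel:
    """Fit the purity model for a single probe (see :func:`fit_purity_models`)."""
    name = betas.name if betas.name is not None else "probe"
    frame = betas.to_frame().T
    frame.index = pd.Index([name])
    models = fit_purity_models(frame, purities, **kwargs)
    return models.model_for(name)


def _population_of(model: CpGPurityModel, sample, beta_obs: float, purity: float) -> int:
    if sample in model.population_assignment:
        return model.population_assignment[sample]
    # nearest line by residual
    residuals = [
        abs(beta_obs - (p["intercept"] + p["slope"] * purity)) for p in model.populations
    ]
    return int(np.argmin(residuals))


def adjust_beta(model: CpGPurityModel, beta_obs: float, purity: float, sample=None) -> float:
    """Extrapolate a sample's population line to purity 1, keeping the residual."""
    if not model.fitted or not model.populations:
        return beta_obs
    pop = model.populations[_population_of(model, sample, beta_obs, purity)]
    adjusted = beta_obs + pop["slope"] * (1.0 - purity)
    return float(np.clip(adjusted, 0.0, 1.0))


def infer_normal(model: CpGPurityModel, sample=None, beta_obs=None, purity=None) -> float:
    """Population line at purity 0 (the inferred normal beta), clamped to [0, 1]."""
    if not model.fitted or not model.populations:
        return float("nan")
    if sample is not None and sample in model.population_assignment:
        idx = model.population_assignment[sample]
    elif beta_obs is not None and purity is not None:
        idx = _population_of(model, sample, beta_obs, purity)
    else:
        idx = 0
    return float(np.clip(model.populations[idx]["intercept"], 0.0, 1.0))


def adjust_cohort(
    models: PurityModelSet, beta: pd.DataFrame, purity: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Adjust a whole beta matrix; returns (adjusted, inferred_normal) frames.

    Both outputs are probes x samples; inferred normal repeats each sample's
    population intercept (NaN for unfit probes or missing betas).
    """
    samples = models.sample_ids
    b = beta.loc[models.probe_ids, samples].to_numpy(dtype=float)
    pur = purity[samples].to_numpy(dtype=float)
    lab = models.assignment
    safe = np.clip(lab, 0, models.slopes.shape[1] - 1)
    slope = np.take_along_axis(models.slopes, safe, axis=1)
    intercept = np.take_along_axis(models.intercepts, safe, axis=1)
    usable = (lab >= 0) & models.fitted[:, None] & ~np.isnan(slope)
    adjusted = np.where(usable, np.clip(b + slope * (1.0 - pur[None, :]), 0, 1), b)
    normal = np.where(usable, np.clip(intercept, 0, 1), np.nan)
    return (
        pd.DataFrame(adjusted, index=models.probe_ids, columns=samples),
        pd.DataFrame(normal, index=models.probe_ids, columns=samples),
    )


def classify_methylation_state(mean_beta: float) -> str:
    """Background methylation class: hypo iff mean beta <= 0.5, else hyper."""
    if mean_beta is None or np.isnan(mean_beta):
        raise ValueError("mean beta is undefined (all values missing)")
    return "hypo" if mean_beta <= 0.5 else "hyper"
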