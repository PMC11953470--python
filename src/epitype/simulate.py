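"""Synthetic bulk methylation + expression cohorts with known ground truth.

The generator emulates the statistical structure the analysis modules assume:
a synthetic genome (one chromosome, evenly spaced genes, CpG islands at
promoters, ATAC peaks over a distal probe stratum), true tumor and normal
methylation states near 0.05/0.95, planted differentially methylated CpG
blocks in chosen genomic contexts separating epitypes (and optionally
subgroups), observed beta values formed as purity-weighted tumor/normal
mixtures with truncated-normal noise, a log-normal FPKM expression matrix
with planted CpG-gene couplings of configurable sign and strength, and
planted co-expression blocks sharing a latent factor.  Everything is
deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GenomicInterval, build_consensus_gene_models

DEFAULT_SEED = 221027
GENE_SPACING = 50_000
GENE_LENGTH = 10_000
CHROM = "chr1"

#: probe stratum -> fraction of probes (contexts populated by construction)
DEFAULT_STRATA = {
    "promoter_island": 0.30,
    "proximal_shore": 0.20,
    "distal_atac": 0.25,
    "distal_ocean": 0.25,
}


@dataclass
class DMCBlock:
    """A planted block of differential CpGs within one context stratum."""

    context: str = "distal_atac"
    n: int = 200
    delta_beta: float = 0.4
    target: str = "epitype"  # "epitype" or "subgroup:<epitype>"


@dataclass
class NetworkBlock:
    size: int = 10
    loading: float = 0.9


@dataclass
class SimulationConfig:
    n_samples: int = 120
    epitype_fractions: tuple[float, ...] = (0.6, 0.4)
    subgroup_fractions: dict[str, tuple[float, ...]] | None = None
    n_probes: int = 20_000
    strata: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_STRATA))
    dmc_blocks: list[DMCBlock] = field(default_factory=lambda: [DMCBlock()])
    purity_range: tuple[float, float] = (0.3, 0.9)
    noise_sd: float = 0.03
    #: fraction of probes with epitype-independent inter-tumor heterogeneity
    #: (per-sample tumor beta scattered around a probe-level center); these
    #: populate the empirical-null universe of variable-but-unlinked CpGs
    het_fraction: float = 0.15
    het_sd: float = 0.15
    n_pairs: int = 50
    pair_coupling: float = 0.7
    pair_sign: int = -1
    network_blocks: list[NetworkBlock] = field(default_factory=lambda: [NetworkBlock()])
    n_genes: int = 400
    seed: int = DEFAULT_SEED

    def validate(self) -> None:
        if not np.isclose(sum(self.epitype_fractions), 1.0):
            raise ValueError("epitype fractions must sum to 1")
        if not np.isclose(sum(self.strata.values()), 1.0):
            raise ValueError("stratum fractions must sum to 1")
        lo, hi = self.purity_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("purity bounds must lie in (0, 1]")
        for blk in self.dmc_blocks:
            if not 0 <= blk.delta_beta < 1:
                raise ValueError("delta_beta must lie in [0, 1)")
            if blk.context not in self.strata:
                raise ValueError(f"unknown stratum {blk.context!r}")
        if self.subgroup_fractions:
            for ep, fracs in self.subgroup_fractions.items():
                if not np.isclose(sum(fracs), 1.0):
                    raise ValueError(f"subgroup fractions for {ep!r} must sum to 1")
        if self.n_samples < 4 or self.n_probes < 10 or self.n_genes < 2:
            raise ValueError("cohort dimensions too small")


@dataclass
class SyntheticTruth:
    """Planted structure of a simulated cohort."""

    epitype: pd.Series
    subgroup: pd.Series | None
    planted_dmc: dict[int, list[str]]
    tumor_beta: pd.DataFrame
    normal_beta: pd.Series
    purity: pd.Series
    pairs: list[dict]
    network_genes: list[list[str]]
    config: SimulationConfig


@dataclass
class Cohort:
    beta: pd.DataFrame
    purity: pd.Series
    fpkm: pd.DataFrame
    manifest: pd.DataFrame
    gene_records: list[dict]
    cgi: list[GenomicInterval]
    atac: list[GenomicInterval]
    tfbs: dict[str, list[GenomicInterval]]
    labels: pd.DataFrame
    truth: SyntheticTruth


def _gene_records(n_genes: int) -> list[dict]:
    recs = []
    for i in range(n_genes):
        start = 25_000 + i * GENE_SPACING
        strand = "+" if i % 2 == 0 else "-"
        recs.append(
            {
                "gene_id": f"G{i:04d}",
                "chrom": CHROM,
                "strand": strand,
                "start": start,
                "end": start + GENE_LENGTH,
            }
        )
    return recs


def _place_probes(cfg: SimulationConfig, models, rng) -> tuple[pd.DataFrame, pd.Series]:
    """Probe positions per stratum on the synthetic genome.

    promoter_island probes sit within +/-400 bp of a TSS (inside a CpG
    island), proximal_shore probes 2.5 kb downstream of a TSS (within 2 kb of
    the island edge), distal strata sit 15 kb (ocean) or 25 kb (ATAC) past
    the TSS, far from every island.
    """
    gene_ids = sorted(models)
    tss = np.array([models[g].tss for g in gene_ids])
    counts = {k: int(round(v * cfg.n_probes)) for k, v in cfg.strata.items()}
    # rounding drift goes to the largest stratum
    drift = cfg.n_probes - sum(counts.values())
    counts[max(counts, key=counts.get)] += drift

    offsets = {
        "promoter_island": (-400, 400),
        "proximal_shore": (2300, 2700),
        "distal_ocean": (14_800, 15_200),
        "distal_atac": (24_700, 25_100),
    }
    rows = []
    strata = []
    i = 0
    for stratum, n in counts.items():
        lo, hi = offsets[stratum]
        anchor = rng.choice(len(tss), size=n, replace=True)
        jitter = rng.integers(lo, hi, size=n)
        sign = np.where(np.array([models[gene_ids[a]].strand for a in anchor]) == "-", -1, 1)
        pos = tss[anchor] + sign * jitter
        for p in np.sort(pos):
            rows.append((f"cg{i:07d}", CHROM, int(p)))
            i += 1
        strata.extend([stratum] * n)
    manifest = pd.DataFrame(rows, columns=["probe_id", "chrom", "pos"])
    # strata were appended per block but rows re-sorted within the block only,
    # so the stratum order still matches
    return manifest, pd.Series(strata, index=manifest["probe_id"].to_numpy())


def _intervals_for(cfg, models, manifest, strata, rng):
    gene_ids = sorted(models)
    cgi = [
        GenomicInterval(CHROM, models[g].tss - 801, models[g].tss + 800)
        for g in gene_ids
    ]
    atac_probes = manifest.loc[(strata == "distal_atac").to_numpy(), "pos"]
    atac = [GenomicInterval(CHROM, int(p) - 101, int(p) + 100) for p in atac_probes]
    return cgi, atac


def simulate_cohort(config: SimulationConfig | None = None) -> Cohort:
    """Generate a full synthetic cohort plus ground truth (see module docs)."""
    cfg = config or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    gene_records = _gene_records(cfg.n_genes)
    models = build_consensus_gene_models(gene_records)
    manifest, strata = _place_probes(cfg, models, rng)
    cgi, atac = _intervals_for(cfg, models, manifest, strata, rng)
    probe_ids = manifest["probe_id"].to_numpy()
    n_probes, n_samples = len(probe_ids), cfg.n_samples
    samples = [f"S{j:03d}" for j in range(n_samples)]

    # -- labels ------------------------------------------------------------
    ep_names = [chr(ord("A") + i) for i in range(len(cfg.epitype_fractions))]
    counts = np.diff(np.round(np.cumsum((0.0,) + cfg.epitype_fractions) * n_samples)).astype(int)
    ep = np.repeat(ep_names, counts)
    rng.shuffle(ep)
    epitype = pd.Series(ep, index=samples, name="epitype")

    subgroup = None
    if cfg.subgroup_fractions:
        sub = pd.Series("", index=samples, dtype=object)
        for ep_name, fracs in cfg.subgroup_fractions.items():
            members = epitype.index[epitype == ep_name]
            c = np.diff(np.round(np.cumsum((0.0,) + tuple(fracs)) * len(members))).astype(int)
            labels = np.repeat([f"{ep_name}{i+1}" for i in range(len(fracs))], c)
            rng.shuffle(labels)
            sub.loc[members] = labels
        subgroup = sub.rename("subgroup")

    # -- methylation states ------------------------------------------------
    low = rng.random(n_probes) < 0.5
    t_base = np.where(low, rng.beta(5, 95, n_probes), rng.beta(95, 5, n_probes))
    somatic = rng.random(n_probes) < 0.1  # probes whose normal state differs
    n_state = np.where(
        somatic ^ low, rng.beta(5, 95, n_probes), rng.beta(95, 5, n_probes)
    )
    normal_beta = pd.Series(n_state, index=probe_ids, name="normal_beta")

    tumor = np.tile(t_base[:, None], (1, n_samples))
    planted: dict[int, list[str]] = {}
    used = np.zeros(n_probes, dtype=bool)
    for bi, blk in enumerate(cfg.dmc_blocks):
        pool = np.flatnonzero((strata == blk.context).to_numpy() & ~used)
        if len(pool) < blk.n:
            raise ValueError(f"stratum {blk.context!r} too small for block of {blk.n}")
        idx = rng.choice(pool, size=blk.n, replace=False)
        used[idx] = True
        planted[bi] = [probe_ids[i] for i in idx]
        if blk.target == "epitype":
            groups = epitype
            shifted = ep_names[-1]  # last epitype carries the shift
        else:
            _, ep_name = blk.target.split(":", 1)
            if subgroup is None:
                raise ValueError("subgroup block requires subgroup_fractions")
            groups = subgroup
            shifted = sorted(pd.unique(subgroup.loc[epitype == ep_name]))[-1]
        shift_cols = (groups == shifted).to_numpy()
        up = rng.random(blk.n) < 0.5
        base = np.where(up, rng.uniform(0.05, 0.9 - blk.delta_beta, blk.n),
                        rng.uniform(0.1 + blk.delta_beta, 0.95, blk.n))
        delta = np.where(up, blk.delta_beta, -blk.delta_beta)
        tumor[idx, :] = base[:, None]
        tumor[np.ix_(idx, np.flatnonzero(shift_cols))] = (base + delta)[:, None]
        normal_beta.iloc[idx] = base

    # epitype-independent inter-tumor heterogeneity: per-sample tumor betas
    # scattered around a probe-level center, uncorrelated with expression
    if cfg.het_fraction > 0:
        free = np.flatnonzero(~used)
        n_het = int(round(cfg.het_fraction * n_probes))
        het_idx = rng.choice(free, size=min(n_het, len(free)), replace=False)
        centers = rng.uniform(0.25, 0.75, len(het_idx))
        tumor[het_idx, :] = centers[:, None] + rng.normal(
            0.0, cfg.het_sd, (len(het_idx), n_samples)
        )
        normal_beta.iloc[het_idx] = centers

    tumor = np.clip(tumor, 0.0, 1.0)

    # -- observed beta = purity-weighted mixture + truncated noise ---------
    purity = pd.Series(
        rng.uniform(*cfg.purity_range, n_samples), index=samples, name="purity"
    )
    mix = tumor * purity.to_numpy()[None, :] + normal_beta.to_numpy()[:, None] * (
        1 - purity.to_numpy()[None, :]
    )
    if cfg.noise_sd > 0:
        a = (0.0 - mix) / cfg.noise_sd
        b = (1.0 - mix) / cfg.noise_sd
        noise = stats.truncnorm.rvs(a, b, scale=cfg.noise_sd, random_state=rng)
        beta_obs = np.clip(mix + noise, 0.0, 1.0)
    else:
        beta_obs = mix
    beta = pd.DataFrame(beta_obs, index=probe_ids, columns=samples)

    # -- expression --------------------------------------------------------
    gene_ids = sorted(models)
    mu = rng.normal(3.0, 1.5, cfg.n_genes)
    eps_sd = 0.8
    logx = mu[:, None] + rng.normal(0.0, eps_sd, (cfg.n_genes, n_samples))
    gene_pos = {g: i for i, g in enumerate(gene_ids)}

    # planted co-expression blocks share a latent factor per sample
    network_genes: list[list[str]] = []
    reserved: set[int] = set()
    for blk in cfg.network_blocks:
        free = [i for i in range(cfg.n_genes) if i not in reserved]
        idx = rng.choice(free, size=blk.size, replace=False)
        reserved.update(idx.tolist())
        factor = rng.normal(0.0, 1.0, n_samples)
        resid = rng.normal(0.0, 1.0, (blk.size, n_samples))
        logx[idx, :] = mu[idx][:, None] + eps_sd * (
            blk.loading * factor[None, :]
            + np.sqrt(1 - blk.loading**2) * resid
        )
        network_genes.append([gene_ids[i] for i in np.sort(idx)])

    # planted CpG-gene couplings: probe beta drives a nearby gene's log-expr
    pair_list: list[dict] = []
    if cfg.n_pairs > 0:
        if not planted:
            raise ValueError("planted pairs require at least one DMC block")
        dmc_ids = [p for ids in planted.values() for p in ids]
        if cfg.n_pairs > len(dmc_ids):
            raise ValueError("n_pairs exceeds planted DMC probe count")
        chosen = rng.choice(len(dmc_ids), size=cfg.n_pairs, replace=False)
        pair_gene_used: set[int] = set(reserved)
        manifest_idx = manifest.set_index("probe_id")
        tss = np.array([models[g].tss for g in gene_ids])
        for ci in chosen:
            probe = dmc_ids[ci]
            pos = int(manifest_idx.loc[probe, "pos"])
            order = np.argsort(np.abs(tss - pos))
            gi = next((int(g) for g in order if int(g) not in pair_gene_used), None)
            if gi is None or abs(tss[gi] - pos) > 250_000:
                continue
            pair_gene_used.add(gi)
            z = beta.loc[probe].to_numpy()
            z = (z - z.mean()) / z.std()
            resid = rng.normal(0.0, 1.0, n_samples)
            c = cfg.pair_coupling
            logx[gi, :] = mu[gi] + eps_sd * (
                cfg.pair_sign * c * z + np.sqrt(1 - c**2) * resid
            )
            pair_list.append(
                {
                    "probe_id": probe,
                    "gene_id": gene_ids[gi],
                    "sign": cfg.pair_sign,
                    "coupling": c,
                }
            )

    fpkm = pd.DataFrame(np.power(2.0, logx), index=gene_ids, columns=samples)

    # -- TF binding sites: one TF enriched on planted distal probes --------
    dmc_set = {p for ids in planted.values() for p in ids}
    tf_a: list[GenomicInterval] = []
    tf_b: list[GenomicInterval] = []
    probe_pos = manifest.set_index("probe_id")["pos"]
    for p in probe_ids:
        pos = int(probe_pos[p])
        if p in dmc_set and rng.random() < 0.6:
            tf_a.append(GenomicInterval(CHROM, pos - 51, pos + 50))
        if rng.random() < 0.05:
            tf_b.append(GenomicInterval(CHROM, pos - 51, pos + 50))
    tfbs = {"TF_A": tf_a, "TF_B": tf_b}

    labels = pd.DataFrame({"epitype": epitype})
    if subgroup is not None:
        labels["subgroup"] = subgroup

    truth = SyntheticTruth(
        epitype=epitype,
        subgroup=subgroup,
        planted_dmc=planted,
        tumor_beta=pd.DataFrame(tumor, index=probe_ids, columns=samples),
        normal_beta=normal_beta,
        purity=purity,
        pairs=pair_list,
        network_genes=network_genes,
        config=cfg,
    )
    return Cohort(
        beta=beta,
        purity=purity,
        fpkm=fpkm,
        manifest=manifest,
        gene_records=gene_records,
        cgi=cgi,
        atac=atac,
        tfbs=tfbs,
        labels=labels,
        truth=truth,
    )


def _write_bed(intervals, path, names=None) -> None:
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    with open(path, "w") as fh:
        for i, iv in enumerate(ivs):
            extra = f"\t{names[i]}" if names is not None else ""
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}{extra}\n")


def write_cohort(cohort: Cohort, directory) -> dict[str, str]:
    """Emit the cohort in the exact formats the pipeline ingests.

    Writes probe manifest / gene model TSVs, CGI + ATAC BED3, TFBS BED4, beta
    / FPKM / purity / labels TSVs, true tumor & normal beta TSVs and a truth
    JSON.  Returns a manifest mapping logical names to file paths.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    def _tsv(name, frame, **kw):
        path = d / f"{name}.tsv"
        frame.to_csv(path, sep="\t", **kw)
        files[name] = str(path)

    _tsv("beta", cohort.beta, index_label="probe_id")
    _tsv("fpkm", cohort.fpkm, index_label="gene_id")
    _tsv("purity", cohort.purity.to_frame(), index_label="sample_id")
    _tsv("labels", cohort.labels, index_label="sample_id")
    _tsv("manifest", cohort.manifest, index=False)
    _tsv("genes", pd.DataFrame(cohort.gene_records), index=False)
    _tsv("true_tumor_beta", cohort.truth.tumor_beta, index_label="probe_id")
    _tsv("true_normal_beta", cohort.truth.normal_beta.to_frame(), index_label="probe_id")

    _write_bed(cohort.cgi, d / "cgi.bed")
    files["cgi"] = str(d / "cgi.bed")
    _write_bed(cohort.atac, d / "atac.bed")
    files["atac"] = str(d / "atac.bed")
    tf_ivs = [iv for tf, ivs in sorted(cohort.tfbs.items()) for iv in ivs]
    tf_names = [tf for tf, ivs in sorted(cohort.tfbs.items()) for _ in ivs]
    order = sorted(range(len(tf_ivs)), key=lambda i: (tf_ivs[i].chrom, tf_ivs[i].start))
    _write_bed([tf_ivs[i] for i in order], d / "tfbs.bed", [tf_names[i] for i in order])
    files["tfbs"] = str(d / "tfbs.bed")

    truth = cohort.truth
    truth_json = {
        "epitype": truth.epitype.to_dict(),
        "subgroup": truth.subgroup.to_dict() if truth.subgroup is not None else None,
        "planted_dmc": {str(k): v for k, v in truth.planted_dmc.items()},
        "pairs": truth.pairs,
        "network_genes": truth.network_genes,
        "config": asdict(truth.config),
    }
    with open(d / "truth.json", "w") as fh:
        json.dump(truth_json, fh, indent=1)
    files["truth"] = str(d / "truth.json")
    return files
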