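"""Gene-centric and CpG-density context annotation of methylation array probes.

Each probe is placed in a genic context relative to the nearest consensus
transcription start site (promoter: within 500 bp; proximal: within 5 kbp but
outside the promoter window; distal: beyond 5 kbp), in a CpG-density context
relative to CpG islands (island / shore / ocean), and flagged for overlap with
open-chromatin (ATAC) peaks and transcription-factor binding sites.  Local CpG
density (observed/expected CpG ratio, GC fraction) yields the two standard
promoter-class schemes: a two-class high/low CpG split and the three-class
HCP/ICP/LCP scheme.

Coordinate conventions: probe positions and gene models are 1-based; intervals
read from BED-style input are 0-based half-open.  Conversion happens at ingest.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

PROMOTER_BP = 500
PROXIMAL_BP = 5000
SHORE_BP = 2000

SAXONOV_OE_CUT = 0.48
WEBER_HIGH_OE = 0.75
WEBER_HIGH_GC = 0.55
DENSITY_WINDOW_BP = 1001
WEBER_SUBWINDOW_BP = 500
WEBER_SUBWINDOW_STEP = 5


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start >= self.end:
            raise ValueError(
                f"interval start must precede end: {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """Consensus transcript model: one TSS/TES per gene.

    Coordinates are 1-based.  On the minus strand the TSS is the 3'-most
    genomic coordinate, so ``tss > tes``.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int

    def __post_init__(self) -> None:
        if self.tss == self.tes:
            raise ValueError(f"gene {self.gene_id}: tss equals tes")
        if self.strand == "-" and self.tss < self.tes:
            raise ValueError(f"gene {self.gene_id}: minus-strand tss must exceed tes")
        if self.strand == "+" and self.tss > self.tes:
            raise ValueError(f"gene {self.gene_id}: plus-strand tss must precede tes")


@dataclass
class CpGAnnotation:
    """Full per-probe context record."""

    probe_id: str
    chrom: str
    pos: int
    genic_context: str = "distal"
    nearest_gene: str = ""
    tss_distance: int | None = None
    cgi_context: str = "ocean"
    oe_ratio: float | None = None
    gc_frac: float | None = None
    saxonov_class: str | None = None
    weber_class: str | None = None
    atac_overlap: bool = False
    tf_set: set[str] = field(default_factory=set)


def build_consensus_gene_models(
    transcript_records: Iterable[Mapping],
) -> dict[str, GeneModel]:
    """Collapse transcript/exon records into one consensus model per gene.

    Records are mappings with keys ``gene_id``, ``chrom``, ``strand``,
    ``start``, ``end`` (1-based inclusive span of a transcript or exon).  The
    consensus TSS is the 5'-most base over all records of the gene and the TES
    the 3'-most base.

    Raises
    ------
    ValueError
        If records of one gene disagree on strand or chromosome.
    """
    spans: dict[str, dict] = {}
    for rec in transcript_records:
        gid = rec["gene_id"]
        entry = spans.setdefault(
            gid,
            {"chrom": rec["chrom"], "strand": rec["strand"], "min": np.inf, "max": -np.inf},
        )
        if entry["strand"] != rec["strand"]:
            raise ValueError(f"gene {gid}: transcripts on conflicting strands")
        if entry["chrom"] != rec["chrom"]:
            raise ValueError(f"gene {gid}: transcripts on conflicting chromosomes")
        entry["min"] = min(entry["min"], int(rec["start"]))
        entry["max"] = max(entry["max"], int(rec["end"]))

    models: dict[str, GeneModel] = {}
    for gid, entry in spans.items():
        lo, hi = int(entry["min"]), int(entry["max"])
        if entry["strand"] == "-":
            tss, tes = hi, lo
        else:
            tss, tes = lo, hi
        models[gid] = GeneModel(gid, entry["chrom"], entry["strand"], tss, tes)
    return models


def _classify_distance(d: int | float) -> str:
    ad = abs(d)
    if ad <= PROMOTER_BP:
        return "promoter"
    if ad <= PROXIMAL_BP:
        return "proximal"
    return "distal"


def annotate_genic_context(
    cpg_pos: int,
    chrom: str,
    models: Mapping[str, GeneModel] | Sequence[GeneModel],
) -> tuple[str, str, int | None]:
    """Assign genic context from the nearest consensus TSS on the chromosome.

    Returns ``(context, nearest_gene, tss_distance)``.  The distance is signed
    by gene strand: positive downstream of the TSS (inside/past the gene),
    negative upstream.  With no gene on the chromosome, the probe is distal
    with an empty nearest gene.  Equidistant TSSs break ties by lexical
    gene id.
    """
    if isinstance(models, Mapping):
        models = list(models.values())
    candidates = [m for m in models if m.chrom == chrom]
    if not candidates:
        return "distal", "", None
    best = min(candidates, key=lambda m: (abs(cpg_pos - m.tss), m.gene_id))
    d = cpg_pos - best.tss
    if best.strand == "-":
        d = -d
    return _classify_distance(d), best.gene_id, d


def _merge_intervals(intervals: Sequence[GenomicInterval]) -> dict[str, np.ndarray]:
    """Merge overlapping intervals, returning per-chrom (n, 2) start/end arrays."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged: dict[str, np.ndarray] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        out: list[list[int]] = []
        for s, e in ivs:
            if out and s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = np.asarray(out, dtype=np.int64)
    return merged


def annotate_cgi_context(
    cpg_pos: int,
    chrom: str,
    cgi: Sequence[GenomicInterval],
    shore_bp: int = SHORE_BP,
) -> str:
    """Island if inside a CpG island, shore within ``shore_bp`` of an island
    edge, ocean otherwise.  ``cpg_pos`` is 1-based; islands 0-based half-open."""
    merged = _merge_intervals(cgi).get(chrom)
    if merged is None or len(merged) == 0:
        return "ocean"
    p = cpg_pos - 1  # 0-based
    inside = (merged[:, 0] <= p) & (p < merged[:, 1])
    if inside.any():
        return "island"
    # distance to nearest edge; a point left of start is start - p away,
    # right of end is p - (end - 1) away
    dist = np.minimum(np.abs(merged[:, 0] - p), np.abs(p - (merged[:, 1] - 1)))
    if dist.min() <= shore_bp:
        return "shore"
    return "ocean"


def _oe_and_gc(seq: str) -> tuple[float, float]:
    length = len(seq)
    counts = Counter(seq)
    n_c, n_g = counts["C"], counts["G"]
    n_cpg = seq.count("CG")
    gc = (n_c + n_g) / length
    oe = 0.0 if n_c == 0 or n_g == 0 else n_cpg * length / (n_c * n_g)
    return oe, gc


def compute_cpg_density(window_sequence: str) -> tuple[float, float, str, str]:
    """CpG density metrics over a window centered on the probe.

    Returns ``(oe_ratio, gc_frac, saxonov_class, weber_class)`` where
    ``oe_ratio = (#CpG * L) / (#C * #G)`` (0 if either count is 0) and
    ``gc_frac = (#C + #G) / L``.  The two-class split calls HCG at
    oe_ratio >= 0.48; the three-class scheme calls HCP when some 500-bp
    subwindow has oe >= 0.75 and GC >= 0.55, LCP when every subwindow has
    oe < 0.48, and ICP otherwise.
    """
    seq = window_sequence.upper()
    if len(seq) < 2:
        raise ValueError("window sequence must have length >= 2")
    oe, gc = _oe_and_gc(seq)
    saxonov = "HCG" if oe >= SAXONOV_OE_CUT else "LCG"

    win = min(WEBER_SUBWINDOW_BP, len(seq))
    starts = range(0, len(seq) - win + 1, WEBER_SUBWINDOW_STEP)
    sub = [_oe_and_gc(seq[s : s + win]) for s in starts]
    if any(o >= WEBER_HIGH_OE and g >= WEBER_HIGH_GC for o, g in sub):
        weber = "HCP"
    elif all(o < SAXONOV_OE_CUT for o, _ in sub):
        weber = "LCP"
    else:
        weber = "ICP"
    return oe, gc, saxonov, weber


def annotate_overlap(cpg_pos: int, chrom: str, peaks: Sequence[GenomicInterval]) -> bool:
    """True iff the 1-bp probe position (1-based) falls inside any peak
    (0-based half-open)."""
    p = cpg_pos - 1
    return any(iv.chrom == chrom and iv.start <= p < iv.end for iv in peaks)


def annotate_probes(
    manifest: pd.DataFrame,
    models: Mapping[str, GeneModel],
    cgi: Sequence[GenomicInterval] = (),
    atac: Sequence[GenomicInterval] = (),
    tfbs: Mapping[str, Sequence[GenomicInterval]] | None = None,
    sequences: Mapping[str, str] | None = None,
    shore_bp: int = SHORE_BP,
) -> pd.DataFrame:
    """Annotate every probe in a manifest (columns probe_id, chrom, pos).

    Vectorized over probes: nearest-TSS search by sorted TSS arrays per
    chromosome, island/shore by merged-interval distance, peak overlap by
    interval stabbing.  ``sequences`` optionally maps probe_id to the density
    window sequence; density fields are null without it.

    Returns a DataFrame indexed by probe_id with columns genic_context,
    nearest_gene, tss_distance, cgi_context, atac_overlap, tf_set, oe_ratio,
    gc_frac, saxonov_class, weber_class.
    """
    probe_ids = manifest["probe_id"].to_numpy()
    chroms = manifest["chrom"].to_numpy()
    pos = manifest["pos"].to_numpy(dtype=np.int64)

    # nearest TSS per chromosome via searchsorted; lexical gene tie-break
    tss_by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in np.unique(chroms):
        ms = sorted(
            (m for m in models.values() if m.chrom == chrom),
            key=lambda m: (m.tss, m.gene_id),
        )
        if ms:
            tss_by_chrom[chrom] = (
                np.array([m.tss for m in ms], dtype=np.int64),
                np.array([m.gene_id for m in ms]),
                np.array([1 if m.strand == "+" else -1 for m in ms], dtype=np.int64),
            )

    genic = np.full(len(pos), "distal", dtype=object)
    nearest = np.full(len(pos), "", dtype=object)
    tss_dist = np.full(len(pos), np.nan)

    for chrom, (tss, gids, strands) in tss_by_chrom.items():
        mask = chroms == chrom
        if not mask.any():
            continue
        p = pos[mask]
        idx = np.searchsorted(tss, p)
        left = np.clip(idx - 1, 0, len(tss) - 1)
        right = np.clip(idx, 0, len(tss) - 1)
        dl = np.abs(p - tss[left])
        dr = np.abs(p - tss[right])
        # prefer smaller distance; on exact tie prefer the lexically smaller
        # gene id (sort order within equal tss already lexical)
        use_left = (dl < dr) | ((dl == dr) & (gids[left] <= gids[right]))
        pick = np.where(use_left, left, right)
        d = (p - tss[pick]) * strands[pick]
        genic[mask] = np.select(
            [np.abs(d) <= PROMOTER_BP, np.abs(d) <= PROXIMAL_BP],
            ["promoter", "proximal"],
            default="distal",
        )
        nearest[mask] = gids[pick]
        tss_dist[mask] = d

    cgi_context = _cgi_context_batch(chroms, pos, cgi, shore_bp)
    atac_flag = _overlap_batch(chroms, pos, atac)

    tf_sets: list[set[str]] = [set() for _ in range(len(pos))]
    if tfbs:
        for tf, peaks in tfbs.items():
            hit = _overlap_batch(chroms, pos, peaks)
            for i in np.flatnonzero(hit):
                tf_sets[i].add(tf)

    out = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chrom": chroms,
            "pos": pos,
            "genic_context": genic,
            "nearest_gene": nearest,
            "tss_distance": tss_dist,
            "cgi_context": cgi_context,
            "atac_overlap": atac_flag,
            "tf_set": tf_sets,
        }
    ).set_index("probe_id")

    dens = pd.DataFrame(
        index=out.index,
        columns=["oe_ratio", "gc_frac", "saxonov_class", "weber_class"],
        dtype=object,
    )
    if sequences:
        for pid, seq in sequences.items():
            if pid in dens.index:
                dens.loc[pid] = compute_cpg_density(seq)
    return pd.concat([out, dens], axis=1)


def _cgi_context_batch(
    chroms: np.ndarray,
    pos: np.ndarray,
    cgi: Sequence[GenomicInterval],
    shore_bp: int,
) -> np.ndarray:
    out = np.full(len(pos), "ocean", dtype=object)
    merged = _merge_intervals(cgi)
    for chrom, ivs in merged.items():
        mask = chroms == chrom
        if not mask.any():
            continue
        p = pos[mask] - 1
        idx = np.searchsorted(ivs[:, 0], p, side="right") - 1
        idx_c = np.clip(idx, 0, len(ivs) - 1)
        inside = (idx >= 0) & (p < ivs[idx_c, 1])
        nxt = np.clip(idx + 1, 0, len(ivs) - 1)
        d_prev = np.where(idx >= 0, p - (ivs[idx_c, 1] - 1), np.iinfo(np.int64).max)
        d_next = np.where(idx + 1 < len(ivs), ivs[nxt, 0] - p, np.iinfo(np.int64).max)
        near = np.minimum(np.abs(d_prev), np.abs(d_next)) <= shore_bp
        out[mask] = np.select([inside, near], ["island", "shore"], default="ocean")
    return out


def _overlap_batch(
    chroms: np.ndarray, pos: np.ndarray, peaks: Sequence[GenomicInterval]
) -> np.ndarray:
    out = np.zeros(len(pos), dtype=bool)
    merged = _merge_intervals(peaks)
    for chrom, ivs in merged.items():
        mask = chroms == chrom
        if not mask.any():
            continue
        p = pos[mask] - 1
        idx = np.searchsorted(ivs[:, 0], p, side="right") - 1
        idx_c = np.clip(idx, 0, len(ivs) - 1)
        out[mask] = (idx >= 0) & (p < ivs[idx_c, 1])
    return out


def variance_by_context(
    beta: pd.DataFrame,
    annotations: pd.DataFrame,
    grouping: Sequence[str],
) -> pd.DataFrame:
    """Per-probe SD across samples, grouped by annotation context keys.

    ``beta`` is probes x samples; missing values are ignored per probe.
    Returns a long DataFrame with one row per probe: the grouping keys and the
    probe's sample SD (ddof=1).
    """
    if beta.shape[1] < 2:
        raise ValueError("need at least 2 samples to compute SDs")
    for key in grouping:
        if key not in annotations.columns:
            raise KeyError(f"context key {key!r} absent from annotations")
    sd = beta.std(axis=1, ddof=1, skipna=True)
    common = beta.index.intersection(annotations.index)
    out = annotations.loc[common, list(grouping)].copy()
    out["sd"] = sd.loc[common]
    return out


def tfbs_enrichment(
    cluster_probes: Iterable[str],
    background_probes: Iterable[str],
    annotations: pd.DataFrame,
) -> pd.DataFrame:
    """Per-TF enrichment of binding-site overlap in a CpG cluster.

    One-sided (greater) Fisher exact test on the 2x2 table of cluster
    membership vs TF overlap, with Benjamini-Hochberg adjustment across TFs.
    The cluster must be a subset of the background.
    """
    cluster = set(cluster_probes)
    background = set(background_probes)
    if not cluster:
        raise ValueError("cluster is empty")
    if not cluster <= background:
        raise ValueError("cluster must be a subset of the background")
    tf_sets = annotations.loc[list(background), "tf_set"]
    all_tfs = sorted(set().union(*tf_sets))
    n_bg = len(background)
    n_cl = len(cluster)
    rows = []
    for tf in all_tfs:
        with_tf = {p for p, s in tf_sets.items() if tf in s}
        a = len(cluster & with_tf)
        b = n_cl - a
        c = len(with_tf) - a
        d = (n_bg - n_cl) - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append((tf, a, n_cl, len(with_tf), odds, p))
    result = pd.DataFrame(
        rows, columns=["tf", "cluster_overlap", "cluster_size", "background_overlap", "odds_ratio", "p"]
    ).set_index("tf")
    if len(result):
        result["p_adj"] = multipletests(result["p"], method="fdr_bh")[1]
    else:
        result["p_adj"] = pd.Series(dtype=float)
    return result
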