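"""End-to-end orchestration: simulate/ingest -> adjust -> cluster -> diffmeth
-> linkpairs -> diffexpr -> networks.

`run_pipeline` wires the module surfaces together with the workflow's default
parameters and returns every intermediate product, so tests and scripts can
interrogate any stage.  It operates on an in-memory cohort (see
:mod:`epitype.simulate`); the CLI exposes the same steps over files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import annotation, diffmeth, epityping, expression, linkage, purity
from .simulate import Cohort


@dataclass
class PipelineResult:
    annotations: pd.DataFrame
    adjusted_beta: pd.DataFrame
    inferred_normal: pd.DataFrame
    features: epityping.FeatureSet
    epitypes: epityping.EpitypeResult
    concordance: float | None
    dmc: pd.DataFrame
    pairs: pd.DataFrame
    null_cutoffs: linkage.NullCutoffs | None
    de: pd.DataFrame
    networks: list[expression.GeneNetwork]
    extras: dict = field(default_factory=dict)


def run_pipeline(
    cohort: Cohort,
    n_top: int = 1000,
    k: int = 2,
    nrun: int = 30,
    seed: int = 221027,
    p_cut: float = 0.01,
    delta_cut: float = 0.25,
    null_probes: int = 2000,
    max_pair_probes: int = 500,
) -> PipelineResult:
    """Run the full workflow on a cohort.

    ``null_probes`` and ``max_pair_probes`` bound the empirical-null and
    pair-enumeration work (the statistics are unchanged; only the sampling
    breadth scales).  Concordance against the cohort's true epitype labels is
    reported when the truth carries a two-epitype design.
    """
    models = annotation.build_consensus_gene_models(cohort.gene_records)
    ann = annotation.annotate_probes(
        cohort.manifest, models, cgi=cohort.cgi, atac=cohort.atac, tfbs=cohort.tfbs
    )

    model_set = purity.fit_purity_models(cohort.beta, cohort.purity, seed=seed)
    adjusted, normal = purity.adjust_cohort(model_set, cohort.beta, cohort.purity)

    features = epityping.select_top_variant(
        adjusted,
        ann,
        epityping.context_predicate(genic="distal", atac=True),
        n_top=n_top,
    )
    result = epityping.nmf_cluster(
        adjusted.loc[features.probes], k=k, nrun=nrun, seed=seed
    )

    concordance = None
    truth_ep = cohort.truth.epitype
    if k == 2 and truth_ep.nunique() == 2:
        concordance = epityping.cluster_label_concordance(
            result.sample_assignment, truth_ep
        )

    groups = result.sample_assignment
    test = "wilcoxon" if k == 2 else "kruskal"
    dmc = diffmeth.diff_meth(
        adjusted, groups, test=test, adjust="bonferroni", p_cut=p_cut, delta_cut=delta_cut
    )
    sig_probes = list(dmc.index[dmc["significant"]])

    cutoffs = None
    pairs = pd.DataFrame(columns=["probe_id", "gene_id", "tss_distance", "jackknife_r"])
    if sig_probes:
        cutoffs = linkage.empirical_null(
            adjusted,
            cohort.fpkm,
            models,
            cohort.manifest,
            n_probes=min(null_probes, len(adjusted)),
            seed=seed,
        )
        probe_subset = sig_probes[:max_pair_probes]
        pairs = linkage.build_pairs(
            adjusted, cohort.fpkm, models, cohort.manifest, probes=probe_subset
        )
        pairs = linkage.call_significant_pairs(pairs, cutoffs)

    de = expression.diff_expr(cohort.fpkm, groups)
    networks = expression.build_gene_networks(cohort.fpkm)

    return PipelineResult(
        annotations=ann,
        adjusted_beta=adjusted,
        inferred_normal=normal,
        features=features,
        epitypes=result,
        concordance=concordance,
        dmc=dmc,
        pairs=pairs,
        null_cutoffs=cutoffs,
        de=de,
        networks=networks,
        extras={"purity_models": model_set},
    )


def recovery_metrics(cohort: Cohort, result: PipelineResult) -> dict[str, float]:
    """Ground-truth recovery summary for a simulated cohort."""
    truth = cohort.truth
    fitted = result.extras["purity_models"].fitted
    adj = result.adjusted_beta.to_numpy()[fitted]
    tum = truth.tumor_beta.to_numpy()[fitted]
    mae_tumor = float(np.nanmean(np.abs(adj - tum)))
    norm = result.inferred_normal.to_numpy()[fitted]
    true_norm = truth.normal_beta.to_numpy()[fitted][:, None]
    mae_normal = float(np.nanmean(np.abs(norm - true_norm)))

    planted = {p for ids in truth.planted_dmc.values() for p in ids}
    sig = set(result.dmc.index[result.dmc["significant"]])
    dmc_recall = len(planted & sig) / len(planted) if planted else float("nan")

    pair_truth = {(p["probe_id"], p["gene_id"]) for p in truth.pairs}
    called = {
        (r.probe_id, r.gene_id)
        for r in result.pairs.itertuples()
        if getattr(r, "significant", False)
    }
    pair_recall = (
        len(pair_truth & called) / len(pair_truth) if pair_truth else float("nan")
    )

    network_hit = 0.0
    if truth.network_genes:
        best = 0.0
        for net in result.networks:
            got = set(net.genes)
            for planted_net in truth.network_genes:
                want = set(planted_net)
                jacc = len(got & want) / len(got | want)
                best = max(best, jacc)
        network_hit = best

    return {
        "mae_adjusted_vs_tumor": mae_tumor,
        "mae_normal": mae_normal,
        "epitype_concordance": result.concordance if result.concordance is not None else float("nan"),
        "dmc_recall": dmc_recall,
        "pair_recall": pair_recall,
        "network_jaccard": network_hit,
        "n_significant_dmc": float(len(sig)),
        "n_significant_pairs": float(len(called)),
    }
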