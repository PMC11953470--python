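"""CpG-gene window mapping, jackknife correlation, empirical null, filters."""

import numpy as np
import pandas as pd
import pytest

from epitype.annotation import GeneModel
from epitype.linkage import (
    NullCutoffs,
    build_pairs,
    call_significant_pairs,
    candidate_epigene_filter,
    empirical_null,
    filter_pair_inputs,
    jackknife_pearson,
    jackknife_pearson_rows,
    map_cpg_to_genes,
)


def oracle_jackknife(x, y):
    """Brute-force: Pearson via the explicit sum formula on full data and
    every leave-one-out subsample; smallest |r| wins (full-data first)."""
    def pearson(u, v):
        u = np.asarray(u, float)
        v = np.asarray(v, float)
        n = len(u)
        num = n * (u * v).sum() - u.sum() * v.sum()
        den = np.sqrt(n * (u**2).sum() - u.sum() ** 2) * np.sqrt(
            n * (v**2).sum() - v.sum() ** 2
        )
        return num / den

    cands = [pearson(x, y)]
    for i in range(len(x)):
        keep = [j for j in range(len(x)) if j != i]
        cands.append(pearson(np.asarray(x)[keep], np.asarray(y)[keep]))
    cands = np.array(cands)
    return cands[np.argmin(np.abs(cands))]


class TestWindowMapping:
    MODELS = {
        "NEAR": GeneModel("NEAR", "chr1", "+", 1_000_000, 1_010_000),
        "IN240": GeneModel("IN240", "chr1", "+", 1_240_000, 1_250_000),
        "EDGE": GeneModel("EDGE", "chr1", "+", 1_250_000, 1_260_000),
        "OUT": GeneModel("OUT", "chr1", "+", 1_260_000, 1_270_000),
        "OTHER": GeneModel("OTHER", "chr2", "+", 1_000_000, 1_010_000),
    }

    def test_window_inclusion_rules(self):
        hits = dict(map_cpg_to_genes(1_000_000, "chr1", self.MODELS))
        assert "IN240" in hits  # 240 kb away
        assert "EDGE" in hits  # exactly 250 kb: inclusive
        assert "OUT" not in hits  # 260 kb away
        assert "OTHER" not in hits  # different chromosome

    def test_signed_distance_by_strand(self):
        models = {"M": GeneModel("M", "chr1", "-", 500_000, 490_000)}
        hits = dict(map_cpg_to_genes(499_000, "chr1", models))
        assert hits["M"] == 1_000  # left of a minus-strand TSS = downstream

    def test_empty_when_no_genes(self):
        assert map_cpg_to_genes(5, "chrZ", self.MODELS) == []


class TestPairFilters:
    def test_beta_range_filter(self):
        probe_ok, _ = filter_pair_inputs([0.3, 0.4, 0.5], [0, 5, 10])
        assert not probe_ok  # range 0.2 <= 0.25
        probe_ok, _ = filter_pair_inputs([0.3, 0.4, 0.56], [0, 5, 10])
        assert probe_ok

    def test_fpkm_filters(self):
        _, gene_ok = filter_pair_inputs([0, 1], [0.1, 0.5, 0.6])
        assert not gene_ok  # mean 0.4 < 0.5
        _, gene_ok = filter_pair_inputs([0, 1], [1.0, 1.5, 1.8])
        assert not gene_ok  # range 0.8 <= 1
        _, gene_ok = filter_pair_inputs([0, 1], [1.0, 1.5, 2.5])
        assert gene_ok


class TestJackknifePearson:
    def test_collinear_returns_unity(self, rng):
        x = rng.random(10)
        assert jackknife_pearson(x, 2 * x + 1) == pytest.approx(1.0)
        assert jackknife_pearson(x, -x) == pytest.approx(-1.0)

    def test_outlier_damped_to_loo_value(self, rng):
        x = rng.random(19)
        y = rng.random(19)
        x = np.append(x, 30.0)
        y = np.append(y, 30.0)  # single point manufactures a high r_full
        r_full = np.corrcoef(x, y)[0, 1]
        jk = jackknife_pearson(x, y)
        r_wo = np.corrcoef(x[:-1], y[:-1])[0, 1]
        assert r_full > 0.9
        assert abs(jk) < 0.5
        assert jk == pytest.approx(r_wo, abs=1e-12)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 51))
            x = rng.normal(size=n)
            y = 0.5 * x + rng.normal(size=n)
            assert jackknife_pearson(x, y) == pytest.approx(
                oracle_jackknife(x, y), abs=1e-12
            )

    def test_within_candidate_envelope(self, rng):
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        cands = [np.corrcoef(x, y)[0, 1]]
        for i in range(15):
            keep = np.arange(15) != i
            cands.append(np.corrcoef(x[keep], y[keep])[0, 1])
        jk = jackknife_pearson(x, y)
        assert min(cands) - 1e-12 <= jk <= max(cands) + 1e-12

    def test_constant_subsample_raises(self):
        x = np.array([1.0, 1.0, 1.0, 1.0, 2.0])
        y = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        with pytest.raises(ValueError, match="constant"):
            jackknife_pearson(x, y)  # dropping the 2.0 leaves x constant

    def test_short_input_raises(self):
        with pytest.raises(ValueError):
            jackknife_pearson([1, 2, 3], [1, 2, 3])

    def test_batch_matches_scalar(self, rng):
        x = rng.normal(size=(40, 25))
        y = 0.3 * x + rng.normal(size=(40, 25))
        batch = jackknife_pearson_rows(x, y)
        for i in range(40):
            assert batch[i] == pytest.approx(jackknife_pearson(x[i], y[i]), abs=1e-10)


def _null_cohort(rng, n_probes=300, n_samples=60, n_genes=40):
    spacing = 50_000
    models = {
        f"G{i:03d}": GeneModel(f"G{i:03d}", "chr1", "+", 25_000 + i * spacing,
                               30_000 + i * spacing)
        for i in range(n_genes)
    }
    manifest = pd.DataFrame(
        {
            "probe_id": [f"cg{i:05d}" for i in range(n_probes)],
            "chrom": "chr1",
            "pos": rng.integers(1, n_genes * spacing, n_probes),
        }
    )
    beta = pd.DataFrame(
        rng.uniform(0.1, 0.9, (n_probes, n_samples)),
        index=manifest["probe_id"], columns=[f"S{j}" for j in range(n_samples)],
    )
    fpkm = pd.DataFrame(
        rng.lognormal(2.0, 1.0, (n_genes, n_samples)),
        index=sorted(models), columns=beta.columns,
    )
    return beta, fpkm, models, manifest


class TestEmpiricalNull:
    def test_null_band_near_analytic_width(self, rng):
        beta, fpkm, models, manifest = _null_cohort(rng, n_samples=100)
        cuts = empirical_null(beta, fpkm, models, manifest, n_probes=300, seed=5)
        # analytic null SD of r is ~1/sqrt(n-1) ~= 0.1; the conservative
        # jackknife band must be inside +/-0.3 and roughly symmetric
        assert -0.3 < cuts.low < -0.05
        assert 0.05 < cuts.high < 0.3
        assert abs(cuts.low + cuts.high) < 0.1

    def test_deterministic_given_seed(self, rng):
        beta, fpkm, models, manifest = _null_cohort(rng, n_probes=150)
        a = empirical_null(beta, fpkm, models, manifest, n_probes=100, seed=11)
        b = empirical_null(beta, fpkm, models, manifest, n_probes=100, seed=11)
        assert (a.low, a.high) == (b.low, b.high)

    def test_small_universe_warns_and_samples_with_replacement(self, rng):
        beta, fpkm, models, manifest = _null_cohort(rng, n_probes=50)
        with pytest.warns(UserWarning, match="with replacement"):
            cuts = empirical_null(beta, fpkm, models, manifest, n_probes=100, seed=3)
        assert cuts.low <= cuts.high


class TestSignificanceCalls:
    def test_strict_boundaries(self):
        cuts = NullCutoffs(-0.3, 0.3, 100, 0)
        pairs = pd.DataFrame(
            {"probe_id": list("abcd"), "gene_id": list("wxyz"),
             "tss_distance": [0] * 4, "jackknife_r": [-0.3, 0.0, 0.3, 0.31]}
        )
        out = call_significant_pairs(pairs, cuts)
        assert list(out["significant"]) == [False, False, False, True]

    def test_planted_signal_flagged(self, rng):
        beta, fpkm, models, manifest = _null_cohort(rng, n_samples=80)
        # plant strong negative coupling: gene G000 expression follows probe 0
        probe = manifest["probe_id"].iloc[0]
        manifest.loc[0, "pos"] = models["G000"].tss + 100
        z = (beta.loc[probe] - beta.loc[probe].mean()) / beta.loc[probe].std()
        fpkm.loc["G000"] = np.exp(2.0 - 2.5 * z)
        cuts = empirical_null(beta, fpkm, models, manifest, n_probes=300, seed=5)
        pairs = build_pairs(beta, fpkm, models, manifest, probes=[probe])
        out = call_significant_pairs(pairs, cuts)
        hit = out[(out["probe_id"] == probe) & (out["gene_id"] == "G000")]
        assert hit["significant"].all()
        assert (hit["jackknife_r"] < 0).all()

    def test_pairs_invariant_to_sample_and_gene_order(self, rng):
        beta, fpkm, models, manifest = _null_cohort(rng, n_probes=80)
        base = build_pairs(beta, fpkm, models, manifest)
        perm_samples = rng.permutation(beta.columns)
        perm_genes = rng.permutation(fpkm.index)
        shuffled = build_pairs(
            beta[perm_samples], fpkm.loc[perm_genes, perm_samples], models, manifest
        )
        merged = base.merge(shuffled, on=["probe_id", "gene_id"], suffixes=("_a", "_b"))
        assert len(merged) == len(base)
        np.testing.assert_allclose(
            merged["jackknife_r_a"], merged["jackknife_r_b"], atol=1e-12
        )


class TestCandidateFilter:
    def _pairs(self, gene, rs, dists, sig=True):
        return pd.DataFrame(
            {
                "probe_id": [f"cg{i}" for i in range(len(rs))],
                "gene_id": gene,
                "tss_distance": dists,
                "jackknife_r": rs,
                "significant": sig,
            }
        )

    def test_gene_with_three_negative_promoter_pairs_retained(self):
        pairs = self._pairs("GENE1", [-0.5, -0.6, -0.7], [1000, -2000, 6500])
        medians = pd.DataFrame({"basal": [10.0], "nonbasal": [3.0]}, index=["GENE1"])
        out = candidate_epigene_filter(pairs, {"GENE1"}, medians)
        assert out == ["GENE1"]

    def test_two_cpgs_insufficient(self):
        pairs = self._pairs("GENE1", [-0.5, -0.6], [1000, 2000])
        medians = pd.DataFrame({"a": [10.0], "b": [3.0]}, index=["GENE1"])
        assert candidate_epigene_filter(pairs, {"GENE1"}, medians) == []

    def test_positive_correlations_dropped(self):
        pairs = self._pairs("GENE1", [0.5, 0.6, 0.7], [1000, 2000, 3000])
        medians = pd.DataFrame({"a": [10.0], "b": [3.0]}, index=["GENE1"])
        assert candidate_epigene_filter(pairs, {"GENE1"}, medians) == []

    def test_distance_de_membership_and_fold_rules(self):
        pairs = self._pairs("GENE1", [-0.5, -0.6, -0.7], [8000, 9000, 10_000])
        medians = pd.DataFrame({"a": [10.0], "b": [3.0]}, index=["GENE1"])
        assert candidate_epigene_filter(pairs, {"GENE1"}, medians) == []  # too far
        near = self._pairs("GENE1", [-0.5, -0.6, -0.7], [1000, 2000, 3000])
        assert candidate_epigene_filter(near, set(), medians) == []  # not DE
        weak = pd.DataFrame({"a": [8.0], "b": [4.0]}, index=["GENE1"])
        assert candidate_epigene_filter(near, {"GENE1"}, weak) == []  # diff 4 <= 5
        strong = pd.DataFrame({"a": [30.0], "b": [2.0]}, index=["GENE1"])
        assert candidate_epigene_filter(
            near, {"GENE1"}, strong, min_fold_change=10
        ) == ["GENE1"]
        mild = pd.DataFrame({"a": [16.0], "b": [2.0]}, index=["GENE1"])
        assert candidate_epigene_filter(
            near, {"GENE1"}, mild, min_fold_change=10
        ) == []  # fold 8 <= 10
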