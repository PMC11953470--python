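"""Context assignment, CpG density metrics, overlaps and TFBS enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epitype.annotation import (
    GeneModel,
    GenomicInterval,
    annotate_cgi_context,
    annotate_genic_context,
    annotate_overlap,
    annotate_probes,
    build_consensus_gene_models,
    compute_cpg_density,
    tfbs_enrichment,
    variance_by_context,
)


class TestConsensusGeneModels:
    def test_tss_is_five_prime_most_base_over_transcripts(self):
        models = build_consensus_gene_models(
            [
                {"gene_id": "A", "chrom": "chr1", "strand": "+", "start": 150, "end": 900},
                {"gene_id": "A", "chrom": "chr1", "strand": "+", "start": 100, "end": 700},
            ]
        )
        assert models["A"].tss == 100
        assert models["A"].tes == 900

    def test_single_transcript_identity(self):
        models = build_consensus_gene_models(
            [{"gene_id": "B", "chrom": "chr2", "strand": "+", "start": 10, "end": 50}]
        )
        assert (models["B"].tss, models["B"].tes) == (10, 50)

    def test_minus_strand_tss_is_rightmost(self):
        models = build_consensus_gene_models(
            [
                {"gene_id": "C", "chrom": "chr1", "strand": "-", "start": 100, "end": 300},
                {"gene_id": "C", "chrom": "chr1", "strand": "-", "start": 200, "end": 500},
            ]
        )
        assert models["C"].tss == 500
        assert models["C"].tes == 100

    def test_conflicting_strands_error_names_gene(self):
        with pytest.raises(ValueError, match="GENEX"):
            build_consensus_gene_models(
                [
                    {"gene_id": "GENEX", "chrom": "chr1", "strand": "+", "start": 1, "end": 10},
                    {"gene_id": "GENEX", "chrom": "chr1", "strand": "-", "start": 5, "end": 20},
                ]
            )


class TestGenicContext:
    MODELS = {
        "A": GeneModel("A", "chr1", "+", 10_000, 20_000),
        "B": GeneModel("B", "chr1", "+", 17_000, 30_000),
    }

    @pytest.mark.parametrize(
        "pos,expected",
        [
            (10_300, "promoter"),  # |d| = 300
            (10_500, "promoter"),  # inclusive boundary
            (10_501, "proximal"),
            (5_000, "proximal"),  # |d| = 5000 inclusive
            (4_999, "distal"),  # |d| = 5001
            (4_000, "distal"),  # |d| = 6000
        ],
    )
    def test_window_boundaries(self, pos, expected):
        ctx, _, _ = annotate_genic_context(pos, "chr1", self.MODELS)
        assert ctx == expected

    def test_nearest_gene_wins(self):
        # 3 kb from A's TSS, 10 kb would be B at 17 kb
        ctx, gene, d = annotate_genic_context(13_000, "chr1", self.MODELS)
        assert (ctx, gene, d) == ("proximal", "A", 3_000)

    def test_no_gene_on_chromosome(self):
        ctx, gene, d = annotate_genic_context(100, "chrX", self.MODELS)
        assert (ctx, gene, d) == ("distal", "", None)

    def test_minus_strand_distance_sign(self):
        models = {"M": GeneModel("M", "chr1", "-", 10_000, 5_000)}
        # 1 kb to the left of a minus-strand TSS is downstream (+)
        _, _, d = annotate_genic_context(9_000, "chr1", models)
        assert d == 1_000

    def test_batch_agrees_with_bruteforce(self, rng):
        n_genes, n_probes = 200, 500
        tss = rng.choice(np.arange(1_000, 2_000_000), size=n_genes, replace=False)
        strands = rng.choice(["+", "-"], size=n_genes)
        models = {}
        for i, (t, s) in enumerate(zip(tss, strands)):
            gid = f"G{i:03d}"
            if s == "+":
                models[gid] = GeneModel(gid, "chr1", "+", int(t), int(t) + 100)
            else:
                models[gid] = GeneModel(gid, "chr1", "-", int(t), int(t) - 100)
        manifest = pd.DataFrame(
            {
                "probe_id": [f"cg{i}" for i in range(n_probes)],
                "chrom": "chr1",
                "pos": rng.integers(1, 2_100_000, n_probes),
            }
        )
        ann = annotate_probes(manifest, models)
        for row in manifest.sample(60, random_state=1).itertuples():
            ctx, gene, d = annotate_genic_context(row.pos, "chr1", models)
            got = ann.loc[row.probe_id]
            assert got["genic_context"] == ctx
            assert got["nearest_gene"] == gene
            assert got["tss_distance"] == d


class TestCgiContext:
    CGI = [GenomicInterval("chr1", 10_000, 11_000)]

    @pytest.mark.parametrize(
        "pos,expected",
        [
            (10_500, "island"),
            (10_001, "island"),  # 1-based first base of the island
            (12_500, "shore"),  # 1500 bp beyond the edge
            (13_000, "shore"),  # exactly 2000 bp
            (13_001, "ocean"),
            (60_000, "ocean"),
        ],
    )
    def test_island_shore_ocean(self, pos, expected):
        assert annotate_cgi_context(pos, "chr1", self.CGI) == expected

    def test_matches_distance_oracle_on_random_positions(self, rng):
        starts = np.sort(rng.choice(np.arange(0, 500_000, 100), 50, replace=False))
        cgi = [GenomicInterval("chr1", int(s), int(s) + int(rng.integers(200, 2000)))
               for s in starts]
        for pos in rng.integers(1, 520_000, 1000):
            pos = int(pos)
            p0 = pos - 1
            inside = any(iv.start <= p0 < iv.end for iv in cgi)
            dist = min(
                min(abs(iv.start - p0), abs(p0 - (iv.end - 1))) for iv in cgi
            )
            expected = "island" if inside else ("shore" if dist <= 2000 else "ocean")
            assert annotate_cgi_context(pos, "chr1", cgi) == expected


class TestCpGDensity:
    def test_direct_counting(self):
        oe, gc, sax, web = compute_cpg_density("CCGGCCGG")
        assert oe == pytest.approx(1.0)
        assert gc == pytest.approx(1.0)
        assert sax == "HCG"

    def test_no_c_gives_zero_oe(self):
        oe, gc, *_ = compute_cpg_density("GGGGAAAA")
        assert oe == 0.0
        assert gc == pytest.approx(0.5)

    def test_at_only(self):
        oe, gc, sax, web = compute_cpg_density("ATATATAT")
        assert (oe, gc) == (0.0, 0.0)
        assert sax == "LCG"
        assert web == "LCP"

    def test_empty_sequence_error(self):
        with pytest.raises(ValueError):
            compute_cpg_density("A")

    def test_oe_invariant_under_reverse_complement(self, rng):
        comp = str.maketrans("ACGT", "TGCA")
        for _ in range(25):
            seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(10, 200))))
            rc = seq.translate(comp)[::-1]
            assert compute_cpg_density(seq)[0] == pytest.approx(
                compute_cpg_density(rc)[0], abs=1e-12
            )


class TestOverlap:
    def test_coordinate_conversion(self):
        peak = [GenomicInterval("chr1", 100, 200)]
        assert annotate_overlap(101, "chr1", peak)  # 1-based 101 = 0-based 100
        assert not annotate_overlap(101, "chr1", [GenomicInterval("chr1", 101, 200)])
        assert annotate_overlap(200, "chr1", peak)  # 0-based 199 inside
        assert not annotate_overlap(201, "chr1", peak)  # 0-based 200 excluded

    def test_empty_peaks(self):
        assert not annotate_overlap(100, "chr1", [])


class TestVarianceByContext:
    def _ann(self, index, contexts):
        return pd.DataFrame({"genic_context": contexts}, index=index)

    def test_constant_probe_sd_zero_and_hand_value(self):
        beta = pd.DataFrame(
            [[0.5, 0.5], [0.0, 1.0]], index=["p1", "p2"], columns=["a", "b"]
        )
        ann = self._ann(["p1", "p2"], ["promoter", "distal"])
        out = variance_by_context(beta, ann, ["genic_context"])
        assert out.loc["p1", "sd"] == 0.0
        assert out.loc["p2", "sd"] == pytest.approx(0.7071, abs=1e-4)

    def test_group_medians_ordered_by_planted_variance(self, rng):
        n = 200
        high = rng.normal(0.5, 0.2, (n, 20))
        low = rng.normal(0.5, 0.02, (n, 20))
        beta = pd.DataFrame(
            np.clip(np.vstack([high, low]), 0, 1),
            index=[f"p{i}" for i in range(2 * n)],
        )
        ann = self._ann(beta.index, ["distal"] * n + ["promoter"] * n)
        out = variance_by_context(beta, ann, ["genic_context"])
        med = out.groupby("genic_context")["sd"].median()
        assert med["distal"] > med["promoter"]

    def test_missing_context_key_errors(self):
        beta = pd.DataFrame([[0.1, 0.2]], index=["p1"], columns=["a", "b"])
        with pytest.raises(KeyError):
            variance_by_context(beta, self._ann(["p1"], ["x"]), ["cgi_context"])


class TestTfbsEnrichment:
    def _annotations(self, overlap_probes, all_probes, tf="TFX"):
        return pd.DataFrame(
            {"tf_set": [{tf} if p in overlap_probes else set() for p in all_probes]},
            index=all_probes,
        )

    def test_p_matches_hypergeometric_tail(self):
        probes = [f"p{i}" for i in range(100)]
        overlap = set(probes[:20])
        cluster = probes[:8] + probes[50:52]  # 8 of 10 overlap
        ann = self._annotations(overlap, probes)
        result = tfbs_enrichment(cluster, probes, ann)
        expected = stats.hypergeom.sf(7, 100, 20, 10)
        assert result.loc["TFX", "p"] == pytest.approx(expected, abs=1e-10)

    def test_random_tables_match_hypergeom(self, rng):
        for _ in range(20):
            n_bg = int(rng.integers(20, 200))
            probes = [f"p{i}" for i in range(n_bg)]
            k_tf = int(rng.integers(1, n_bg))
            n_cl = int(rng.integers(1, n_bg))
            overlap = set(rng.choice(probes, k_tf, replace=False))
            cluster = list(rng.choice(probes, n_cl, replace=False))
            ann = self._annotations(overlap, probes)
            result = tfbs_enrichment(cluster, probes, ann)
            a = len(set(cluster) & overlap)
            expected = stats.hypergeom.sf(a - 1, n_bg, k_tf, n_cl)
            assert result.loc["TFX", "p"] == pytest.approx(expected, abs=1e-10)

    def test_saturated_tf_p_one(self):
        probes = [f"p{i}" for i in range(30)]
        ann = self._annotations(set(probes), probes)
        result = tfbs_enrichment(probes[:5], probes, ann)
        assert result.loc["TFX", "p"] == pytest.approx(1.0)

    def test_cluster_equals_background_p_one(self):
        probes = [f"p{i}" for i in range(30)]
        ann = self._annotations(set(probes[:10]), probes)
        result = tfbs_enrichment(probes, probes, ann)
        assert (result["p"] == 1.0).all()

    def test_empty_cluster_errors(self):
        with pytest.raises(ValueError):
            tfbs_enrichment([], ["p1"], self._annotations(set(), ["p1"]))


def test_context_partition_covers_all_probes(small_cohort, small_models):
    """Every probe gets exactly one genic and one CGI context."""
    ann = annotate_probes(
        small_cohort.manifest, small_models,
        cgi=small_cohort.cgi, atac=small_cohort.atac,
    )
    genic_counts = ann["genic_context"].value_counts()
    cgi_counts = ann["cgi_context"].value_counts()
    assert genic_counts.sum() == len(ann)
    assert cgi_counts.sum() == len(ann)
    assert set(genic_counts.index) <= {"promoter", "proximal", "distal"}
    assert set(cgi_counts.index) <= {"island", "shore", "ocean"}
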