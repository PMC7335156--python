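import numpy as np
import pandas as pd
import pytest

from seedmeth import annotate
from seedmeth.annotate import (associate_dmrs, classify_te_methylation,
                               feature_regions, gene_te_overlaps,
                               methylation_by_te_status, te_counts_per_gene,
                               te_frequency_contrast)
from seedmeth.io import GenomicFeature


def gene(gid, chrom, start, end, strand="+"):
    return GenomicFeature(gid, "gene", chrom, start, end, strand)


def te(tid, chrom, start, end):
    return GenomicFeature(tid, "TE", chrom, start, end, ".",
                          te_class="LTR")


def dmr_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "context",
                                       "direction"])


class TestFeatureRegions:
    def test_plus_strand_with_clipping(self):
        regions = feature_regions(gene("g", "c", 1000, 2000), flank=2000)
        assert regions["upstream"] == (0, 1000)
        assert regions["body"] == (1000, 2000)
        assert regions["downstream"] == (2000, 4000)

    def test_minus_strand_mirrored(self):
        regions = feature_regions(gene("g", "c", 5000, 6000, "-"))
        assert regions["upstream"] == (6000, 8000)
        assert regions["downstream"] == (3000, 5000)

    def test_unstranded_te_oriented_like_plus(self):
        regions = feature_regions(te("t", "c", 5000, 6000))
        assert regions["upstream"] == (3000, 5000)

    def test_chromosome_end_clipping(self):
        regions = feature_regions(gene("g", "c", 1000, 2000),
                                  chrom_length=2500)
        assert regions["downstream"] == (2000, 2500)


class TestAssociateDmrs:
    def test_boundary_spanning_dmr_in_both_regions(self):
        feats = [gene("g1", "c", 1000, 2000)]
        dmrs = dmr_frame([("c", 1900, 2100, "CG", "hyper")])
        out = associate_dmrs(dmrs, feats)
        assert sorted(out["region"]) == ["body", "downstream"]

    def test_distant_dmr_unassigned(self):
        feats = [gene("g1", "c", 10000, 12000)]
        out = associate_dmrs(dmr_frame([("c", 0, 50, "CG", "hyper")]), feats)
        assert out.empty

    def test_abutting_half_open_no_body_overlap(self):
        feats = [gene("g1", "c", 1000, 2000)]
        out = associate_dmrs(dmr_frame([("c", 2000, 2100, "CG", "hyper")]),
                             feats)
        assert list(out["region"]) == ["downstream"]

    def test_brute_force_oracle_random_fixture(self, rng):
        """All-pairs interval intersection oracle over random DMRs and
        features on two chromosomes."""
        feats = []
        for i in range(120):
            chrom = f"c{rng.integers(1, 3)}"
            start = int(rng.integers(0, 50_000))
            length = int(rng.integers(50, 3000))
            strand = "+" if rng.random() < 0.5 else "-"
            feats.append(gene(f"g{i}", chrom, start, start + length, strand))
        dmrs = dmr_frame([
            (f"c{rng.integers(1, 3)}", s := int(rng.integers(0, 55_000)),
             s + int(rng.integers(50, 500)), "CG", "hyper")
            for _ in range(150)])
        got = associate_dmrs(dmrs, feats, flank=2000)
        got_set = set(zip(got["dmr_index"], got["feature_id"],
                          got["region"]))
        expected = set()
        for di, d in dmrs.iterrows():
            for f in feats:
                if f.chrom != d["chrom"]:
                    continue
                for region, (a, b) in feature_regions(f, 2000).items():
                    if d["start"] < b and a < d["end"]:
                        expected.add((di, f.id, region))
        assert got_set == expected


class TestTeMethylationStatus:
    def mc_table(self, positions, context="CG"):
        return pd.DataFrame({"chrom": "c", "pos": positions,
                             "context": context,
                             "called": True})

    def test_density_threshold_boundary(self):
        calls = classify_te_methylation([te("t", "c", 0, 300)],
                                        self.mc_table([10, 20, 30]))
        cg = calls[calls["context"] == "CG"].iloc[0]
        assert cg["density_per_100bp"] == pytest.approx(1.0)
        assert cg["status"] == "methylated"

    def test_zero_mcs_nonmethylated(self):
        calls = classify_te_methylation([te("t", "c", 0, 300)],
                                        self.mc_table([]))
        assert (calls["status"] == "non-methylated").all()

    def test_intermediate_class(self):
        calls = classify_te_methylation([te("t", "c", 0, 300)],
                                        self.mc_table([10, 20]))
        cg = calls[calls["context"] == "CG"].iloc[0]
        assert cg["status"] == "intermediate"

    def test_intermediate_collapse_mode(self):
        calls = classify_te_methylation([te("t", "c", 0, 300)],
                                        self.mc_table([10, 20]),
                                        collapse_intermediate=True)
        cg = calls[calls["context"] == "CG"].iloc[0]
        assert cg["status"] == "non-methylated"

    def test_scale_covariance(self):
        """Doubling TE length with doubled mC count preserves status."""
        single = classify_te_methylation(
            [te("t", "c", 0, 200)], self.mc_table([10, 20]))
        double = classify_te_methylation(
            [te("t", "c", 0, 400)], self.mc_table([10, 20, 210, 220]))
        assert list(single["status"]) == list(double["status"])


class TestTeFrequency:
    def test_identical_counts_p_one(self):
        c = pd.Series([2, 2, 2, 2])
        assert te_frequency_contrast(c, c.copy())["p_value"] == 1.0

    def test_extreme_separation_significant(self):
        a = pd.Series(np.full(20, 5))
        b = pd.Series(np.zeros(20, dtype=int))
        assert te_frequency_contrast(a, b)["p_value"] < 1e-6

    def test_paired_signed_rank_mode(self):
        a = pd.Series([3, 4, 5, 6, 7, 8, 9, 10])
        b = pd.Series([1, 2, 3, 4, 5, 6, 7, 8])
        res = te_frequency_contrast(a, b, paired=True)
        assert res["p_value"] < 0.05

    def test_empty_set_reported_missing(self):
        res = te_frequency_contrast(pd.Series(dtype=int),
                                    pd.Series([1, 2]))
        assert np.isnan(res["p_value"])

    def test_count_conservation(self):
        genes = [gene("g1", "c", 10_000, 12_000),
                 gene("g2", "c", 20_000, 21_000)]
        tes = [te("t1", "c", 10_500, 10_700), te("t2", "c", 11_900, 12_100),
               te("t3", "c", 19_000, 19_100), te("t4", "c", 50_000, 50_200)]
        total = sum(te_counts_per_gene(genes, tes, region).sum()
                    for region in annotate.REGIONS)
        pairs = gene_te_overlaps(genes, tes)
        assert total == len(pairs)


class TestExpressionByTeStatus:
    def test_groups_partition_te_harbouring_genes(self):
        genes = [gene("g1", "c", 10_000, 12_000),
                 gene("g2", "c", 20_000, 22_000),
                 gene("g3", "c", 40_000, 42_000)]
        tes = [te("t1", "c", 10_500, 10_800),
               te("t2", "c", 20_500, 20_800)]
        overlaps = gene_te_overlaps(genes, tes)
        te_calls = pd.DataFrame([
            {"te_id": "t1", "context": "CHH", "status": "methylated"},
            {"te_id": "t2", "context": "CHH", "status": "non-methylated"},
        ])
        expr = pd.DataFrame({"gene_id": ["g1", "g2", "g3"],
                             "S1": [1.0, 50.0, 8.0]})
        summ = methylation_by_te_status(expr, "S1", te_calls, overlaps,
                                        "CHH", "body")
        by = summ.set_index("te_status")
        assert by.loc["methylated", "n_genes"] == 1
        assert by.loc["non-methylated", "n_genes"] == 1
        assert (by.loc["methylated", "fpkm_median"]
                < by.loc["non-methylated", "fpkm_median"])

    def test_no_te_harbouring_genes(self):
        summ = methylation_by_te_status(
            pd.DataFrame({"gene_id": ["g1"], "S1": [1.0]}), "S1",
            pd.DataFrame(columns=["te_id", "context", "status"]),
            pd.DataFrame(columns=["gene_id", "region", "te_id"]),
            "CG", "body")
        assert (summ["n_genes"] == 0).all()
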