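import numpy as np
import pandas as pd
import pytest
from scipy import stats

from seedmeth import simulate
from seedmeth.simulate import (ConfigError, MethylationLandscape,
                               PlantedDMR, SimulationConfig,
                               generate_genome, methylome_truth, plant_dmrs,
                               simulate_expression, simulate_methylome,
                               simulate_smallrna)


def tiny_config(**kw):
    defaults = dict(seed=7, n_chromosomes=1, chromosome_length=60_000,
                    chloroplast_length=8_000, n_genes=6, n_tes=4,
                    stages=("S1", "S2"), depth_mean=8)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestGenerateGenome:
    def test_empty_feature_case(self):
        cfg = tiny_config(n_genes=0, n_tes=0)
        genome, feats = generate_genome(cfg)
        assert feats == []
        assert set(genome.chromosomes) == {"Ca1", "CaCp"}

    def test_fully_intragenic_tes_contained(self):
        cfg = tiny_config(fraction_intragenic_tes=1.0, n_genes=8, n_tes=6,
                          gene_length_range=(3000, 5000),
                          te_length_range=(200, 800),
                          chromosome_length=100_000)
        _, feats = generate_genome(cfg)
        genes = [f for f in feats if f.ftype == "gene"]
        tes = [f for f in feats if f.ftype == "TE"]
        assert len(tes) == 6
        for t in tes:
            assert any(g.chrom == t.chrom and g.start <= t.start
                       and t.end <= g.end for g in genes)

    def test_same_seed_identical(self):
        g1, f1 = generate_genome(tiny_config())
        g2, f2 = generate_genome(tiny_config())
        assert g1.chromosomes == g2.chromosomes
        assert f1 == f2

    def test_features_do_not_overlap_except_intragenic(self):
        cfg = tiny_config(fraction_intragenic_tes=0.0, n_genes=10, n_tes=8,
                          chromosome_length=120_000)
        _, feats = generate_genome(cfg)
        ivals = sorted((f.chrom, f.start, f.end) for f in feats)
        for (c1, s1, e1), (c2, s2, e2) in zip(ivals, ivals[1:]):
            assert c1 != c2 or s2 >= e1

    def test_infeasible_packing_rejected(self):
        cfg = tiny_config(chromosome_length=5_000, n_genes=50,
                          gene_length_range=(1000, 1000))
        with pytest.raises(ConfigError):
            generate_genome(cfg)

    def test_config_validation(self):
        with pytest.raises(ConfigError):
            tiny_config(conversion_error=0.2).validate()
        with pytest.raises(ConfigError):
            tiny_config(depth_mean=0).validate()


class TestMethylomeTruth:
    def test_chloroplast_unmethylated(self, small_world):
        cp = small_world["truth"]["CaCp"]
        assert (cp["m_base"] == 0).all()

    def test_truth_independent_of_stage_and_replicate(self, small_world):
        cfg = small_world["config"]
        land = small_world["landscape"]
        genome = small_world["genome"]
        t2, _ = methylome_truth(genome, small_world["features"], land, cfg)
        pd.testing.assert_frame_equal(small_world["truth"]["Ca1"],
                                      t2["Ca1"])

    def test_planted_dmr_levels_override(self):
        cfg = tiny_config()
        genome, feats = generate_genome(cfg)
        dmr = PlantedDMR("Ca1", 10_000, 10_300, "CG", 0.1, 0.9)
        land = MethylationLandscape(planted_dmrs=[dmr])
        truth, _ = methylome_truth(genome, feats, land, cfg)
        for group, want in (("A", 0.1), ("B", 0.9)):
            m = simulate.true_levels(truth, land, cfg, "S1", group)["Ca1"]
            t = truth["Ca1"]
            sel = ((t["pos"] >= 10_000) & (t["pos"] < 10_300)
                   & (t["context"] == "CG"))
            assert sel.sum() > 0
            assert (m[sel.to_numpy()] == want).all()

    def test_stage_gain_raises_te_chh(self):
        cfg = tiny_config(n_tes=4, fraction_intragenic_tes=0.0)
        genome, feats = generate_genome(cfg)
        land = MethylationLandscape(stage_te_chh_gain={"S1": 0.0,
                                                       "S2": 0.1})
        truth, _ = methylome_truth(genome, feats, land, cfg)
        m1 = simulate.true_levels(truth, land, cfg, "S1")["Ca1"]
        m2 = simulate.true_levels(truth, land, cfg, "S2")["Ca1"]
        t = truth["Ca1"]
        te_chh = (t["stratum"] == 2) & (t["context"] == "CHH") & t["is_meth"]
        np.testing.assert_allclose(
            m2[te_chh.to_numpy()] - m1[te_chh.to_numpy()], 0.1)
        others = ~te_chh.to_numpy()
        assert (m1[others] == m2[others]).all()

    def test_planted_dmrs_must_not_overlap(self):
        with pytest.raises(ConfigError):
            MethylationLandscape(planted_dmrs=[
                PlantedDMR("c", 0, 300, "CG", 0.1, 0.9),
                PlantedDMR("c", 200, 500, "CG", 0.1, 0.9)]).validate()

    def test_plant_dmrs_respects_avoid_list(self):
        cfg = tiny_config(chromosome_length=200_000)
        avoid = [("Ca1", 0, 100_000)]
        dmrs = plant_dmrs({"Ca1": 200_000, "CaCp": 8_000}, cfg, n_dmrs=10,
                          avoid=avoid)
        assert all(d.start >= 100_000 for d in dmrs)
        assert len({(d.start // 1) for d in dmrs}) == 10


class TestSimulateMethylome:
    def test_degenerate_full_methylation_no_error(self):
        cfg = tiny_config(conversion_error=0.0)
        genome, feats = generate_genome(cfg)
        land = MethylationLandscape(
            base_level={c: {s: 1.0 for s in simulate.STRATA}
                        for c in ("CG", "CHG", "CHH")},
            site_fraction={c: {s: 1.0 for s in simulate.STRATA}
                           for c in ("CG", "CHG", "CHH")},
            gene_cg_fraction_concentration=1e9)
        truth, _ = methylome_truth(genome, feats, land, cfg)
        sample = simulate_methylome(genome, truth, land, cfg, "S1")
        nuclear = sample[sample["chrom"] == "Ca1"]
        covered = nuclear[(nuclear["n_meth"] + nuclear["n_unmeth"]) > 0]
        # per-gene Beta fractions degenerate at ~1, so every covered
        # nuclear site is fully methylated
        assert (covered["n_unmeth"] == 0).all()

    def test_degenerate_zero_methylation_no_error(self):
        cfg = tiny_config(conversion_error=0.0)
        genome, feats = generate_genome(cfg)
        land = MethylationLandscape(
            site_fraction={c: {s: 0.0 for s in simulate.STRATA}
                           for c in ("CG", "CHG", "CHH")},
            gene_cg_fraction_concentration=1e9)
        truth, _ = methylome_truth(genome, feats, land, cfg)
        sample = simulate_methylome(genome, truth, land, cfg, "S1")
        assert (sample["n_meth"] == 0).all()

    def test_zero_coverage_sites_kept(self, small_world):
        sample = small_world["sample"]
        cov = sample["n_meth"] + sample["n_unmeth"]
        assert (cov == 0).any()

    def test_observed_level_converges_to_model(self, small_world):
        """Law of large numbers: mean observed methylation at simulated
        chloroplast sites is eps within 3 SEs (m = 0 there)."""
        cfg = small_world["config"]
        cp = small_world["sample"]
        cp = cp[cp["chrom"] == "CaCp"]
        n = (cp["n_meth"] + cp["n_unmeth"]).sum()
        rate = cp["n_meth"].sum() / n
        eps = cfg.conversion_error
        se = np.sqrt(eps * (1 - eps) / n)
        assert abs(rate - eps) <= 3 * se

    def test_same_seed_identical_sample(self, small_world):
        cfg = small_world["config"]
        s2 = simulate_methylome(small_world["genome"],
                                small_world["truth"],
                                small_world["landscape"], cfg, "S1")
        pd.testing.assert_frame_equal(small_world["sample"], s2)

    def test_unknown_stage_rejected(self, small_world):
        with pytest.raises(ConfigError):
            simulate_methylome(small_world["genome"], small_world["truth"],
                               small_world["landscape"],
                               small_world["config"], "S9")


class TestSimulateExpression:
    def make_gene_truth(self, n, rng):
        return pd.DataFrame({
            "gene_id": [f"g{i:04d}" for i in range(n)],
            "body_cg_level": rng.uniform(0, 100, size=n),
            "n_body_cg_sites": 100,
        })

    def test_zero_coupling_null_spearman(self, rng):
        truth = self.make_gene_truth(1500, rng)
        cfg = tiny_config()
        expr, _ = simulate_expression(truth, cfg, coupling=0.0)
        rho = stats.spearmanr(truth["body_cg_level"], expr["S1"]).statistic
        assert abs(rho) < 0.05

    def test_positive_coupling_induces_rank_correlation(self, rng):
        truth = self.make_gene_truth(1500, rng)
        cfg = tiny_config()
        expr, _ = simulate_expression(truth, cfg, coupling=0.8)
        rho = stats.spearmanr(truth["body_cg_level"], expr["S1"]).statistic
        assert rho > 0.5

    def test_planted_deg_bookkeeping(self, rng):
        truth = self.make_gene_truth(300, rng)
        cfg = tiny_config()
        _, de = simulate_expression(truth, cfg, n_up=50, n_down=30)
        sig = de["qvalue"] <= 0.05
        up = sig & (de["log2fc"] >= 1)
        down = sig & (de["log2fc"] <= -1)
        assert up.sum() == 50 and down.sum() == 30
        assert list(de.loc[up, "planted"].unique()) == ["up"]

    def test_same_seed_identical_tables(self, rng):
        truth = self.make_gene_truth(100, rng)
        cfg = tiny_config()
        e1, d1 = simulate_expression(truth, cfg)
        e2, d2 = simulate_expression(truth, cfg)
        pd.testing.assert_frame_equal(e1, e2)
        pd.testing.assert_frame_equal(d1, d2)


class TestSimulateSmallRNA:
    def make_tes(self):
        return [simulate.GenomicFeature(f"t{i}", "TE", "Ca1",
                                        i * 5000, i * 5000 + 1000, ".",
                                        te_class="LTR")
               for i in range(10)]

    def test_zero_background_all_middles_in_hyper_bodies(self):
        tes = self.make_tes()
        hyper = tes[:3]
        cfg = tiny_config()
        reads = simulate_smallrna({"Ca1": 100_000}, tes, hyper, cfg,
                                  lambda_bg=0.0, lambda_hyper=0.02)
        assert len(reads) > 0
        mids = reads["start"] + (reads["end"] - reads["start"] - 1) // 2
        in_hyper = np.zeros(len(reads), dtype=bool)
        for t in hyper:
            in_hyper |= (mids >= t.start) & (mids < t.end)
        assert in_hyper.all()

    def test_hyper_excess_lands_in_hyper_bodies(self):
        tes = self.make_tes()
        hyper = tes[:3]
        cfg = tiny_config()
        reads = simulate_smallrna({"Ca1": 100_000}, tes, hyper, cfg,
                                  lambda_bg=0.01, density_ratio=50.0)
        mids = reads["start"] + (reads["end"] - reads["start"] - 1) // 2
        in_hyper = np.zeros(len(reads), dtype=bool)
        for t in hyper:
            in_hyper |= (mids >= t.start) & (mids < t.end)
        assert in_hyper.mean() > 0.5

    def test_length_classes_and_determinism(self):
        tes = self.make_tes()
        cfg = tiny_config()
        r1 = simulate_smallrna({"Ca1": 100_000}, tes, tes[:3], cfg,
                               lambda_bg=0.01)
        r2 = simulate_smallrna({"Ca1": 100_000}, tes, tes[:3], cfg,
                               lambda_bg=0.01)
        pd.testing.assert_frame_equal(r1, r2)
        assert set(r1["length"]) <= {21, 24}
        assert (r1["end"] - r1["start"] == r1["length"]).all()
        frac24 = (r1["length"] == 24).mean()
        assert 0.6 < frac24 < 0.95
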