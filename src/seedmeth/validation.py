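"""Self-contained validation studies on synthetic data.

Each function builds a synthetic scenario with known truth, runs the
corresponding analysis stage, and returns the measured operating
characteristics (error-rate recovery, null calibration, DMR
sensitivity and false-call rate, metagene and decile recovery,
small-RNA test power and size).  The problem sizes are chosen so every
study completes in seconds to a few minutes on one CPU while leaving
enough events for stable estimates; they are the package's reference
conditions and are reused by the test suite and by
``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import calling, dmr, metagene, simulate, smallrna
from .io import GenomicFeature


def _seeded(base_seed: int, offset: int) -> int:
    return (int(base_seed) * 1000 + offset) % (2 ** 31)


# ---------------------------------------------------------------------------
# conversion error
# ---------------------------------------------------------------------------

def conversion_error_recovery(seed: int = 1, eps: float = 0.006,
                              chloroplast_length: int = 250_000) -> dict:
    """Estimate the planted non-conversion rate from a simulated
    chloroplast with >= 1e5 covered cytosines."""
    cfg = simulate.SimulationConfig(
        seed=_seeded(seed, 1), n_chromosomes=1, chromosome_length=1000,
        chloroplast_length=chloroplast_length, n_genes=0, n_tes=0,
        depth_mean=10.0, conversion_error=eps, stages=("S1",))
    genome, feats = simulate.generate_genome(cfg)
    land = simulate.MethylationLandscape()
    truth, _ = simulate.methylome_truth(genome, feats, land, cfg)
    sample = simulate.simulate_methylome(genome, truth, land, cfg, "S1")
    cp = sample[sample["chrom"] == cfg.chloroplast_name]
    covered = cp[(cp["n_meth"] + cp["n_unmeth"]) > 0]
    estimate = calling.estimate_conversion_error(cp)
    n_reads = int((cp["n_meth"] + cp["n_unmeth"]).sum())
    se = float(np.sqrt(eps * (1 - eps) / n_reads))
    return {"planted": eps, "estimate": estimate, "n_sites": len(covered),
            "n_reads": n_reads, "se": se,
            "abs_error": abs(estimate - eps)}


# ---------------------------------------------------------------------------
# DMR null calibration and recovery
# ---------------------------------------------------------------------------

def _two_group_samples(cfg, genome, truth, land, n_replicates=2):
    a = [simulate.simulate_methylome(genome, truth, land, cfg, "S1", "A", r)
         for r in range(n_replicates)]
    b = [simulate.simulate_methylome(genome, truth, land, cfg, "S2", "B", r)
         for r in range(n_replicates)]
    return a, b


def null_window_calibration(seed: int = 1,
                            chromosome_length: int = 600_000,
                            depth: float = 20.0) -> dict:
    """Two groups drawn from one landscape (no planted differences):
    fraction of testable CG windows passing every DMR filter."""
    cfg = simulate.SimulationConfig(
        seed=_seeded(seed, 2), n_chromosomes=1,
        chromosome_length=chromosome_length, chloroplast_length=1000,
        n_genes=0, n_tes=0, depth_mean=depth, stages=("S1", "S2"))
    genome, feats = simulate.generate_genome(cfg)
    land = simulate.MethylationLandscape()
    truth, _ = simulate.methylome_truth(genome, feats, land, cfg)
    a, b = _two_group_samples(cfg, genome, truth, land)
    lengths = {"Ca1": chromosome_length}
    win = dmr.aggregate_windows(a, b, "CG", lengths)
    win = win[win["n_cytosines"] >= 3].reset_index(drop=True)
    win["p_value"] = dmr.gtest_pvalues(win["M_A"], win["N_A"],
                                       win["M_B"], win["N_B"])
    win["q_value"] = dmr.slim_qvalues(win["p_value"].to_numpy())
    passing = ((win["diff"].abs() >= 25) & (win["q_value"] <= 0.01))
    return {"n_windows": len(win), "n_passing": int(passing.sum()),
            "fraction_passing": float(passing.mean()) if len(win) else 0.0}


def dmr_recovery(seed: int = 1, n_dmrs: int = 40, width: int = 300,
                 level_a: float = 0.2, level_b: float = 0.7,
                 chromosome_length: int = 400_000,
                 depth: float = 20.0) -> dict:
    """Sensitivity and false-call rate for planted CG DMRs with a
    >= 30-point level difference."""
    cfg = simulate.SimulationConfig(
        seed=_seeded(seed, 3), n_chromosomes=1,
        chromosome_length=chromosome_length, chloroplast_length=1000,
        n_genes=0, n_tes=0, depth_mean=depth, stages=("S1", "S2"))
    genome, feats = simulate.generate_genome(cfg)
    planted = simulate.plant_dmrs({"Ca1": chromosome_length}, cfg,
                                  n_dmrs=n_dmrs, width=width,
                                  level_a=level_a, level_b=level_b)
    land = simulate.MethylationLandscape(planted_dmrs=planted)
    truth, _ = simulate.methylome_truth(genome, feats, land, cfg)
    a, b = _two_group_samples(cfg, genome, truth, land)
    _, called = dmr.call_dmrs(a, b, {"Ca1": chromosome_length},
                              contexts=("CG",))
    truth_tab = simulate.dmr_truth_table(land)
    hit = 0
    for _, t in truth_tab.iterrows():
        ov = called[(called["chrom"] == t["chrom"])
                    & (called["start"] < t["end"])
                    & (called["end"] > t["start"])
                    & (called["direction"] == t["direction"])]
        hit += int(len(ov) > 0)
    false_calls = 0
    for _, c in called.iterrows():
        ov = truth_tab[(truth_tab["chrom"] == c["chrom"])
                       & (truth_tab["start"] < c["end"])
                       & (truth_tab["end"] > c["start"])]
        false_calls += int(len(ov) == 0)
    return {
        "n_planted": len(truth_tab), "n_called": len(called),
        "n_recovered": hit,
        "sensitivity": hit / len(truth_tab) if len(truth_tab) else np.nan,
        "n_false": false_calls,
        "false_rate": false_calls / len(called) if len(called) else 0.0,
    }


# ---------------------------------------------------------------------------
# metagene recovery
# ---------------------------------------------------------------------------

def _uniform_landscape(body_cg: float, flank_cg: float,
                       te_chh: float, gains: dict) -> \
        simulate.MethylationLandscape:
    base = {
        "CG": {"background": flank_cg, "gene_body": body_cg,
               "te_body": flank_cg},
        "CHG": {s: 0.5 for s in simulate.STRATA},
        "CHH": {"background": 0.05, "gene_body": 0.05, "te_body": te_chh},
    }
    frac = {
        "CG": {s: 1.0 for s in simulate.STRATA},
        "CHG": {s: 0.4 for s in simulate.STRATA},
        "CHH": {"background": 0.08, "gene_body": 0.08, "te_body": 1.0},
    }
    return simulate.MethylationLandscape(
        base_level=base, site_fraction=frac, stage_te_chh_gain=gains,
        gene_cg_fraction_concentration=1e9)


def metagene_recovery(seed: int = 1, body_cg: float = 0.90,
                      flank_cg: float = 0.60, te_chh: float = 0.40,
                      gain_per_stage: float = 0.05,
                      depth: float = 20.0) -> dict:
    """Piecewise-constant landscape (gene-body CG 0.90, flanks 0.60;
    TE-body CHH gaining +0.05 per stage over three stages): per-bin
    recovery within 3 binomial SEs and the ordering of stage TE CHH
    body means."""
    stages = ("S1", "S2", "S3")
    gains = {s: gain_per_stage * i for i, s in enumerate(stages)}
    cfg = simulate.SimulationConfig(
        seed=_seeded(seed, 4), n_chromosomes=1, chromosome_length=700_000,
        chloroplast_length=1000, n_genes=60, n_tes=60,
        fraction_intragenic_tes=0.0, gene_length_range=(2000, 2000),
        te_length_range=(1000, 1000), min_feature_gap=4200,
        depth_mean=depth, stages=stages, conversion_error=0.006)
    genome, feats = simulate.generate_genome(cfg)
    land = _uniform_landscape(body_cg, flank_cg, te_chh, gains)
    truth, _ = simulate.methylome_truth(genome, feats, land, cfg)
    genes = [f for f in feats if f.ftype == "gene"]
    tes = [f for f in feats if f.ftype == "TE"]
    eps = cfg.conversion_error

    def observed_expected(sample, features, context, expected_by_region):
        prof = metagene.profile(sample, features, context,
                                chrom_lengths=genome.lengths)
        rows = []
        for _, r in prof.iterrows():
            m = expected_by_region[r["region"]]
            p = m + (1 - m) * eps
            p_exp = 100 * p
            se = 100 * np.sqrt(p * (1 - p) / max(r["coverage"], 1))
            rows.append({"bin_index": r["bin_index"],
                         "region": r["region"], "level": r["level"],
                         "expected": p_exp, "se": se,
                         "within_3se": bool(abs(r["level"] - p_exp)
                                            <= 3 * se + 1e-9)})
        return pd.DataFrame(rows)

    sample1 = simulate.simulate_methylome(genome, truth, land, cfg, "S1")
    gene_check = observed_expected(
        sample1, genes, "CG",
        {"upstream": flank_cg, "body": body_cg, "downstream": flank_cg})

    te_means = []
    te_checks = []
    for i, stage in enumerate(stages):
        sample = (sample1 if stage == "S1" else
                  simulate.simulate_methylome(genome, truth, land, cfg,
                                              stage))
        level = te_chh + gains[stage]
        check = observed_expected(
            sample, tes, "CHH",
            {"upstream": 0.05 * 0.08, "body": level,
             "downstream": 0.05 * 0.08})
        te_checks.append(check[check["region"] == "body"])
        body = check[check["region"] == "body"]
        te_means.append(float((body["level"]).mean()))
    return {
        "gene_bins_within_3se": int(gene_check["within_3se"].sum()),
        "gene_bins_total": len(gene_check),
        "te_body_bins_within_3se": int(sum(c["within_3se"].sum()
                                           for c in te_checks)),
        "te_body_bins_total": int(sum(len(c) for c in te_checks)),
        "te_chh_body_means_by_stage": te_means,
        "strictly_increasing": bool(np.all(np.diff(te_means) > 0)),
        "gene_body_mean": float(
            gene_check.loc[gene_check["region"] == "body", "level"].mean()),
        "gene_flank_mean": float(
            gene_check.loc[gene_check["region"] != "body", "level"].mean()),
    }


# ---------------------------------------------------------------------------
# expression decile coupling
# ---------------------------------------------------------------------------

def decile_coupling(seed: int = 1, coupling: float = 0.5,
                    n_genes: int = 600, depth: float = 20.0) -> dict:
    """Gene-body CG level by expression decile under a given coupling.

    Returns the pooled body-bin CG mean per requested decile plus
    between-gene 3-SE bands (mean +/- 3 * SEM over genes), which is the
    proper yardstick when gene-to-gene landscape variation dominates
    the binomial noise."""
    cfg = simulate.SimulationConfig(
        seed=_seeded(seed, 5), n_chromosomes=1,
        chromosome_length=1_800_000, chloroplast_length=1000,
        n_genes=n_genes, n_tes=0, gene_length_range=(2000, 2000),
        min_feature_gap=500, depth_mean=depth, stages=("S1",))
    genome, feats = simulate.generate_genome(cfg)
    land = simulate.MethylationLandscape()
    truth, gene_truth = simulate.methylome_truth(genome, feats, land, cfg)
    genes = [f for f in feats if f.ftype == "gene"]
    sample = simulate.simulate_methylome(genome, truth, land, cfg, "S1")
    expression, _ = simulate.simulate_expression(gene_truth, cfg,
                                                 coupling=coupling)
    deciles = metagene.expression_deciles(expression, "S1")
    body = metagene.feature_body_levels(sample, genes, "CG")
    body = body.rename(columns={"feature_id": "gene_id"})
    merged = deciles.merge(body, on="gene_id")
    out = {}
    for k in (2, 6, 10):
        grp = merged[merged["decile"] == k]["level"].dropna()
        mean = float(grp.mean())
        sem = float(grp.std(ddof=1) / np.sqrt(len(grp)))
        out[k] = {"mean": mean, "sem": sem, "n_genes": int(len(grp)),
                  "band": (mean - 3 * sem, mean + 3 * sem)}
    return {"coupling": coupling, "deciles": out,
            "ordered": out[2]["mean"] < out[6]["mean"] < out[10]["mean"],
            "bands_2_10_overlap": (out[2]["band"][1] >= out[10]["band"][0]
                                   and out[10]["band"][1]
                                   >= out[2]["band"][0])}


# ---------------------------------------------------------------------------
# small-RNA contrast power and size
# ---------------------------------------------------------------------------

def smallrna_rejection_rate(seed: int = 1, density_ratio: float = 5.0,
                            n_seeds: int = 50, n_tes: int = 60,
                            te_length: int = 500,
                            lambda_bg: float = 0.002,
                            alpha: float = 0.01) -> dict:
    """Fraction of simulations where Fisher's exact contrast between
    CHH-hyper TEs and the remaining TEs rejects at ``alpha``."""
    span = 1_000_000
    tes = [GenomicFeature(f"t{i}", "TE", "Ca1", 2000 + i * (span // n_tes),
                          2000 + i * (span // n_tes) + te_length, ".",
                          te_class="LTR")
           for i in range(n_tes)]
    hyper = tes[:n_tes // 4]
    other = tes[n_tes // 4:]
    rejections = 0
    total_reads = 0
    for k in range(n_seeds):
        cfg = simulate.SimulationConfig(
            seed=_seeded(seed, 6000 + 10 * k + int(density_ratio)),
            n_chromosomes=1, chromosome_length=span, stages=("S1",))
        reads = simulate.simulate_smallrna(
            {"Ca1": span + 5000}, tes, hyper, cfg, lambda_bg=lambda_bg,
            density_ratio=density_ratio)
        total_reads += len(reads)
        res = smallrna.contrast_density(hyper, other, reads, length=24)
        rejections += int(res["p_value"] < alpha)
    return {"density_ratio": density_ratio, "n_seeds": n_seeds,
            "mean_reads": total_reads / n_seeds,
            "rejection_rate": rejections / n_seeds}
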