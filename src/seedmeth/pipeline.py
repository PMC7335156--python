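"""Stage orchestration behind the ``seedmeth`` command-line interface.

Each ``run_*`` function reads its inputs (from a previous stage's
output directory or from paths named in the config), executes one stage
of the analysis, and writes TSV artifacts plus a manifest entry.  The
``all`` driver threads the in-memory objects through every stage so the
bundled synthetic study runs end to end without re-reading the large
per-cytosine tables from disk.  Reruns with the same config and seed
are byte-identical.
"""

from __future__ import annotations

import logging
import time
from contextlib import contextmanager
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, annotate, calling, dmr, integrate, io, metagene, \
    simulate, smallrna
from .config import PipelineConfig

log = logging.getLogger("seedmeth")

FLOAT_FMT = "%.6g"


@contextmanager
def _stage(name: str):
    t0 = time.perf_counter()
    log.info("stage %s: start", name)
    yield
    log.info("stage %s: done in %.1fs", name, time.perf_counter() - t0)


def _write(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def sample_name(stage: str, rep: int) -> str:
    return f"{stage}_rep{rep + 1}"


def _sim_config(cfg: PipelineConfig) -> simulate.SimulationConfig:
    s = cfg.simulate
    return simulate.SimulationConfig(
        seed=cfg.seed,
        n_chromosomes=s.n_chromosomes,
        chromosome_length=s.chromosome_length,
        chloroplast_length=s.chloroplast_length,
        depth_mean=s.depth_mean,
        conversion_error=s.conversion_error,
        n_genes=s.n_genes,
        n_tes=s.n_tes,
        fraction_intragenic_tes=s.fraction_intragenic_tes,
        stages=tuple(s.stages),
        n_replicates=s.n_replicates,
    )


def build_landscape(cfg: PipelineConfig, features) -> tuple[
        simulate.MethylationLandscape, list]:
    """Landscape with planted CG DMRs plus whole-body CHH DMRs on a
    random subset of TEs (the CHH-hypermethylated TE truth set)."""
    s = cfg.simulate
    sim_cfg = _sim_config(cfg)
    tes = [f for f in features if f.ftype == "TE"]
    rng = np.random.default_rng([cfg.seed % (2 ** 31), 7])
    n_hyper = int(round(s.fraction_hyper_tes * len(tes)))
    hyper_idx = sorted(rng.choice(len(tes), size=n_hyper, replace=False)) \
        if n_hyper else []
    hyper_tes = [tes[i] for i in hyper_idx]
    lo, hi = s.te_chh_dmr_levels
    chh_dmrs = [simulate.PlantedDMR(t.chrom, t.start, t.end, "CHH", lo, hi)
                for t in hyper_tes]
    avoid = [(t.chrom, t.start, t.end) for t in hyper_tes]
    la, lb = s.planted_dmr_levels
    cg_dmrs = simulate.plant_dmrs(
        {c: l for c, l in _chrom_lengths_of(features, cfg).items()},
        sim_cfg, n_dmrs=s.n_planted_dmrs, width=s.planted_dmr_width,
        context="CG", level_a=la, level_b=lb, avoid=avoid)
    landscape = simulate.MethylationLandscape(
        stage_te_chh_gain={stage: 0.05 * i
                           for i, stage in enumerate(s.stages)},
        planted_dmrs=cg_dmrs + chh_dmrs,
    )
    landscape.validate()
    return landscape, hyper_tes


def _chrom_lengths_of(features, cfg: PipelineConfig) -> dict[str, int]:
    s = cfg.simulate
    out = {f"Ca{i + 1}": s.chromosome_length
           for i in range(s.n_chromosomes)}
    out["CaCp"] = s.chloroplast_length
    return out


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def run_simulate(cfg: PipelineConfig, outdir: Path) -> dict:
    """Generate the synthetic study and write every input artifact."""
    s = cfg.simulate
    sim_cfg = _sim_config(cfg)
    with _stage("simulate"):
        genome, features = simulate.generate_genome(sim_cfg)
        landscape, hyper_tes = build_landscape(cfg, features)
        truth, gene_truth = simulate.methylome_truth(
            genome, features, landscape, sim_cfg)
        genes = [f for f in features if f.ftype == "gene"]
        tes = [f for f in features if f.ftype == "TE"]

        io.write_fasta(outdir / "genome.fa", genome.chromosomes)
        io.write_gff3_genes(outdir / "genes.gff3", genes)
        io.write_bed_tes(outdir / "tes.bed", tes)

        reports = {}
        for stage in s.stages:
            group = "B" if stage == cfg.group_b else "A"
            for rep in range(s.n_replicates):
                name = sample_name(stage, rep)
                table = simulate.simulate_methylome(
                    genome, truth, landscape, sim_cfg, stage, group, rep)
                path = outdir / "reports" / f"{name}.cx.tsv"
                path.parent.mkdir(parents=True, exist_ok=True)
                io.write_cytosine_report(path, table)
                reports.setdefault(stage, []).append(str(path))

        expression, de = simulate.simulate_expression(
            gene_truth, sim_cfg, coupling=s.expression_coupling,
            n_up=s.n_up_degs, n_down=s.n_down_degs)
        _write(expression, outdir / "expression.tsv")
        _write(de[["gene_id", "log2fc", "qvalue"]], outdir / "de_table.tsv")

        srna = simulate.simulate_smallrna(
            genome.lengths, tes, hyper_tes, sim_cfg,
            lambda_bg=s.smallrna_lambda_bg,
            density_ratio=s.smallrna_density_ratio,
            frac_24nt=s.smallrna_frac_24nt)
        io.write_smallrna_bed(outdir / "smallrna.bed", srna)

        tdir = outdir / "truth"
        _write(simulate.dmr_truth_table(landscape), tdir / "dmr_truth.tsv")
        _write(gene_truth, tdir / "gene_truth.tsv")
        _write(de.rename(columns={"planted": "status"})
               [["gene_id", "log2fc", "qvalue", "status"]],
               tdir / "deg_truth.tsv")
        _write(pd.DataFrame({"te_id": [t.id for t in hyper_tes]}),
               tdir / "hyper_te_truth.tsv")
        placements = pd.DataFrame([{
            "id": f.id, "ftype": f.ftype, "chrom": f.chrom,
            "start": f.start, "end": f.end, "strand": f.strand,
            "te_class": f.te_class} for f in features])
        _write(placements, tdir / "placements.tsv")
        if s.write_site_truth:
            for stage in s.stages:
                group = "B" if stage == cfg.group_b else "A"
                _write(simulate.site_truth_table(truth, landscape, sim_cfg,
                                                 stage, group),
                       tdir / f"site_truth_{stage}.tsv")

    manifest = {
        "genome": str(outdir / "genome.fa"),
        "genes_gff": str(outdir / "genes.gff3"),
        "tes_bed": str(outdir / "tes.bed"),
        "reports": reports,
        "expression": str(outdir / "expression.tsv"),
        "de_table": str(outdir / "de_table.tsv"),
        "smallrna": str(outdir / "smallrna.bed"),
        "chloroplast": "CaCp",
    }
    return manifest


def _inputs(cfg: PipelineConfig, outdir: Path) -> dict:
    """Input paths: explicit config entries win; otherwise use the
    layout written by ``run_simulate`` in outdir."""
    manifest_path = outdir / "manifest.yaml"
    base = {}
    if manifest_path.exists():
        with open(manifest_path) as fh:
            base = (yaml.safe_load(fh) or {}).get("inputs", {})
    base.update(cfg.inputs)
    missing = [k for k in ("genome", "genes_gff", "tes_bed", "reports")
               if k not in base]
    if missing:
        raise FileNotFoundError(
            f"missing inputs {missing}; run `seedmeth simulate` first or "
            "name them in the config")
    return base


def _load_common(cfg: PipelineConfig, outdir: Path):
    inputs = _inputs(cfg, outdir)
    chroms = io.read_fasta(inputs["genome"])
    genome = io.GenomeAssembly(chroms, inputs.get("chloroplast", "CaCp"))
    genes = io.read_gff3_genes(inputs["genes_gff"])
    tes = io.read_bed_tes(inputs["tes_bed"])
    return inputs, genome, genes, tes


def _load_samples(inputs: dict, stages) -> dict[str, list[pd.DataFrame]]:
    out = {}
    for stage in stages:
        out[stage] = [io.read_cytosine_table(p)
                      for p in inputs["reports"][stage]]
    return out


def run_call(cfg: PipelineConfig, outdir: Path, genome=None,
             samples=None) -> dict:
    """Estimate conversion error and call mCs for every sample."""
    inputs = _inputs(cfg, outdir)
    if genome is None:
        chroms = io.read_fasta(inputs["genome"])
        genome = io.GenomeAssembly(chroms, inputs.get("chloroplast", "CaCp"))
    if samples is None:
        samples = _load_samples(inputs, list(inputs["reports"]))
    p = cfg.params
    called: dict[str, list[pd.DataFrame]] = {}
    eps_rows, summaries = [], []
    with _stage("call"):
        for stage, reps in samples.items():
            called[stage] = []
            for rep, table in enumerate(reps):
                name = sample_name(stage, rep)
                cp = table[table["chrom"] == genome.chloroplast_name]
                eps = calling.estimate_conversion_error(cp)
                nuclear = table[table["chrom"] != genome.chloroplast_name]
                calls = calling.call_methylcytosines(
                    nuclear, eps, min_depth=p.min_depth, alpha=p.alpha)
                called[stage].append(calls)
                eps_rows.append({"sample": name, "conversion_error": eps})
                summ = calling.context_summary(calls, min_depth=p.min_depth)
                summ.insert(0, "sample", name)
                summaries.append(summ)
                mcs = calls[calls["called"]]
                _write(mcs[["chrom", "pos", "strand", "context", "n_meth",
                            "n_unmeth", "level", "p_value"]],
                       outdir / "calls" / f"{name}.mcs.tsv")
        _write(pd.DataFrame(eps_rows), outdir / "calls" /
               "conversion_error.tsv")
        _write(pd.concat(summaries, ignore_index=True),
               outdir / "calls" / "context_summary.tsv")
    return called


def run_dmr(cfg: PipelineConfig, outdir: Path, genome=None,
            samples=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sliding-window DMR detection between group_a and group_b."""
    inputs = _inputs(cfg, outdir)
    if genome is None:
        chroms = io.read_fasta(inputs["genome"])
        genome = io.GenomeAssembly(chroms, inputs.get("chloroplast", "CaCp"))
    if samples is None:
        samples = _load_samples(inputs, [cfg.group_a, cfg.group_b])
    p = cfg.params
    lengths = {c: l for c, l in genome.lengths.items()
               if c != genome.chloroplast_name}
    with _stage("dmr"):
        windows, dmrs = dmr.call_dmrs(
            samples[cfg.group_a], samples[cfg.group_b], lengths,
            size=p.window, step=p.step, min_site_depth=p.min_depth,
            min_cytosines=p.min_cytosines, min_diff=p.min_diff,
            max_q=p.max_q, merge_gap=p.merge_gap, pi0=p.pi0)
        _write(windows, outdir / "dmr" / "windows.tsv")
        _write(dmrs, outdir / "dmr" / "dmrs.tsv")
        bed = dmr.dmrs_to_bed(dmrs)
        bed.to_csv(outdir / "dmr" / "dmrs.bed", sep="\t", header=False,
                   index=False)
    return windows, dmrs


def run_annotate(cfg: PipelineConfig, outdir: Path, genome=None, genes=None,
                 tes=None, dmrs=None, called=None) -> dict:
    """DMR-gene/TE association, TE methylation status, TE frequency."""
    if genome is None or genes is None or tes is None:
        _, genome, genes, tes = _load_common(cfg, outdir)
    if dmrs is None:
        dmrs = pd.read_csv(outdir / "dmr" / "dmrs.tsv", sep="\t")
    if called is None:
        mcs_path = outdir / "calls" / \
            f"{sample_name(cfg.group_b, 0)}.mcs.tsv"
        mc_table = pd.read_csv(mcs_path, sep="\t")
        mc_table["called"] = True
    else:
        mc_table = called[cfg.group_b][0]
    p = cfg.params
    lengths = {c: l for c, l in genome.lengths.items()}
    with _stage("annotate"):
        assignments = annotate.associate_dmrs(dmrs, list(genes) + list(tes),
                                              flank=p.flank,
                                              chrom_lengths=lengths)
        _write(assignments, outdir / "annotate" / "assignments.tsv")
        te_calls = annotate.classify_te_methylation(tes, mc_table)
        _write(te_calls, outdir / "annotate" / "te_status.tsv")

        dmr_genes = annotate.dmr_associated_genes(assignments)
        set_a = [g for g in genes if g.id in dmr_genes]
        set_b = [g for g in genes if g.id not in dmr_genes]
        rows = []
        for region in annotate.REGIONS:
            ca = annotate.te_counts_per_gene(set_a, tes, region, p.flank,
                                             lengths)
            cb = annotate.te_counts_per_gene(set_b, tes, region, p.flank,
                                             lengths)
            res = annotate.te_frequency_contrast(ca, cb)
            rows.append({"region": region, "set_a": "DMR+", "set_b": "DMR-",
                         **res})
        _write(pd.DataFrame(rows), outdir / "annotate" /
               "te_frequency.tsv")
    return {"assignments": assignments, "te_calls": te_calls}


def run_metagene(cfg: PipelineConfig, outdir: Path, genome=None, genes=None,
                 tes=None, samples=None) -> pd.DataFrame:
    """Gene/TE metagene profiles and expression-decile profiles."""
    inputs = _inputs(cfg, outdir)
    if genome is None or genes is None or tes is None:
        _, genome, genes, tes = _load_common(cfg, outdir)
    if samples is None:
        samples = _load_samples(inputs, list(inputs["reports"]))
    expression = io.read_expression(inputs.get(
        "expression", outdir / "expression.tsv"))
    p = cfg.params
    lengths = genome.lengths
    profiles = []
    with _stage("metagene"):
        for stage, reps in samples.items():
            pooled = (pd.concat(reps, ignore_index=True)
                      .groupby(["chrom", "pos", "strand", "context"],
                               observed=True)[["n_meth", "n_unmeth"]]
                      .sum().reset_index())
            for context in io.CONTEXTS:
                prof = metagene.profile(pooled, genes, context,
                                        flank=p.flank, nbins=p.nbins,
                                        chrom_lengths=lengths)
                prof.insert(0, "stratum", "all_genes")
                prof.insert(0, "context", context)
                prof.insert(0, "sample", stage)
                profiles.append(prof)
            prof = metagene.profile(pooled, tes, "CHH", flank=p.flank,
                                    nbins=p.nbins, chrom_lengths=lengths)
            prof.insert(0, "stratum", "all_tes")
            prof.insert(0, "context", "CHH")
            prof.insert(0, "sample", stage)
            profiles.append(prof)
            if stage in expression.columns:
                deciles = metagene.expression_deciles(expression, stage)
                by_dec = metagene.profile_by_decile(
                    pooled, genes, "CG", deciles, flank=p.flank,
                    nbins=p.nbins, chrom_lengths=lengths)
                for k, prof in by_dec.items():
                    prof.insert(0, "stratum", f"decile_{k}")
                    prof.insert(0, "context", "CG")
                    prof.insert(0, "sample", stage)
                    profiles.append(prof)
        out = pd.concat(profiles, ignore_index=True)
        _write(out, outdir / "metagene" / "profiles.tsv")
    return out


def run_smallrna(cfg: PipelineConfig, outdir: Path, genome=None, tes=None,
                 dmrs=None) -> dict:
    """Small-RNA density over TEs; contrast CHH-hyper TEs vs the rest."""
    inputs = _inputs(cfg, outdir)
    if genome is None or tes is None:
        _, genome, _, tes = _load_common(cfg, outdir)
    if dmrs is None:
        dmrs = pd.read_csv(outdir / "dmr" / "dmrs.tsv", sep="\t")
    reads = io.read_smallrna_bed(inputs.get(
        "smallrna", outdir / "smallrna.bed"))
    p = cfg.params
    lengths = genome.lengths
    with _stage("smallrna"):
        chh_hyper = dmrs[(dmrs["context"] == "CHH")
                         & (dmrs["direction"] == "hyper")]
        hyper_assign = annotate.associate_dmrs(
            chh_hyper, tes, flank=0, chrom_lengths=lengths)
        hyper_ids = set(hyper_assign.loc[hyper_assign["region"] == "body",
                                         "feature_id"])
        hyper_tes = [t for t in tes if t.id in hyper_ids]
        other_tes = [t for t in tes if t.id not in hyper_ids]

        tracks = []
        for label, subset in (("all_tes", tes), ("chh_hyper_tes",
                                                 hyper_tes)):
            track = smallrna.density(reads, subset, flank=p.flank,
                                     nbins=p.nbins, chrom_lengths=lengths)
            track.insert(0, "stratum", label)
            tracks.append(track)
        density = pd.concat(tracks, ignore_index=True)
        _write(density, outdir / "smallrna" / "density.tsv")

        contrasts = []
        for length in smallrna.LENGTH_CLASSES:
            if hyper_tes and other_tes:
                res = smallrna.contrast_density(hyper_tes, other_tes,
                                                reads, length=length)
                res.pop("table")
                contrasts.append({"set_a": "chh_hyper_tes",
                                  "set_b": "other_tes",
                                  "length": length, **res})
        _write(pd.DataFrame(contrasts), outdir / "smallrna" /
               "contrast.tsv")

        assoc, not_assoc = smallrna.te_split_by_smallrna(tes, reads)
        split = pd.DataFrame(
            {"te_id": [t.id for t in assoc] + [t.id for t in not_assoc],
             "srna_associated": [True] * len(assoc)
             + [False] * len(not_assoc)})
        _write(split.sort_values("te_id", ignore_index=True),
               outdir / "smallrna" / "te_split.tsv")
    return {"density": density, "hyper_tes": hyper_tes}


def run_integrate(cfg: PipelineConfig, outdir: Path,
                  assignments=None) -> dict:
    """DMR-DEG overlap, concordance table and candidate screen."""
    inputs = _inputs(cfg, outdir)
    if assignments is None:
        assignments = pd.read_csv(outdir / "annotate" / "assignments.tsv",
                                  sep="\t")
    de = io.read_de_table(inputs.get("de_table", outdir / "de_table.tsv"))
    gene_lists = {}
    for label, path in cfg.gene_lists.items():
        with open(path) as fh:
            gene_lists[label] = [ln.strip() for ln in fh if ln.strip()]
    with _stage("integrate"):
        venn = integrate.dmr_deg_overlap(assignments, de)
        _write(pd.DataFrame([{k: venn[k] for k in
                              ("n_dmr_assoc", "n_deg", "n_intersection",
                               "n_union")}]),
               outdir / "integrate" / "venn.tsv")
        conc = integrate.concordance_table(assignments, de)
        _write(conc, outdir / "integrate" / "concordance.tsv")
        candidates = integrate.candidate_screen(conc, de, gene_lists)
        _write(candidates, outdir / "integrate" / "candidates.tsv")
    return {"venn": venn, "concordance": conc, "candidates": candidates}


def run_all(cfg: PipelineConfig, outdir: Path) -> None:
    """The whole study: simulate, call, DMRs, annotation, metagene
    profiles, small-RNA density, integration, manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = run_simulate(cfg, outdir)
    _write_manifest(cfg, outdir, inputs)
    chroms = io.read_fasta(inputs["genome"])
    genome = io.GenomeAssembly(chroms, inputs["chloroplast"])
    genes = io.read_gff3_genes(inputs["genes_gff"])
    tes = io.read_bed_tes(inputs["tes_bed"])
    samples = _load_samples(inputs, cfg.simulate.stages)
    called = run_call(cfg, outdir, genome=genome, samples=samples)
    _, dmrs = run_dmr(cfg, outdir, genome=genome, samples=samples)
    ann = run_annotate(cfg, outdir, genome=genome, genes=genes, tes=tes,
                       dmrs=dmrs, called=called)
    run_metagene(cfg, outdir, genome=genome, genes=genes, tes=tes,
                 samples=samples)
    run_smallrna(cfg, outdir, genome=genome, tes=tes, dmrs=dmrs)
    run_integrate(cfg, outdir, assignments=ann["assignments"])


def _write_manifest(cfg: PipelineConfig, outdir: Path,
                    inputs: dict) -> None:
    from dataclasses import asdict
    manifest = {
        "seedmeth_version": __version__,
        "seed": cfg.seed,
        "parameters": asdict(cfg.params),
        "simulate": asdict(cfg.simulate),
        "comparison": {"group_a": cfg.group_a, "group_b": cfg.group_b},
        "inputs": inputs,
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
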