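"""Synthetic genomes, methylomes, expression and small-RNA data with
known truth, for exercising every stage of the pipeline.

The generator inverts the measurement model of bisulphite sequencing:
each reference cytosine carries a true methylation level m (0 for
unmethylated sites, a stratum-specific level for methylated ones);
coverage is Poisson(depth_mean) and the methylated read count is
Binomial(coverage, m + (1 - m) * eps), where eps is the bisulphite
non-conversion error.  The chloroplast chromosome is simulated fully
unmethylated so the error rate can be re-estimated from it exactly as
with real data.

The per-site truth (which sites are methylated, and at what level) is a
property of the genome: it is drawn from a seed stream that does not
depend on stage, group or replicate, so samples simulated from the same
landscape differ only by sampling noise.  Stage-dependent CHH gain in
TE bodies, and planted DMRs that assign different levels to the two
comparison groups, are deterministic modifications of that shared
truth.  Gene-body CG methylation varies across genes (a per-gene
methylated-site fraction drawn from a Beta distribution) so that
expression can be rank-coupled to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GenomeAssembly, GenomicFeature, genome_cytosines

STRATA = ("background", "gene_body", "te_body")
_BASES = np.frombuffer(b"ACGT", dtype="S1")


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedDMR:
    """An interval where every cytosine of ``context`` has true level
    level_a in group A samples and level_b in group B samples."""
    chrom: str
    start: int
    end: int
    context: str
    level_a: float
    level_b: float

    def __post_init__(self):
        if not (0 <= self.level_a <= 1 and 0 <= self.level_b <= 1):
            raise ConfigError("planted DMR levels must be in [0, 1]")
        if self.level_a == self.level_b:
            raise ConfigError("planted DMR levels must differ")


@dataclass
class MethylationLandscape:
    """True methylation structure of the synthetic genome.

    ``base_level``: level of a methylated site, per context and stratum.
    ``site_fraction``: fraction of cytosines that are methylated at all,
    per context and stratum.  Defaults follow the levels typical of a
    plant seed methylome: high CG (~0.92) and CHG (~0.85) levels with a
    much lower CHH level (~0.40), and mC site fractions of 0.55 / 0.40 /
    0.08.  ``stage_te_chh_gain`` adds to the CHH level of methylated
    TE-body sites per stage, emulating progressive RdDM-driven gain.
    ``gene_cg_fraction_concentration`` spreads the per-gene CG
    methylated-site fraction (Beta-distributed around the gene_body
    default) so gene-body CG methylation differs between genes.
    """
    base_level: dict = field(default_factory=lambda: {
        ctx: {s: lvl for s in STRATA}
        for ctx, lvl in (("CG", 0.92), ("CHG", 0.85), ("CHH", 0.40))})
    site_fraction: dict = field(default_factory=lambda: {
        ctx: {s: frac for s in STRATA}
        for ctx, frac in (("CG", 0.55), ("CHG", 0.40), ("CHH", 0.08))})
    stage_te_chh_gain: dict = field(default_factory=dict)
    planted_dmrs: list = field(default_factory=list)
    gene_cg_fraction_concentration: float = 10.0

    def validate(self) -> None:
        for table in (self.base_level, self.site_fraction):
            for ctx, strata in table.items():
                for stratum, v in strata.items():
                    if not 0.0 <= v <= 1.0:
                        raise ConfigError(
                            f"{ctx}/{stratum}: probability {v} not in [0,1]")
        ivals = sorted((d.chrom, d.start, d.end) for d in self.planted_dmrs)
        for (c1, s1, e1), (c2, s2, e2) in zip(ivals, ivals[1:]):
            if c1 == c2 and s2 < e1:
                raise ConfigError("planted DMRs must not overlap")


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 500_000
    chloroplast_length: int = 125_000
    depth_mean: float = 20.0
    conversion_error: float = 0.006
    n_genes: int = 300
    n_tes: int = 200
    fraction_intragenic_tes: float = 0.25
    stages: tuple = ("S1", "S2", "S3", "S5", "S7")
    n_replicates: int = 2
    gene_length_range: tuple = (1000, 4000)
    te_length_range: tuple = (200, 2000)
    min_feature_gap: int = 200
    chloroplast_name: str = "CaCp"

    def validate(self) -> None:
        if self.depth_mean <= 0:
            raise ConfigError("depth_mean must be > 0")
        if not 0.0 <= self.conversion_error < 0.05:
            raise ConfigError("conversion_error must be in [0, 0.05)")
        if not 0.0 <= self.fraction_intragenic_tes <= 1.0:
            raise ConfigError("fraction_intragenic_tes must be in [0, 1]")
        if self.n_chromosomes < 1 or self.chromosome_length < 1:
            raise ConfigError("need at least one non-empty chromosome")
        if not self.stages:
            raise ConfigError("need at least one stage")


def _rng(config: SimulationConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed % (2 ** 31), *stream])


# ---------------------------------------------------------------------------
# genome and features
# ---------------------------------------------------------------------------

_TE_CLASS_PROBS = (("LTR", 0.45), ("LINE", 0.15), ("DNA", 0.30),
                   ("other", 0.10))


def generate_genome(config: SimulationConfig
                    ) -> tuple[GenomeAssembly, list[GenomicFeature]]:
    """Uniform-random assembly plus non-overlapping gene and TE placements.

    A fraction of TEs is placed inside gene bodies (intragenic); the
    rest sit between genes.  The chloroplast chromosome carries no
    features.  Deterministic under config.seed.
    """
    config.validate()
    rng = _rng(config, 1)
    chroms: dict[str, str] = {}
    for i in range(config.n_chromosomes):
        seq = rng.choice(_BASES, size=config.chromosome_length)
        chroms[f"Ca{i + 1}"] = seq.tobytes().decode("ascii")
    cp = rng.choice(_BASES, size=config.chloroplast_length)
    chroms[config.chloroplast_name] = cp.tobytes().decode("ascii")
    genome = GenomeAssembly(chroms, config.chloroplast_name)

    n_intra = int(round(config.fraction_intragenic_tes * config.n_tes))
    n_inter = config.n_tes - n_intra
    chrom_names = [f"Ca{i + 1}" for i in range(config.n_chromosomes)]

    # per-chromosome share of genes and intergenic TEs
    gene_chrom = np.sort(rng.integers(0, config.n_chromosomes,
                                      config.n_genes))
    te_chrom = np.sort(rng.integers(0, config.n_chromosomes, n_inter))
    gene_lengths = rng.integers(config.gene_length_range[0],
                                config.gene_length_range[1] + 1,
                                config.n_genes)
    te_lengths = rng.integers(config.te_length_range[0],
                              config.te_length_range[1] + 1, n_inter)

    features: list[GenomicFeature] = []
    genes: list[GenomicFeature] = []
    for ci, chrom in enumerate(chrom_names):
        lens = np.concatenate([gene_lengths[gene_chrom == ci],
                               te_lengths[te_chrom == ci]])
        kinds = (["gene"] * int((gene_chrom == ci).sum())
                 + ["TE"] * int((te_chrom == ci).sum()))
        order = rng.permutation(len(lens))
        lens, kinds = lens[order], [kinds[k] for k in order]
        total = int(lens.sum()) + config.min_feature_gap * (len(lens) + 1)
        L = config.chromosome_length
        if total > L:
            raise ConfigError(
                f"features ({total} bp incl. gaps) exceed {chrom} ({L} bp)")
        extra = rng.multinomial(L - total, np.full(len(lens) + 1,
                                                   1.0 / (len(lens) + 1)))
        cursor = 0
        for j, (length, kind) in enumerate(zip(lens, kinds)):
            cursor += config.min_feature_gap + int(extra[j])
            start, end = cursor, cursor + int(length)
            strand = "+" if rng.random() < 0.5 else "-"
            if kind == "gene":
                fid = f"gene{len(genes) + 1:05d}"
                feat = GenomicFeature(fid, "gene", chrom, start, end, strand)
                genes.append(feat)
            else:
                cls = rng.choice([c for c, _ in _TE_CLASS_PROBS],
                                 p=[p for _, p in _TE_CLASS_PROBS])
                fid = f"te{sum(f.ftype == 'TE' for f in features) + 1:05d}" \
                      f"_{cls}"
                feat = GenomicFeature(fid, "TE", chrom, start, end, strand,
                                      te_class=str(cls))
            features.append(feat)
            cursor = end

    # intragenic TEs inside randomly chosen gene bodies
    eligible = [g for g in genes
                if g.length >= config.te_length_range[0] + 20]
    if n_intra and not eligible:
        raise ConfigError("no gene long enough to host an intragenic TE")
    n_te_so_far = sum(f.ftype == "TE" for f in features)
    for k in range(n_intra):
        host = eligible[int(rng.integers(0, len(eligible)))]
        max_len = min(config.te_length_range[1], host.length - 20)
        length = int(rng.integers(config.te_length_range[0], max_len + 1))
        start = host.start + int(rng.integers(0, host.length - length + 1))
        cls = rng.choice([c for c, _ in _TE_CLASS_PROBS],
                         p=[p for _, p in _TE_CLASS_PROBS])
        fid = f"te{n_te_so_far + k + 1:05d}_{cls}"
        features.append(GenomicFeature(fid, "TE", host.chrom, start,
                                       start + length, host.strand,
                                       te_class=str(cls)))
    return genome, features


# ---------------------------------------------------------------------------
# methylome truth
# ---------------------------------------------------------------------------

_STRATUM_CODE = {"background": 0, "gene_body": 1, "te_body": 2}


def methylome_truth(genome: GenomeAssembly,
                    features: Sequence[GenomicFeature],
                    landscape: MethylationLandscape,
                    config: SimulationConfig
                    ) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Per-site base truth shared by all samples.

    Returns ({chrom: frame with pos, strand, context, stratum, gene_idx,
    is_meth, m_base}, gene truth frame with the realised mean gene-body
    CG level per gene).  The chloroplast is fully unmethylated.
    Deterministic under config.seed and independent of stage, group and
    replicate.
    """
    landscape.validate()
    rng = _rng(config, 2)
    genes = [f for f in features if f.ftype == "gene"]
    f0 = landscape.site_fraction["CG"]["gene_body"]
    conc = landscape.gene_cg_fraction_concentration
    if genes and 0.0 < f0 < 1.0:
        gene_frac = rng.beta(conc * f0, conc * (1.0 - f0), size=len(genes))
    else:
        gene_frac = np.full(len(genes), f0)

    truth: dict[str, pd.DataFrame] = {}
    gene_rows = []
    for chrom, seq in genome.chromosomes.items():
        sites = genome_cytosines(genome, chrom)
        if chrom == genome.chloroplast_name:
            sites["stratum"] = 0
            sites["gene_idx"] = -1
            sites["is_meth"] = False
            sites["m_base"] = 0.0
            truth[chrom] = sites
            continue
        stratum = np.zeros(len(seq), dtype=np.int8)
        gene_of = np.full(len(seq), -1, dtype=np.int32)
        for gi, g in enumerate(genes):
            if g.chrom == chrom:
                stratum[g.start:g.end] = 1
                gene_of[g.start:g.end] = gi
        for f in features:
            if f.ftype == "TE" and f.chrom == chrom:
                stratum[f.start:f.end] = 2
        pos = sites["pos"].to_numpy()
        sites["stratum"] = stratum[pos]
        sites["gene_idx"] = gene_of[pos]

        ctx_codes = sites["context"].map(
            {"CG": 0, "CHG": 1, "CHH": 2}).to_numpy()
        frac = np.empty(len(sites))
        level = np.empty(len(sites))
        for ctx, ci in (("CG", 0), ("CHG", 1), ("CHH", 2)):
            for stratum_name, sc in _STRATUM_CODE.items():
                mask = (ctx_codes == ci) & (sites["stratum"].to_numpy() == sc)
                frac[mask] = landscape.site_fraction[ctx][stratum_name]
                level[mask] = landscape.base_level[ctx][stratum_name]
        # per-gene CG site fraction inside gene bodies (TE-free part)
        cg_in_gene = (ctx_codes == 0) & (sites["stratum"].to_numpy() == 1)
        if cg_in_gene.any():
            frac[cg_in_gene] = gene_frac[sites["gene_idx"]
                                         .to_numpy()[cg_in_gene]]
        is_meth = rng.random(len(sites)) < frac
        sites["is_meth"] = is_meth
        sites["m_base"] = np.where(is_meth, level, 0.0)
        truth[chrom] = sites

    for gi, g in enumerate(genes):
        t = truth.get(g.chrom)
        body_cg = t[(t["gene_idx"] == gi) & (t["context"] == "CG")
                    & (t["stratum"] == 1)]
        gene_rows.append({
            "gene_id": g.id,
            "site_fraction": float(gene_frac[gi]) if len(gene_frac) else
            np.nan,
            "body_cg_level": (100.0 * body_cg["m_base"].mean()
                              if len(body_cg) else np.nan),
            "n_body_cg_sites": len(body_cg),
        })
    return truth, pd.DataFrame(gene_rows)


def true_levels(truth: Mapping[str, pd.DataFrame],
                landscape: MethylationLandscape,
                config: SimulationConfig, stage: str,
                group: str = "A") -> dict[str, np.ndarray]:
    """Per-site true level m for one stage and comparison group."""
    if stage not in config.stages:
        raise ConfigError(f"unknown stage {stage!r}")
    gain = landscape.stage_te_chh_gain.get(stage, 0.0)
    out = {}
    for chrom, sites in truth.items():
        m = sites["m_base"].to_numpy().copy()
        if gain and chrom != config.chloroplast_name:
            te_chh = (sites["is_meth"].to_numpy()
                      & (sites["stratum"].to_numpy() == 2)
                      & (sites["context"].to_numpy() == "CHH"))
            m[te_chh] = np.minimum(m[te_chh] + gain, 1.0)
        for dmr in landscape.planted_dmrs:
            if dmr.chrom != chrom:
                continue
            pos = sites["pos"].to_numpy()
            sel = ((pos >= dmr.start) & (pos < dmr.end)
                   & (sites["context"].to_numpy() == dmr.context))
            m[sel] = dmr.level_a if group == "A" else dmr.level_b
        out[chrom] = m
    return out


def _trinucleotides(seq: str, pos: np.ndarray, strand: np.ndarray
                    ) -> np.ndarray:
    arr = np.frombuffer((seq + "NN").encode("ascii"), dtype="S1")
    comp = np.zeros(256, dtype="S1")
    for a, b in zip(b"ACGTN", b"TGCAN"):
        comp[a] = bytes([b])
    plus = strand == "+"
    tri = np.empty(len(pos), dtype="U3")
    p = pos[plus]
    tri[plus] = np.char.add(np.char.add(
        arr[p].astype("U1"), arr[p + 1].astype("U1")),
        arr[p + 2].astype("U1"))
    q = pos[~plus]
    b0 = comp[arr[q].view(np.uint8)].astype("U1")
    b1 = comp[arr[np.maximum(q - 1, 0)].view(np.uint8)].astype("U1")
    b1[q - 1 < 0] = "N"
    b2 = comp[arr[np.maximum(q - 2, 0)].view(np.uint8)].astype("U1")
    b2[q - 2 < 0] = "N"
    tri[~plus] = np.char.add(np.char.add(b0, b1), b2)
    return tri


def simulate_methylome(genome: GenomeAssembly,
                       truth: Mapping[str, pd.DataFrame],
                       landscape: MethylationLandscape,
                       config: SimulationConfig, stage: str,
                       group: str = "A", replicate: int = 0
                       ) -> pd.DataFrame:
    """One sample's cytosine table (all reference cytosines, 0-based pos).

    Coverage ~ Poisson(depth_mean); n_meth ~ Binomial(coverage,
    m + (1 - m) * eps).  Zero-coverage sites are kept with 0/0 counts.
    """
    config.validate()
    if stage not in config.stages:
        raise ConfigError(f"unknown stage {stage!r}")
    stage_idx = config.stages.index(stage)
    group_code = 0 if group == "A" else 1
    rng = _rng(config, 3, stage_idx, group_code, replicate)
    eps = config.conversion_error
    levels = true_levels(truth, landscape, config, stage, group)
    frames = []
    for chrom, sites in truth.items():
        m = levels[chrom]
        cov = rng.poisson(config.depth_mean, size=len(sites))
        p_obs = m + (1.0 - m) * eps
        n_meth = rng.binomial(cov, p_obs)
        df = sites[["pos", "strand", "context"]].copy()
        df.insert(0, "chrom", chrom)
        df["n_meth"] = n_meth
        df["n_unmeth"] = cov - n_meth
        df["trinucleotide"] = _trinucleotides(
            genome.chromosomes[chrom], df["pos"].to_numpy(),
            df["strand"].to_numpy())
        frames.append(df[["chrom", "pos", "strand", "n_meth", "n_unmeth",
                          "context", "trinucleotide"]])
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# expression and differential expression
# ---------------------------------------------------------------------------

def simulate_expression(gene_truth: pd.DataFrame,
                        config: SimulationConfig,
                        coupling: float = 0.5,
                        n_up: int = 50, n_down: int = 50,
                        log_fpkm_mean: float = 1.0,
                        log_fpkm_sd: float = 1.5
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """FPKM per stage plus a planted differential-expression table.

    FPKM is log-normal with a Gaussian-copula rank coupling of strength
    ``coupling`` (Pearson on latent normals) to the gene's true body CG
    level; coupling 0 leaves expression independent of methylation.
    The DE table plants exactly ``n_up`` up- and ``n_down``
    down-regulated genes (|log2FC| >= 1, q <= 0.05); all other genes get
    sub-threshold fold changes and q > 0.05.  The truth is returned in
    the table's ``planted`` column.
    """
    if not -1.0 <= coupling <= 1.0:
        raise ConfigError("coupling must be in [-1, 1]")
    n = len(gene_truth)
    if n_up + n_down > n:
        raise ConfigError("more planted DEGs than genes")
    rng = _rng(config, 4)
    from scipy.special import erfinv
    v = gene_truth["body_cg_level"].fillna(0.0).to_numpy()
    order = np.argsort(np.argsort(v, kind="mergesort"), kind="mergesort")
    u = (order + 0.5) / n
    z_meth = np.sqrt(2.0) * erfinv(2.0 * u - 1.0)

    expr = {"gene_id": gene_truth["gene_id"].to_numpy()}
    for stage in config.stages:
        noise = rng.standard_normal(n)
        z = coupling * z_meth + np.sqrt(1.0 - coupling ** 2) * noise
        expr[stage] = np.exp(log_fpkm_mean + log_fpkm_sd * z)
    expression = pd.DataFrame(expr)

    idx = rng.permutation(n)
    up_idx, down_idx = idx[:n_up], idx[n_up:n_up + n_down]
    log2fc = rng.normal(0.0, 0.3, size=n).clip(-0.99, 0.99)
    qvalue = rng.uniform(0.1, 1.0, size=n)
    log2fc[up_idx] = rng.uniform(1.0, 4.0, size=n_up)
    log2fc[down_idx] = -rng.uniform(1.0, 4.0, size=n_down)
    qvalue[up_idx] = rng.uniform(0.0, 0.05, size=n_up)
    qvalue[down_idx] = rng.uniform(0.0, 0.05, size=n_down)
    planted = np.full(n, "ns", dtype=object)
    planted[up_idx] = "up"
    planted[down_idx] = "down"
    de = pd.DataFrame({
        "gene_id": gene_truth["gene_id"].to_numpy(),
        "log2fc": log2fc,
        "qvalue": qvalue,
        "planted": planted,
    })
    return expression, de


# ---------------------------------------------------------------------------
# small RNA
# ---------------------------------------------------------------------------

def simulate_smallrna(chrom_lengths: Mapping[str, int],
                      tes: Sequence[GenomicFeature],
                      hyper_set: Sequence[GenomicFeature],
                      config: SimulationConfig,
                      lambda_bg: float = 0.001,
                      density_ratio: float = 5.0,
                      frac_24nt: float = 0.8,
                      lambda_hyper: float | None = None) -> pd.DataFrame:
    """Small-RNA reads at per-bp middle-base rate lambda_hyper inside
    hyper_set TE bodies and lambda_bg everywhere else.

    lambda_hyper defaults to density_ratio * lambda_bg.  Reads are
    placed by their middle base (uniform within the target region), are
    24 nt with probability frac_24nt and 21 nt otherwise.  Deterministic
    under config.seed.
    """
    if lambda_hyper is None:
        lambda_hyper = density_ratio * lambda_bg
    if lambda_bg < 0 or lambda_hyper < 0:
        raise ConfigError("small-RNA rates must be >= 0")
    rng = _rng(config, 5)
    rows = []

    def _emit(chrom, mid, clen):
        length = 24 if rng.random() < frac_24nt else 21
        start = int(mid) - (length - 1) // 2
        start = min(max(start, 0), max(clen - length, 0))
        rows.append((chrom, start, start + length, length,
                     "+" if rng.random() < 0.5 else "-"))

    hyper_by_chrom: dict[str, list] = {}
    for te in hyper_set:
        hyper_by_chrom.setdefault(te.chrom, []).append((te.start, te.end))
    for chrom, clen in chrom_lengths.items():
        bodies = hyper_by_chrom.get(chrom, [])
        n_bg = rng.poisson(lambda_bg * clen)
        for mid in rng.integers(0, clen, size=n_bg):
            if any(s <= mid < e for s, e in bodies):
                continue  # hyper bodies get their own rate below
            _emit(chrom, mid, clen)
    for te in hyper_set:
        n_hyper = rng.poisson(lambda_hyper * te.length)
        clen = chrom_lengths[te.chrom]
        for mid in rng.integers(te.start, te.end, size=n_hyper):
            _emit(te.chrom, mid, clen)
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "length",
                                     "strand"])
    df = df.sort_values(["chrom", "start", "end", "strand"],
                        kind="mergesort", ignore_index=True)
    df.insert(3, "name", [f"sr{i:07d}" for i in range(len(df))])
    df["score"] = 0
    return df[["chrom", "start", "end", "name", "score", "strand",
               "length"]]


# ---------------------------------------------------------------------------
# truth-table exports
# ---------------------------------------------------------------------------

def site_truth_table(truth: Mapping[str, pd.DataFrame],
                     landscape: MethylationLandscape,
                     config: SimulationConfig, stage: str,
                     group: str = "A") -> pd.DataFrame:
    """Flat per-site truth (chrom, pos, strand, context, stratum, m)."""
    frames = []
    levels = true_levels(truth, landscape, config, stage, group)
    for chrom, sites in truth.items():
        df = sites[["pos", "strand", "context", "stratum"]].copy()
        df.insert(0, "chrom", chrom)
        df["m"] = levels[chrom]
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def dmr_truth_table(landscape: MethylationLandscape) -> pd.DataFrame:
    return pd.DataFrame([{
        "chrom": d.chrom, "start": d.start, "end": d.end,
        "context": d.context, "level_a": d.level_a, "level_b": d.level_b,
        "direction": "hyper" if d.level_b > d.level_a else "hypo",
    } for d in landscape.planted_dmrs],
        columns=["chrom", "start", "end", "context", "level_a", "level_b",
                 "direction"])


def plant_dmrs(chrom_lengths: Mapping[str, int],
               config: SimulationConfig, n_dmrs: int = 40,
               width: int = 300, context: str = "CG",
               level_a: float = 0.2, level_b: float = 0.7,
               avoid: Sequence[tuple[str, int, int]] = (),
               margin: int = 300) -> list[PlantedDMR]:
    """Choose non-overlapping intervals for planted DMRs, alternating
    hyper and hypo direction, away from chromosome edges and from the
    ``avoid`` intervals (plus a safety margin on both sides)."""
    rng = _rng(config, 6)
    placed: list[PlantedDMR] = []
    occupied = [(c, s - margin, e + margin) for c, s, e in avoid]
    attempts = 0
    chrom_names = [c for c in chrom_lengths
                   if c != config.chloroplast_name]
    while len(placed) < n_dmrs and attempts < 1000 * max(n_dmrs, 1):
        attempts += 1
        chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
        lo, hi = 1000, chrom_lengths[chrom] - width - 1000
        if hi <= lo:
            continue
        start = int(rng.integers(lo, hi))
        end = start + width
        if any(c == chrom and start - margin < e and s < end + margin
               for c, s, e in ((d.chrom, d.start, d.end) for d in placed)):
            continue
        if any(c == chrom and start < e and s < end
               for c, s, e in occupied):
            continue
        if len(placed) % 2 == 0:
            la, lb = level_a, level_b
        else:
            la, lb = level_b, level_a
        placed.append(PlantedDMR(chrom, start, start + width, context,
                                 la, lb))
    if len(placed) < n_dmrs:
        raise ConfigError("could not place the requested planted DMRs")
    return placed
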