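"""Associating DMRs and TEs with genes, and TE methylation status.

Genes carry a strand-aware body plus 2-kb flanks measured from the
transcription start and termination sites; a DMR overlapping several
regions (e.g. spanning the body/downstream boundary) is counted in each
of them.  TEs are called methylated when they harbour at least one
methylcytosine per 100 bp of body, non-methylated when they harbour
none; TEs in between are kept as an explicit "intermediate" class and
excluded from methylated/non-methylated contrasts (a permissive mode
folds them into non-methylated).
"""

from __future__ import annotations

from typing import Literal, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .io import GenomicFeature

DEFAULT_FLANK = 2000
REGIONS = ("upstream", "body", "downstream")


def feature_regions(feature: GenomicFeature, flank: int = DEFAULT_FLANK,
                    chrom_length: int | None = None
                    ) -> dict[str, tuple[int, int]]:
    """Strand-aware upstream / body / downstream intervals, clipped to
    the chromosome.  Strand '.' orients flanks like '+'.  A clipped-away
    flank is dropped."""
    s, e = feature.start, feature.end
    if feature.strand == "-":
        up = (e, e + flank)
        down = (s - flank, s)
    else:
        up = (s - flank, s)
        down = (e, e + flank)
    out = {}
    hi = chrom_length if chrom_length is not None else np.inf
    for name, (a, b) in (("upstream", up), ("body", (s, e)),
                         ("downstream", down)):
        a2, b2 = max(a, 0), min(b, hi)
        if a2 < b2:
            out[name] = (int(a2), int(b2))
    return out


def _region_trees(features: Sequence[GenomicFeature], flank: int,
                  chrom_lengths: dict[str, int] | None
                  ) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for idx, feat in enumerate(features):
        clen = chrom_lengths.get(feat.chrom) if chrom_lengths else None
        tree = trees.setdefault(feat.chrom, IntervalTree())
        for region, (a, b) in feature_regions(feat, flank, clen).items():
            tree.addi(a, b, (idx, region))
    return trees


def associate_dmrs(dmrs: pd.DataFrame, features: Sequence[GenomicFeature],
                   flank: int = DEFAULT_FLANK,
                   chrom_lengths: dict[str, int] | None = None
                   ) -> pd.DataFrame:
    """One row per (DMR, feature, region) with >= 1 bp overlap.

    Columns: dmr_index (row label in ``dmrs``), feature_id, ftype,
    region, plus the DMR's context and direction when present.
    """
    trees = _region_trees(features, flank, chrom_lengths)
    rows = []
    for dmr_index, dmr in dmrs.iterrows():
        tree = trees.get(dmr["chrom"])
        if tree is None:
            continue
        for hit in sorted(tree.overlap(dmr["start"], dmr["end"]),
                          key=lambda h: (h.data[0], h.data[1])):
            idx, region = hit.data
            feat = features[idx]
            rows.append({
                "dmr_index": dmr_index,
                "feature_id": feat.id,
                "ftype": feat.ftype,
                "region": region,
                "context": dmr.get("context", np.nan),
                "direction": dmr.get("direction", np.nan),
            })
    return pd.DataFrame(rows, columns=["dmr_index", "feature_id", "ftype",
                                       "region", "context", "direction"])


def dmr_associated_genes(assignments: pd.DataFrame) -> set[str]:
    """Genes with at least one DMR assignment in body or flanks."""
    if assignments.empty:
        return set()
    return set(assignments.loc[assignments["ftype"] == "gene", "feature_id"])


# ---------------------------------------------------------------------------
# TE methylation status
# ---------------------------------------------------------------------------

def classify_te_methylation(tes: Sequence[GenomicFeature],
                            mcs: pd.DataFrame,
                            collapse_intermediate: bool = False
                            ) -> pd.DataFrame:
    """Per-TE, per-context methylation status from called mCs.

    ``mcs`` is a called-site table (chrom, pos, context, called).
    density = n_mc / (length/100); status is methylated when
    density >= 1, non-methylated when n_mc = 0, intermediate otherwise
    (or non-methylated if ``collapse_intermediate``).
    """
    called = mcs[mcs["called"]] if "called" in mcs.columns else mcs
    by_chrom = {
        chrom: grp.sort_values("pos")
        for chrom, grp in called.groupby("chrom", observed=True)
    }
    rows = []
    for te in tes:
        if te.length == 0:
            raise ValueError(f"TE {te.id} has zero length")
        grp = by_chrom.get(te.chrom)
        for context in ("CG", "CHG", "CHH"):
            if grp is None:
                n_mc = 0
            else:
                sub = grp[grp["context"] == context]
                pos = sub["pos"].to_numpy()
                n_mc = int(np.searchsorted(pos, te.end)
                           - np.searchsorted(pos, te.start))
            density = n_mc / (te.length / 100.0)
            if density >= 1.0:
                status = "methylated"
            elif n_mc == 0:
                status = "non-methylated"
            else:
                status = ("non-methylated" if collapse_intermediate
                          else "intermediate")
            rows.append({"te_id": te.id, "context": context, "n_mc": n_mc,
                         "density_per_100bp": density, "status": status})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# TE frequency across gene sets
# ---------------------------------------------------------------------------

def te_counts_per_gene(genes: Sequence[GenomicFeature],
                       tes: Sequence[GenomicFeature],
                       region: str, flank: int = DEFAULT_FLANK,
                       chrom_lengths: dict[str, int] | None = None
                       ) -> pd.Series:
    """Number of TEs overlapping the stated region of each gene."""
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}")
    te_trees: dict[str, IntervalTree] = {}
    for i, te in enumerate(tes):
        te_trees.setdefault(te.chrom, IntervalTree()).addi(
            te.start, te.end, i)
    counts = {}
    for gene in genes:
        clen = chrom_lengths.get(gene.chrom) if chrom_lengths else None
        regions = feature_regions(gene, flank, clen)
        tree = te_trees.get(gene.chrom)
        if region not in regions or tree is None:
            counts[gene.id] = 0
            continue
        a, b = regions[region]
        counts[gene.id] = len(tree.overlap(a, b))
    return pd.Series(counts, name=f"n_tes_{region}")


def te_frequency_contrast(counts_a: pd.Series, counts_b: pd.Series,
                          paired: bool = False) -> dict:
    """Compare per-gene TE counts between two gene sets (or two regions
    of one set).

    Unpaired set-vs-set contrasts use the two-sided Mann-Whitney
    rank-sum test; region-vs-region contrasts within one gene set use
    the paired Wilcoxon signed-rank test (``paired=True``; the series
    must then be index-aligned).
    """
    if len(counts_a) == 0 or len(counts_b) == 0:
        return {"p_value": np.nan, "n_a": len(counts_a),
                "n_b": len(counts_b), "mean_a": np.nan, "mean_b": np.nan}
    if paired:
        a, b = counts_a.align(counts_b, join="inner")
        diffs = a - b
        if (diffs == 0).all():
            p = 1.0
        else:
            p = float(stats.wilcoxon(a, b, zero_method="wilcox",
                                     alternative="two-sided").pvalue)
    else:
        if (set(counts_a.unique()) == set(counts_b.unique())
                and len(counts_a.unique()) == 1):
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(
                counts_a, counts_b, alternative="two-sided").pvalue)
    return {"p_value": p, "n_a": len(counts_a), "n_b": len(counts_b),
            "mean_a": float(counts_a.mean()), "mean_b": float(counts_b.mean())}


# ---------------------------------------------------------------------------
# expression by TE methylation status
# ---------------------------------------------------------------------------

def gene_te_overlaps(genes: Sequence[GenomicFeature],
                     tes: Sequence[GenomicFeature],
                     flank: int = DEFAULT_FLANK,
                     chrom_lengths: dict[str, int] | None = None
                     ) -> pd.DataFrame:
    """All (gene, region, TE) overlap triples."""
    te_trees: dict[str, IntervalTree] = {}
    for i, te in enumerate(tes):
        te_trees.setdefault(te.chrom, IntervalTree()).addi(
            te.start, te.end, i)
    rows = []
    for gene in genes:
        clen = chrom_lengths.get(gene.chrom) if chrom_lengths else None
        tree = te_trees.get(gene.chrom)
        if tree is None:
            continue
        for region, (a, b) in feature_regions(gene, flank, clen).items():
            for hit in tree.overlap(a, b):
                rows.append({"gene_id": gene.id, "region": region,
                             "te_id": tes[hit.data].id})
    return pd.DataFrame(rows, columns=["gene_id", "region", "te_id"])


def methylation_by_te_status(expression: pd.DataFrame, sample: str,
                             te_calls: pd.DataFrame,
                             overlaps: pd.DataFrame,
                             context: str, region: str) -> pd.DataFrame:
    """FPKM summaries for genes harbouring methylated vs non-methylated
    TEs in a region/context.

    A gene goes to the methylated group when ANY overlapping TE in that
    region is methylated in the context; to the non-methylated group
    when all its overlapping TEs are non-methylated.  Genes whose TEs
    are all intermediate are excluded, mirroring the TE-level contrast.
    """
    calls = te_calls[te_calls["context"] == context].set_index("te_id")
    sub = overlaps[overlaps["region"] == region]
    rows = []
    groups: dict[str, list[str]] = {"methylated": [], "non-methylated": []}
    for gene_id, grp in sub.groupby("gene_id"):
        statuses = set(calls.loc[calls.index.intersection(grp["te_id"]),
                                 "status"])
        if "methylated" in statuses:
            groups["methylated"].append(gene_id)
        elif statuses == {"non-methylated"}:
            groups["non-methylated"].append(gene_id)
    expr = expression.set_index("gene_id")[sample]
    for status, gene_ids in groups.items():
        fpkm = expr.reindex(gene_ids).dropna()
        rows.append({
            "context": context, "region": region, "te_status": status,
            "n_genes": len(fpkm),
            "fpkm_q25": fpkm.quantile(0.25) if len(fpkm) else np.nan,
            "fpkm_median": fpkm.median() if len(fpkm) else np.nan,
            "fpkm_q75": fpkm.quantile(0.75) if len(fpkm) else np.nan,
        })
    return pd.DataFrame(rows)
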