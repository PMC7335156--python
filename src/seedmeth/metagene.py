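"""Metagene methylation profiles: 10 bins each for the 2-kb upstream
flank, the feature body and the 2-kb downstream flank, 5'->3'.

Bin levels are coverage-weighted: within a bin the counts of every
contributing cytosine of the requested context are pooled across all
features of the stratum and the level is 100 * sum(n_meth) /
sum(coverage).  This is the "normalise to the cytosines present in the
bin" reading; a per-feature-mean mode is available for comparison.  By
default every covered site contributes its observed proportion, not
only binomially-called mCs, so near-zero regional levels are unbiased;
a called-only mode supports mC-style summaries.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GenomicFeature

DEFAULT_FLANK = 2000
DEFAULT_NBINS = 10

REGION_OF_BIN = (["upstream"] * 10 + ["body"] * 10 + ["downstream"] * 10)


def _split_bins(a: int, b: int, nbins: int) -> np.ndarray:
    """Edges of nbins near-equal bins over [a, b); sizes differ by <=1."""
    return a + (np.arange(nbins + 1) * (b - a)) // nbins


def bin_intervals(feature: GenomicFeature, flank: int = DEFAULT_FLANK,
                  nbins: int = DEFAULT_NBINS,
                  chrom_length: int | None = None) -> np.ndarray:
    """(3*nbins, 2) genomic intervals in profile order (bin 0 5'-most).

    Flanks are clipped at chromosome bounds before binning; fully
    clipped flank bins come back empty (start == end).  For minus-strand
    features the profile axis is reversed so bin 0 is always upstream of
    the transcription start site.
    """
    s, e = feature.start, feature.end
    hi = chrom_length if chrom_length is not None else np.iinfo(np.int64).max
    left = (max(s - flank, 0), s)
    right = (e, min(e + flank, hi))
    out = np.empty((3 * nbins, 2), dtype=np.int64)
    for r, (a, b) in enumerate((left, (s, e), right)):
        edges = _split_bins(a, b, nbins) if a < b else np.full(nbins + 1, a)
        out[r * nbins:(r + 1) * nbins, 0] = edges[:-1]
        out[r * nbins:(r + 1) * nbins, 1] = edges[1:]
    if feature.strand == "-":
        out = out[::-1]
    return out


def bin_positions(feature: GenomicFeature, flank: int = DEFAULT_FLANK,
                  nbins: int = DEFAULT_NBINS,
                  chrom_length: int | None = None) -> dict[int, int]:
    """Map every genomic position in the feature's span to its profile
    bin index 0..3*nbins-1.  Reference implementation of the partition;
    the profile path uses interval arithmetic instead."""
    mapping: dict[int, int] = {}
    for idx, (a, b) in enumerate(bin_intervals(feature, flank, nbins,
                                               chrom_length)):
        for pos in range(a, b):
            mapping[pos] = idx
    return mapping


def profile(sample: pd.DataFrame, features: Sequence[GenomicFeature],
            context: str, flank: int = DEFAULT_FLANK,
            nbins: int = DEFAULT_NBINS,
            chrom_lengths: Mapping[str, int] | None = None,
            called_only: bool = False,
            per_feature_mean: bool = False) -> pd.DataFrame:
    """30-bin methylation profile of one context over a feature stratum.

    ``sample`` is a (called) cytosine table with chrom, pos, context,
    n_meth, n_unmeth (and ``called`` if called_only).  Features whose
    body is shorter than nbins are skipped.  Returns one row per bin:
    bin_index, region, level (percent; NaN where no cytosine
    contributes), n_cytosines, n_meth, coverage.
    """
    nb3 = 3 * nbins
    sub = sample[sample["context"] == context]
    if called_only and "called" in sub.columns:
        sub = sub[sub["called"]]
    cov_all = sub["n_meth"] + sub["n_unmeth"]
    sub = sub[cov_all > 0]

    by_chrom = {}
    for chrom, grp in sub.groupby("chrom", observed=True):
        grp = grp.sort_values("pos", kind="mergesort")
        pos = grp["pos"].to_numpy()
        m = np.concatenate([[0], np.cumsum(grp["n_meth"].to_numpy())])
        cov = np.concatenate(
            [[0], np.cumsum((grp["n_meth"] + grp["n_unmeth"]).to_numpy())])
        by_chrom[chrom] = (pos, m, cov)

    tot_m = np.zeros(nb3)
    tot_cov = np.zeros(nb3)
    tot_sites = np.zeros(nb3, dtype=np.int64)
    sum_levels = np.zeros(nb3)
    n_feat_bin = np.zeros(nb3, dtype=np.int64)
    for feat in features:
        if feat.length < nbins:
            continue
        if feat.chrom not in by_chrom:
            continue
        clen = chrom_lengths.get(feat.chrom) if chrom_lengths else None
        ivals = bin_intervals(feat, flank, nbins, clen)
        pos, m, cov = by_chrom[feat.chrom]
        lo = np.searchsorted(pos, ivals[:, 0], side="left")
        hi = np.searchsorted(pos, ivals[:, 1], side="left")
        bm = m[hi] - m[lo]
        bc = cov[hi] - cov[lo]
        tot_m += bm
        tot_cov += bc
        tot_sites += hi - lo
        has = bc > 0
        sum_levels[has] += 100.0 * bm[has] / bc[has]
        n_feat_bin += has

    with np.errstate(invalid="ignore", divide="ignore"):
        if per_feature_mean:
            level = np.where(n_feat_bin > 0, sum_levels / n_feat_bin, np.nan)
        else:
            level = np.where(tot_cov > 0, 100.0 * tot_m / tot_cov, np.nan)
    return pd.DataFrame({
        "bin_index": np.arange(nb3),
        "region": (REGION_OF_BIN if nbins == 10 else
                   ["upstream"] * nbins + ["body"] * nbins
                   + ["downstream"] * nbins),
        "level": level,
        "n_cytosines": tot_sites,
        "n_meth": tot_m.astype(np.int64),
        "coverage": tot_cov.astype(np.int64),
    })


def feature_body_levels(sample: pd.DataFrame,
                        features: Sequence[GenomicFeature],
                        context: str) -> pd.DataFrame:
    """Pooled methylation level of each feature's body.

    Returns one row per feature: feature_id, level (percent, NaN when no
    covered cytosine of the context falls in the body), n_meth,
    coverage.
    """
    sub = sample[sample["context"] == context]
    sub = sub[(sub["n_meth"] + sub["n_unmeth"]) > 0]
    by_chrom = {}
    for chrom, grp in sub.groupby("chrom", observed=True):
        grp = grp.sort_values("pos", kind="mergesort")
        pos = grp["pos"].to_numpy()
        m = np.concatenate([[0], np.cumsum(grp["n_meth"].to_numpy())])
        cov = np.concatenate(
            [[0], np.cumsum((grp["n_meth"] + grp["n_unmeth"]).to_numpy())])
        by_chrom[chrom] = (pos, m, cov)
    rows = []
    for feat in features:
        bm = bc = 0
        if feat.chrom in by_chrom:
            pos, m, cov = by_chrom[feat.chrom]
            lo = np.searchsorted(pos, feat.start, side="left")
            hi = np.searchsorted(pos, feat.end, side="left")
            bm, bc = int(m[hi] - m[lo]), int(cov[hi] - cov[lo])
        rows.append({"feature_id": feat.id,
                     "level": 100.0 * bm / bc if bc else np.nan,
                     "n_meth": bm, "coverage": bc})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# expression deciles
# ---------------------------------------------------------------------------

def expression_deciles(expression: pd.DataFrame, sample: str
                       ) -> pd.DataFrame:
    """Assign genes to FPKM deciles 1 (lowest / non-expressed) .. 10
    (highest).  Ties break by gene_id so the split is deterministic;
    decile sizes differ by at most one."""
    if len(expression) < 10:
        raise ValueError("need at least 10 genes to form deciles")
    ranked = expression[["gene_id", sample]].sort_values(
        [sample, "gene_id"], kind="mergesort", ignore_index=True)
    chunks = np.array_split(np.arange(len(ranked)), 10)
    decile = np.empty(len(ranked), dtype=np.int64)
    for k, idx in enumerate(chunks, start=1):
        decile[idx] = k
    ranked["decile"] = decile
    return ranked.rename(columns={sample: "fpkm"})


def profile_by_decile(sample: pd.DataFrame,
                      genes: Sequence[GenomicFeature], context: str,
                      decile_table: pd.DataFrame,
                      deciles: Sequence[int] = (2, 4, 6, 8, 10),
                      **profile_kwargs) -> dict[int, pd.DataFrame]:
    """One metagene profile per requested expression decile."""
    by_id = {g.id: g for g in genes}
    out = {}
    for k in deciles:
        ids = decile_table.loc[decile_table["decile"] == k, "gene_id"]
        feats = [by_id[i] for i in ids if i in by_id]
        out[k] = profile(sample, feats, context, **profile_kwargs)
    return out
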