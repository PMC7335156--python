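"""Small-RNA density over TEs and their flanks.

A read is assigned by the genomic position of its middle base
(start + floor((length-1)/2), i.e. left-of-centre for even lengths), so
each read lands in at most one bin per feature.  Densities are reads
per 100 bp, per 30-bin metagene axis, separately for the 21-nt and
24-nt size classes that dominate plant small-RNA populations (24-nt
reads guide RdDM-type CHH methylation).  Reads are deduplicated on
(chrom, start, end, strand), mirroring the unique-read collapse used
upstream.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenomicFeature
from .metagene import DEFAULT_FLANK, DEFAULT_NBINS, REGION_OF_BIN, \
    bin_intervals

LENGTH_CLASSES = (21, 24)


def middle_base(start: int, end: int) -> int:
    """0-based genomic position of a read's middle base."""
    length = end - start
    if length <= 0:
        raise ValueError("empty read interval")
    return start + (length - 1) // 2


def dedup_reads(records: pd.DataFrame) -> pd.DataFrame:
    return records.drop_duplicates(
        subset=["chrom", "start", "end", "strand"], ignore_index=True)


def density(records: pd.DataFrame, features: Sequence[GenomicFeature],
            flank: int = DEFAULT_FLANK, nbins: int = DEFAULT_NBINS,
            chrom_lengths: Mapping[str, int] | None = None,
            dedup: bool = True) -> pd.DataFrame:
    """Per-bin small-RNA density track over a feature stratum.

    Returns one row per (length class, bin): reads assigned by middle
    base, total bin bp pooled across features, and density = 100 *
    reads / bp (reads per 100 bp).  A read hitting overlapping features
    counts once per feature.
    """
    if dedup:
        records = dedup_reads(records)
    records = records.copy()
    records["mid"] = records["start"] + (records["end"]
                                         - records["start"] - 1) // 2
    nb3 = 3 * nbins
    rows = []
    for lclass, sub in records.groupby("length", observed=True):
        mids_by_chrom = {
            chrom: np.sort(grp["mid"].to_numpy())
            for chrom, grp in sub.groupby("chrom", observed=True)
        }
        reads = np.zeros(nb3, dtype=np.int64)
        bp = np.zeros(nb3, dtype=np.int64)
        for feat in features:
            if feat.length < nbins:
                continue
            clen = chrom_lengths.get(feat.chrom) if chrom_lengths else None
            ivals = bin_intervals(feat, flank, nbins, clen)
            bp += ivals[:, 1] - ivals[:, 0]
            mids = mids_by_chrom.get(feat.chrom)
            if mids is None:
                continue
            reads += (np.searchsorted(mids, ivals[:, 1], side="left")
                      - np.searchsorted(mids, ivals[:, 0], side="left"))
        with np.errstate(invalid="ignore", divide="ignore"):
            dens = np.where(bp > 0, 100.0 * reads / bp, np.nan)
        rows.append(pd.DataFrame({
            "length": lclass,
            "bin_index": np.arange(nb3),
            "region": (REGION_OF_BIN if nbins == 10 else
                       ["upstream"] * nbins + ["body"] * nbins
                       + ["downstream"] * nbins),
            "reads": reads,
            "bp": bp,
            "density_per_100bp": dens,
        }))
    if not rows:
        return pd.DataFrame(columns=["length", "bin_index", "region",
                                     "reads", "bp", "density_per_100bp"])
    return pd.concat(rows, ignore_index=True)


def _body_reads(tes: Sequence[GenomicFeature], mids_by_chrom) -> int:
    total = 0
    for te in tes:
        mids = mids_by_chrom.get(te.chrom)
        if mids is None:
            continue
        total += int(np.searchsorted(mids, te.end)
                     - np.searchsorted(mids, te.start))
    return total


def contrast_density(tes_a: Sequence[GenomicFeature],
                     tes_b: Sequence[GenomicFeature],
                     records: pd.DataFrame, length: int = 24,
                     dedup: bool = True) -> dict:
    """Fisher's exact test for a density difference between TE sets.

    The 2x2 table opposes middle-base read counts in each set's bodies
    to the remaining (unoccupied) body bp:
    [[reads_A, reads_B], [bp_A - reads_A, bp_B - reads_B]].
    Reports the two-sided hypergeometric p and the density ratio A/B.
    """
    if dedup:
        records = dedup_reads(records)
    sub = records[records["length"] == length]
    mids = {
        chrom: np.sort((grp["start"] + (grp["end"] - grp["start"] - 1) // 2)
                       .to_numpy())
        for chrom, grp in sub.groupby("chrom", observed=True)
    }
    reads_a = _body_reads(tes_a, mids)
    reads_b = _body_reads(tes_b, mids)
    bp_a = sum(t.length for t in tes_a)
    bp_b = sum(t.length for t in tes_b)
    if reads_a > bp_a or reads_b > bp_b:
        raise ValueError("more reads than bp in a TE set")
    table = [[reads_a, reads_b], [bp_a - reads_a, bp_b - reads_b]]
    p = float(stats.fisher_exact(table, alternative="two-sided").pvalue)
    dens_a = 100.0 * reads_a / bp_a if bp_a else np.nan
    dens_b = 100.0 * reads_b / bp_b if bp_b else np.nan
    ratio = dens_a / dens_b if dens_b else np.inf
    return {"reads_a": reads_a, "reads_b": reads_b, "bp_a": bp_a,
            "bp_b": bp_b, "density_a": dens_a, "density_b": dens_b,
            "density_ratio": ratio, "p_value": p, "table": table}


def te_split_by_smallrna(tes: Sequence[GenomicFeature],
                         records: pd.DataFrame, length: int = 24,
                         dedup: bool = True
                         ) -> tuple[list[GenomicFeature],
                                    list[GenomicFeature]]:
    """Partition TEs into small-RNA-associated (>= 1 middle base in the
    body) and not-associated sets."""
    if dedup:
        records = dedup_reads(records)
    sub = records[records["length"] == length]
    mids = {
        chrom: np.sort((grp["start"] + (grp["end"] - grp["start"] - 1) // 2)
                       .to_numpy())
        for chrom, grp in sub.groupby("chrom", observed=True)
    }
    assoc, not_assoc = [], []
    for te in tes:
        arr = mids.get(te.chrom)
        n = 0 if arr is None else int(np.searchsorted(arr, te.end)
                                      - np.searchsorted(arr, te.start))
        (assoc if n >= 1 else not_assoc).append(te)
    return assoc, not_assoc
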