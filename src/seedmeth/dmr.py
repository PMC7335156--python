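"""Sliding-window detection of differentially methylated regions.

The genome is tiled with 100-bp windows every 50 bp.  Within a window
and sequence context, cytosines covered by >= 5 reads in both groups
are pooled; windows with at least three such cytosines are tested for a
group difference with a binomial logistic-regression likelihood-ratio
test, p-values are converted to q-values with a pi0-adjusted (SLIM
style) step-up procedure, and windows with >= 25 percentage-point level
difference at q <= 0.01 are kept and merged into DMRs when consecutive
significant bins of the same context and direction lie within 50 bp.

The likelihood-ratio statistic for a binomial GLM whose only predictor
is the group indicator has a closed form: replicate counts pool within
each group, and the statistic equals the G-test on the pooled 2x2 table
(methylated/unmethylated by group).  That identity holds for any number
of replicates and is what this module evaluates.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import xlogy

DEFAULT_WINDOW = 100
DEFAULT_STEP = 50
DEFAULT_MIN_CYTOSINES = 3
DEFAULT_MIN_SITE_DEPTH = 5
DEFAULT_MIN_DIFF = 25.0
DEFAULT_MAX_Q = 0.01
DEFAULT_MERGE_GAP = 50


# ---------------------------------------------------------------------------
# window tiling
# ---------------------------------------------------------------------------

def window_starts(length: int, size: int = DEFAULT_WINDOW,
                  step: int = DEFAULT_STEP) -> np.ndarray:
    """Start coordinates of sliding windows on one chromosome.

    Starts run 0, step, 2*step, ... while a full step remains
    (start + step <= length); if the final window still does not reach
    the chromosome end one more start is added so the union of windows
    is exactly [0, length).
    """
    if not size >= step >= 1:
        raise ValueError("need size >= step >= 1")
    if length <= 0:
        return np.empty(0, dtype=np.int64)
    starts = np.arange(0, max(length - step, 0) + 1, step, dtype=np.int64)
    last_end = min(starts[-1] + size, length)
    if last_end < length:
        starts = np.append(starts, starts[-1] + step)
    return starts


def tile_windows(chrom_lengths: dict[str, int], size: int = DEFAULT_WINDOW,
                 step: int = DEFAULT_STEP) -> pd.DataFrame:
    """All windows of the genome as a (chrom, start, end) frame."""
    frames = []
    for chrom, length in chrom_lengths.items():
        starts = window_starts(length, size, step)
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "start": starts,
            "end": np.minimum(starts + size, length),
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# window aggregation
# ---------------------------------------------------------------------------

def aggregate_windows(samples_a: Sequence[pd.DataFrame],
                      samples_b: Sequence[pd.DataFrame],
                      context: str,
                      chrom_lengths: dict[str, int],
                      size: int = DEFAULT_WINDOW,
                      step: int = DEFAULT_STEP,
                      min_site_depth: int = DEFAULT_MIN_SITE_DEPTH
                      ) -> pd.DataFrame:
    """Pool per-site counts of one context into sliding windows.

    A cytosine contributes only when its coverage, pooled across
    replicates, is >= min_site_depth in BOTH groups.  Returns one row
    per window that contains at least one contributing site, with
    pooled counts M/N per group, levels, and the level difference
    diff = level_B - level_A in percentage points.
    """
    per_group = []
    for label, samples in (("A", samples_a), ("B", samples_b)):
        parts = []
        for df in samples:
            sub = df.loc[df["context"] == context,
                         ["chrom", "pos", "strand", "n_meth", "n_unmeth"]]
            parts.append(sub)
        grp = pd.concat(parts, ignore_index=True)
        grp = (grp.groupby(["chrom", "pos", "strand"], observed=True)
               [["n_meth", "n_unmeth"]].sum().reset_index())
        grp["cov"] = grp["n_meth"] + grp["n_unmeth"]
        per_group.append(grp.rename(columns={
            "n_meth": f"M_{label}", "cov": f"N_{label}"})
            .drop(columns="n_unmeth"))

    sites = per_group[0].merge(per_group[1], on=["chrom", "pos", "strand"],
                               how="inner")
    sites = sites[(sites["N_A"] >= min_site_depth)
                  & (sites["N_B"] >= min_site_depth)]
    if sites.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "context",
                                     "n_cytosines", "M_A", "N_A", "M_B",
                                     "N_B", "level_A", "level_B", "diff"])

    # each site can fall in up to ceil(size/step) overlapping windows
    n_off = -(-size // step)
    last_start = {c: window_starts(l, size, step)[-1]
                  for c, l in chrom_lengths.items() if l > 0}
    sites = sites.reset_index(drop=True)
    pos = sites["pos"].to_numpy()
    chrom_codes, chrom_names = pd.factorize(sites["chrom"])
    last = np.array([last_start.get(c, -1) for c in chrom_names])

    pieces = []
    for k in range(n_off):
        widx = pos // step - k
        start = widx * step
        ok = (widx >= 0) & (pos < start + size) & (start <= last[chrom_codes])
        if not ok.any():
            continue
        piece = sites.loc[ok, ["chrom", "M_A", "N_A", "M_B", "N_B"]].copy()
        piece["start"] = start[ok]
        pieces.append(piece)
    assigned = pd.concat(pieces, ignore_index=True)

    win = (assigned.groupby(["chrom", "start"], observed=True)
           .agg(n_cytosines=("M_A", "size"), M_A=("M_A", "sum"),
                N_A=("N_A", "sum"), M_B=("M_B", "sum"), N_B=("N_B", "sum"))
           .reset_index())
    lengths = win["chrom"].map(chrom_lengths)
    win["end"] = np.minimum(win["start"] + size, lengths)
    win["context"] = context
    win["level_A"] = 100.0 * win["M_A"] / win["N_A"]
    win["level_B"] = 100.0 * win["M_B"] / win["N_B"]
    win["diff"] = win["level_B"] - win["level_A"]
    win = win.sort_values(["chrom", "start"], kind="mergesort",
                          ignore_index=True)
    return win[["chrom", "start", "end", "context", "n_cytosines",
                "M_A", "N_A", "M_B", "N_B", "level_A", "level_B", "diff"]]


# ---------------------------------------------------------------------------
# the window test
# ---------------------------------------------------------------------------

def gtest_pvalues(M_A, N_A, M_B, N_B):
    """Vectorised 2x2 G-test (= binomial-GLM likelihood-ratio test).

    Table per window: [[M_A, N_A - M_A], [M_B, N_B - M_B]].  Windows
    with N = 0 in either group yield NaN (no test); degenerate margins
    (both groups all-methylated or all-unmethylated) give p = 1.
    """
    M_A, N_A, M_B, N_B = (np.asarray(x, dtype=float)
                          for x in (M_A, N_A, M_B, N_B))
    U_A, U_B = N_A - M_A, N_B - M_B
    tot = N_A + N_B
    with np.errstate(divide="ignore", invalid="ignore"):
        cm = (M_A + M_B) / tot          # pooled methylated proportion
        cu = (U_A + U_B) / tot
        g = 2.0 * (xlogy(M_A, M_A / (N_A * cm))
                   + xlogy(U_A, U_A / (N_A * cu))
                   + xlogy(M_B, M_B / (N_B * cm))
                   + xlogy(U_B, U_B / (N_B * cu)))
    g = np.where(np.isfinite(g), np.maximum(g, 0.0), 0.0)
    p = stats.chi2.sf(g, df=1)
    p = np.where((N_A == 0) | (N_B == 0), np.nan, p)
    return p


def window_test(counts_a: Sequence[tuple[int, int]],
                counts_b: Sequence[tuple[int, int]]) -> float:
    """Likelihood-ratio p-value for one window from per-replicate counts.

    Each group is a sequence of (n_methylated, coverage) pairs, one per
    replicate.  Replicates are i.i.d. binomial observations within a
    group, so they pool; with one observation per group this is exactly
    the 2x2 G-test.
    """
    ma = sum(m for m, _ in counts_a)
    na = sum(n for _, n in counts_a)
    mb = sum(m for m, _ in counts_b)
    nb = sum(n for _, n in counts_b)
    if na == 0 or nb == 0:
        raise ValueError("zero total coverage in a group")
    return float(gtest_pvalues(ma, na, mb, nb))


def test_windows(win: pd.DataFrame) -> pd.DataFrame:
    """Add p_value and q_value columns to an aggregated window frame."""
    out = win.copy()
    out["p_value"] = gtest_pvalues(out["M_A"], out["N_A"],
                                   out["M_B"], out["N_B"])
    out["q_value"] = slim_qvalues(out["p_value"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# q-values
# ---------------------------------------------------------------------------

def estimate_pi0(p: np.ndarray,
                 lambdas: Sequence[float] = (0.4, 0.5, 0.6, 0.7, 0.8)
                 ) -> float:
    """Fraction of true nulls, Storey-style: #{p > lambda}/(n(1-lambda))
    averaged over a lambda grid and clipped to (0, 1]."""
    p = np.asarray(p, dtype=float)
    n = p.size
    if n == 0:
        return 1.0
    ests = [np.sum(p > lam) / (n * (1.0 - lam)) for lam in lambdas]
    return float(min(1.0, max(np.mean(ests), 1.0 / n)))


def slim_qvalues(p: np.ndarray, pi0: float | None = None) -> np.ndarray:
    """pi0-adjusted step-up q-values: q_(i) = pi0 * n * p_(i) / i, made
    monotone non-decreasing in p.  With pi0 = 1 this is exactly
    Benjamini-Hochberg.  NaN p-values propagate as NaN and are ignored
    for ranking and pi0 estimation.
    """
    p = np.asarray(p, dtype=float)
    valid = ~np.isnan(p)
    pv = p[valid]
    if pv.size and (pv.min() < 0 or pv.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    if pv.size == 0:
        return q
    if pi0 is None:
        pi0 = estimate_pi0(pv)
    if not 0 < pi0 <= 1:
        raise ValueError(f"pi0 must be in (0, 1]: {pi0}")
    n = pv.size
    order = np.argsort(pv, kind="mergesort")
    ranked = pi0 * (pv[order] / (np.arange(1, n + 1) / n))
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    qv = np.empty(n)
    qv[order] = np.minimum(ranked, 1.0)
    q[valid] = qv
    return q


# ---------------------------------------------------------------------------
# filtering and merging
# ---------------------------------------------------------------------------

def filter_and_merge(windows: pd.DataFrame,
                     min_diff: float = DEFAULT_MIN_DIFF,
                     max_q: float = DEFAULT_MAX_Q,
                     merge_gap: int = DEFAULT_MERGE_GAP,
                     min_cytosines: int = DEFAULT_MIN_CYTOSINES
                     ) -> pd.DataFrame:
    """Merge significant bins into DMRs.

    A bin passes when it has >= min_cytosines contributing cytosines,
    |diff| >= min_diff points and q <= max_q.  Passing bins of the same
    chromosome, context and direction merge when the gap to the previous
    bin (next.start - prev.end) is <= merge_gap; overlapping bins always
    merge.  mean_diff is the coverage-weighted mean of member-bin diffs.
    """
    required = ["chrom", "start", "end", "context", "n_cytosines",
                "diff", "q_value", "N_A", "N_B"]
    for col in required:
        if col not in windows.columns:
            raise ValueError(f"windows frame lacks column {col!r}")
    by_chrom = windows.groupby("chrom", observed=True)["start"]
    if not by_chrom.apply(lambda s: s.is_monotonic_increasing).all():
        raise ValueError("windows must be sorted by chrom, start")

    ok = ((windows["n_cytosines"] >= min_cytosines)
          & (windows["diff"].abs() >= min_diff)
          & (windows["q_value"] <= max_q))
    bins = windows[ok].copy()
    cols = ["chrom", "start", "end", "context", "direction",
            "mean_diff", "min_q", "n_bins"]
    if bins.empty:
        return pd.DataFrame(columns=cols)
    bins["direction"] = np.where(bins["diff"] > 0, "hyper", "hypo")
    bins["weight"] = bins["N_A"] + bins["N_B"]

    dmrs = []
    for (chrom, context, direction), grp in bins.groupby(
            ["chrom", "context", "direction"], observed=True, sort=False):
        grp = grp.sort_values("start", kind="mergesort")
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        run_end = np.maximum.accumulate(ends)
        new_run = np.ones(len(grp), dtype=bool)
        new_run[1:] = starts[1:] - run_end[:-1] > merge_gap
        run_id = np.cumsum(new_run)
        for _, run in grp.assign(_run=run_id).groupby("_run"):
            w = run["weight"].to_numpy(dtype=float)
            dmrs.append({
                "chrom": chrom,
                "start": int(run["start"].min()),
                "end": int(run["end"].max()),
                "context": context,
                "direction": direction,
                "mean_diff": float(np.average(run["diff"], weights=w)),
                "min_q": float(run["q_value"].min()),
                "n_bins": len(run),
            })
    out = pd.DataFrame(dmrs, columns=cols)
    return out.sort_values(["chrom", "start", "context", "direction"],
                           kind="mergesort", ignore_index=True)


def call_dmrs(samples_a: Sequence[pd.DataFrame],
              samples_b: Sequence[pd.DataFrame],
              chrom_lengths: dict[str, int],
              contexts: Sequence[str] = ("CG", "CHG", "CHH"),
              size: int = DEFAULT_WINDOW, step: int = DEFAULT_STEP,
              min_site_depth: int = DEFAULT_MIN_SITE_DEPTH,
              min_cytosines: int = DEFAULT_MIN_CYTOSINES,
              min_diff: float = DEFAULT_MIN_DIFF,
              max_q: float = DEFAULT_MAX_Q,
              merge_gap: int = DEFAULT_MERGE_GAP,
              pi0: float | None = None
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full window scan: returns (tested windows, merged DMRs).

    Contexts are tested separately, each with its own q-value
    correction, so one genomic interval can yield up to three
    context-specific DMRs.
    """
    wins, dmrs = [], []
    for context in contexts:
        win = aggregate_windows(samples_a, samples_b, context,
                                chrom_lengths, size, step, min_site_depth)
        win = win[win["n_cytosines"] >= min_cytosines].reset_index(drop=True)
        if win.empty:
            continue
        win["p_value"] = gtest_pvalues(win["M_A"], win["N_A"],
                                       win["M_B"], win["N_B"])
        win["q_value"] = slim_qvalues(win["p_value"].to_numpy(), pi0=pi0)
        wins.append(win)
        merged = filter_and_merge(win, min_diff, max_q, merge_gap,
                                  min_cytosines)
        if not merged.empty:
            dmrs.append(merged)
    win_cols = ["chrom", "start", "end", "context", "n_cytosines", "M_A",
                "N_A", "M_B", "N_B", "level_A", "level_B", "diff",
                "p_value", "q_value"]
    dmr_cols = ["chrom", "start", "end", "context", "direction",
                "mean_diff", "min_q", "n_bins"]
    win_out = (pd.concat(wins, ignore_index=True) if wins
               else pd.DataFrame(columns=win_cols))
    dmr_out = (pd.concat(dmrs, ignore_index=True) if dmrs
               else pd.DataFrame(columns=dmr_cols))
    dmr_out = dmr_out.sort_values(["chrom", "start", "context"],
                                  kind="mergesort", ignore_index=True)
    return win_out, dmr_out


def diff_distribution(dmrs: pd.DataFrame,
                      features: pd.DataFrame | None = None,
                      bin_width: float = 5.0) -> pd.DataFrame:
    """Histogram of DMR mean_diff values, optionally restricted to DMRs
    overlapping a feature subset (frame with chrom/start/end)."""
    sub = dmrs
    if features is not None:
        keep = np.zeros(len(dmrs), dtype=bool)
        for chrom, feats in features.groupby("chrom", observed=True):
            mask = dmrs["chrom"] == chrom
            if not mask.any():
                continue
            ds = dmrs.loc[mask, "start"].to_numpy()[:, None]
            de = dmrs.loc[mask, "end"].to_numpy()[:, None]
            fs = feats["start"].to_numpy()[None, :]
            fe = feats["end"].to_numpy()[None, :]
            keep[np.flatnonzero(mask)] = (
                (ds < fe) & (fs < de)).any(axis=1)
        sub = dmrs[keep]
    edges = np.arange(-100.0, 100.0 + bin_width, bin_width)
    counts, _ = np.histogram(sub["mean_diff"], bins=edges)
    return pd.DataFrame({"diff_low": edges[:-1], "diff_high": edges[1:],
                         "n_dmrs": counts})


def dmrs_to_bed(dmrs: pd.DataFrame) -> pd.DataFrame:
    """BED6 view of a DMR table; score = min(1000, -10*log10(min_q))."""
    with np.errstate(divide="ignore"):
        score = np.minimum(1000, -10.0 * np.log10(
            np.maximum(dmrs["min_q"], 1e-300)))
    return pd.DataFrame({
        "chrom": dmrs["chrom"], "start": dmrs["start"], "end": dmrs["end"],
        "name": dmrs["context"] + "_" + dmrs["direction"],
        "score": score.astype(int),
        "strand": ".",
    })
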