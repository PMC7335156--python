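"""Bisulphite conversion-error estimation and binomial methylcytosine calling.

After bisulphite conversion, an unmethylated cytosine reads as T and a
methylated one as C, so the C-call count at a site with coverage N is
Binomial(N, m + (1-m)*eps) where m is the true methylation level and eps
the conversion error.  A site is declared a methylcytosine when its
C-call count is binomially improbable under the error rate alone:
upper-tail p = P(X >= n_meth | X ~ Bin(N, eps)) <= alpha at depth
N >= min_depth.  Defaults alpha = 1e-4, min_depth = 5.

eps is estimated from the chloroplast chromosome, which is naturally
unmethylated, by pooling all its cytosines across contexts and strands:
eps = sum(n_meth) / sum(coverage).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_MIN_DEPTH = 5
DEFAULT_ALPHA = 1e-4


class EstimationError(ValueError):
    pass


def estimate_conversion_error(chloroplast: pd.DataFrame) -> float:
    """Pooled non-conversion rate over chloroplast cytosines.

    ``chloroplast`` must already be restricted to the chloroplast
    chromosome (all contexts, both strands).
    """
    total = int(chloroplast["n_meth"].sum() + chloroplast["n_unmeth"].sum())
    if total == 0:
        raise EstimationError("no covered chloroplast cytosines")
    eps = float(chloroplast["n_meth"].sum()) / total
    if not 0.0 <= eps < 1.0:
        raise EstimationError(f"implausible conversion error {eps}")
    return eps


def binomial_pvalue(n_meth, coverage, eps):
    """Exact upper-tail binomial probability P(X >= n_meth | N, eps).

    Vectorised; evaluated through the regularised incomplete beta
    function (scipy's binomial survival function), which is stable deep
    in the tail.  p = 1 whenever n_meth = 0.
    """
    n_meth = np.asarray(n_meth)
    coverage = np.asarray(coverage)
    if np.any(n_meth < 0) or np.any(n_meth > coverage):
        raise ValueError("need 0 <= n_meth <= coverage")
    if not 0.0 <= eps < 1.0:
        raise ValueError(f"conversion error must be in [0, 1): {eps}")
    # sf(k-1) = P(X >= k); sf handles k-1 = -1 -> 1 exactly
    p = stats.binom.sf(n_meth - 1, coverage, eps)
    return p if p.shape else float(p)


def call_methylcytosines(sample: pd.DataFrame, eps: float,
                         min_depth: int = DEFAULT_MIN_DEPTH,
                         alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Annotate a cytosine table with level, p-value and the mC call.

    Adds columns: ``coverage``; ``level`` (percent, NaN at zero
    coverage); ``p_value`` and boolean ``called``.  Every covered site
    keeps its observed level whether or not it is called.
    """
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1]: {alpha}")
    out = sample.copy()
    cov = (out["n_meth"] + out["n_unmeth"]).to_numpy()
    out["coverage"] = cov
    with np.errstate(invalid="ignore"):
        out["level"] = np.where(cov > 0, 100.0 * out["n_meth"] / cov, np.nan)
    out["p_value"] = binomial_pvalue(out["n_meth"].to_numpy(), cov, eps)
    out["called"] = (cov >= min_depth) & (out["p_value"] <= alpha)
    return out


def context_summary(called: pd.DataFrame,
                    min_depth: int = DEFAULT_MIN_DEPTH,
                    by_strand: bool = False) -> pd.DataFrame:
    """Per-context (optionally per-strand) methylation summary.

    ``called`` is the output of :func:`call_methylcytosines`.  Callable
    sites are those with coverage >= min_depth; the percentage of
    methylcytosines uses callable sites as denominator.  Level quartiles
    and mean are computed over called mCs only.
    """
    keys = ["context", "strand"] if by_strand else ["context"]
    rows = []
    for key, grp in called.groupby(keys, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        callable_ = grp[grp["coverage"] >= min_depth]
        mcs = callable_[callable_["called"]]
        row = dict(zip(keys, key))
        row["n_callable"] = len(callable_)
        row["n_methylated"] = len(mcs)
        row["pct_methylcytosines"] = (
            100.0 * len(mcs) / len(callable_) if len(callable_) else np.nan)
        levels = mcs["level"]
        row.update({
            "level_mean": levels.mean() if len(mcs) else np.nan,
            "level_q25": levels.quantile(0.25) if len(mcs) else np.nan,
            "level_median": levels.median() if len(mcs) else np.nan,
            "level_q75": levels.quantile(0.75) if len(mcs) else np.nan,
        })
        rows.append(row)
    return pd.DataFrame(rows).sort_values(keys, ignore_index=True)
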