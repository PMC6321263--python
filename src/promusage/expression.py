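"""Gene-level normalization, expression filtering, DEG calling, set algebra.

Count matrices are pandas DataFrames with gene ids as the index and sample
ids as columns.  Depth normalization uses the median-of-ratios size factor:
for sample *j*, s_j = median over genes of count[g,j] / geomean_g, the median
taken over genes whose geometric mean across samples is positive.  FPKM and
TPM follow the usual definitions:

    FPKM[g,j] = count[g,j] * 1e9 / (length_g * total_j)
    TPM[g,j]  = rate_g / sum_g(rate_g) * 1e6,   rate_g = count[g,j] / length_g

A gene is "expressed" if its size-factor-normalized count exceeds a threshold
(default 3) in at least one sample.

Differential expression uses fold-change of group means of normalized counts
(pseudocount 1) with a two-sided Welch t-test on log2(normalized + 1); a gene
is a DEG when |log2 fold-change| > 1 and p < 0.05.  This deliberately simple
test stands in for a negative-binomial GLM and is labelled as such: it trades
power at low counts for transparency and zero fitted hyperparameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "size_factors_median_of_ratios",
    "normalize_expression",
    "expressed_filter",
    "call_degs",
    "deg_set_algebra",
    "SetOverlapSummary",
]

EXPRESSED_THRESHOLD = 3.0
DEG_LFC_THRESHOLD = 1.0  # |log2 FC| > 1, i.e. fold-change > 2
DEG_ALPHA = 0.05


def _check_counts(m: pd.DataFrame) -> None:
    if (m.to_numpy() < 0).any():
        raise ValueError("count matrix has negative entries")


def size_factors_median_of_ratios(m: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (one positive factor per sample)."""
    _check_counts(m)
    x = m.to_numpy(float)
    with np.errstate(divide="ignore"):
        logx = np.log(x)
    log_geomean = logx.mean(axis=1)  # -inf for any gene with a zero
    usable = np.isfinite(log_geomean)
    if not usable.any():
        raise ValueError(
            "no gene has a nonzero count in every sample; size factors undefined"
        )
    geomean = np.exp(log_geomean[usable])
    ratios = x[usable] / geomean[:, None]
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=m.columns, name="size_factor")


def normalize_expression(
    m: pd.DataFrame, lengths: Mapping[str, float] | pd.Series, method: str
) -> pd.DataFrame:
    """FPKM or TPM matrix from raw counts and gene lengths (bases)."""
    _check_counts(m)
    method = method.upper()
    if method not in ("FPKM", "TPM"):
        raise ValueError(f"method must be FPKM or TPM, got {method!r}")
    lengths = pd.Series(lengths).reindex(m.index)
    if lengths.isna().any():
        missing = list(m.index[lengths.isna()])[:5]
        raise ValueError(f"missing gene lengths, e.g. {missing}")
    if (lengths < 1).any():
        raise ValueError("gene lengths must be >= 1 base")
    totals = m.sum(axis=0)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise ValueError(f"zero column total for sample(s) {bad}")
    rate = m.div(lengths, axis=0)
    if method == "FPKM":
        out = rate.div(totals, axis=1) * 1e9
    else:
        out = rate.div(rate.sum(axis=0), axis=1) * 1e6
    out.attrs["method"] = method
    return out


def expressed_filter(
    m: pd.DataFrame, s: pd.Series, threshold: float = EXPRESSED_THRESHOLD
) -> set[str]:
    """Genes with normalized count (count / size factor) > threshold in >=1 sample."""
    if not set(m.columns).issubset(set(s.index)):
        raise ValueError("size factors do not cover all samples")
    norm = m.div(s.reindex(m.columns), axis=1)
    keep = (norm > threshold).any(axis=1)
    return set(m.index[keep])


def call_degs(
    m: pd.DataFrame,
    s: pd.Series,
    group_a: Sequence[str],
    group_b: Sequence[str],
    lfc_threshold: float = DEG_LFC_THRESHOLD,
    alpha: float = DEG_ALPHA,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene differential expression of *group_b* relative to *group_a*.

    Returns a DataFrame indexed by gene with columns ``log2_fold_change``,
    ``p_value`` and ``is_deg``.  Fold-change is computed from group means of
    size-factor-normalized counts with a pseudocount; the p-value is a
    two-sided Welch t on log2(normalized + pseudocount).
    """
    for name, g in (("group_a", group_a), ("group_b", group_b)):
        if len(g) < 2:
            raise ValueError(f"{name}: need >=2 samples, got {len(g)}")
    norm = m.div(s.reindex(m.columns), axis=1)
    na = norm[list(group_a)].to_numpy(float)
    nb = norm[list(group_b)].to_numpy(float)

    lfc = np.log2(nb.mean(axis=1) + pseudocount) - np.log2(
        na.mean(axis=1) + pseudocount
    )
    la, lb = np.log2(na + pseudocount), np.log2(nb + pseudocount)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(lb, la, axis=1, equal_var=False)
    # zero variance in both groups: p=1 when means agree, else minimal p
    degenerate = np.isnan(p)
    if degenerate.any():
        same = np.isclose(lb.mean(axis=1), la.mean(axis=1))
        p = np.where(degenerate & same, 1.0, p)
        p = np.where(degenerate & ~same, np.finfo(float).tiny, p)
        t = np.where(degenerate, 0.0, t)
    is_deg = (np.abs(lfc) > lfc_threshold) & (p < alpha)
    return pd.DataFrame(
        {"log2_fold_change": lfc, "p_value": p, "is_deg": is_deg}, index=m.index
    )


@dataclass
class SetOverlapSummary:
    """Pairwise and global overlap structure of named gene sets.

    Shared percentages are reported against two denominators because both are
    in common use: the union of the pair, and the summed sizes of the pair.
    """

    pairwise: pd.DataFrame
    global_intersection: int
    global_union: int


def deg_set_algebra(deg_sets: Mapping[str, set[str]]) -> SetOverlapSummary:
    """Intersection/union sizes and shared percentages for >=2 named sets."""
    if len(deg_sets) < 2:
        raise ValueError("need >=2 named sets")
    names = list(deg_sets)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            sa, sb = set(deg_sets[a]), set(deg_sets[b])
            shared = len(sa & sb)
            union = len(sa | sb)
            total = len(sa) + len(sb)
            rows.append(
                {
                    "set_a": a,
                    "set_b": b,
                    "size_a": len(sa),
                    "size_b": len(sb),
                    "shared": shared,
                    "union": union,
                    "shared_pct_of_union": 100.0 * shared / union if union else 0.0,
                    "shared_pct_of_total": 100.0 * shared / total if total else 0.0,
                }
            )
    all_sets = [set(s) for s in deg_sets.values()]
    return SetOverlapSummary(
        pairwise=pd.DataFrame(rows),
        global_intersection=len(set.intersection(*all_sets)),
        global_union=len(set.union(*all_sets)),
    )
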