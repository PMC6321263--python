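"""Promoter-usage proportions and between-group comparison.

The usage proportion of promoter *i* in a sample is the read count of its
first exon divided by the total over all first exons of the gene — a
read-mass proxy for relative promoter activity.  Proportions are computed per
sample and compared between groups with a two-sided Welch (unequal-variance)
t-test on the per-sample proportions; an arcsine-square-root transform is
available as an option.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .counting import FirstExonCounts, rpm_normalize

__all__ = ["UsageComparison", "usage_proportions", "compare_usage", "compare_all"]


@dataclass
class UsageComparison:
    """Welch t-test of one promoter's usage between two groups."""

    promoter_id: str
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    t_stat: float
    p_value: float
    n_a: int
    n_b: int


def usage_proportions(
    counts: Iterable[FirstExonCounts],
    sample_groups: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-sample usage proportions from first-exon counts.

    Returns a long-format table with columns ``sample_id, group_id,
    promoter_id, count, rpm, proportion``.  A sample whose first-exon total is
    zero gets NaN proportions (flagged with a warning) and is skipped by the
    group comparisons.
    """
    counts = list(counts)
    if not counts:
        raise ValueError("no samples given")
    pid_sets = {tuple(fc.counts) for fc in counts}
    if len(pid_sets) != 1:
        raise ValueError(f"samples disagree on promoter ids: {pid_sets}")

    rows = []
    for fc in counts:
        total = fc.total
        if total == 0:
            warnings.warn(
                f"sample {fc.sample_id}: zero first-exon reads; "
                "proportions undefined",
                stacklevel=2,
            )
        rpm = rpm_normalize(fc).rpm if fc.library_size > 0 else None
        group = sample_groups.get(fc.sample_id, "") if sample_groups else ""
        for pid, c in fc.counts.items():
            rows.append(
                {
                    "sample_id": fc.sample_id,
                    "group_id": group,
                    "promoter_id": pid,
                    "count": c,
                    "rpm": rpm[pid] if rpm is not None else np.nan,
                    "proportion": c / total if total > 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Welch t; degenerate zero-variance cases handled explicitly."""
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, b.mean() - a.mean()), np.finfo(float).tiny
    t, p = stats.ttest_ind(b, a, equal_var=False)
    return float(t), float(p)


def compare_usage(
    table: pd.DataFrame,
    group_a: str,
    group_b: str,
    promoter_id: str,
    transform: str | None = None,
) -> UsageComparison:
    """Welch t-test of *promoter_id* usage, *group_b* versus *group_a*.

    ``transform='arcsine'`` applies arcsin(sqrt(p)) before testing (variance
    stabilization for proportions); means are always reported on the raw
    proportion scale.  Samples with undefined proportions are excluded.
    """
    sub = table[(table["promoter_id"] == promoter_id) & table["proportion"].notna()]
    vals = {}
    for g in (group_a, group_b):
        x = sub.loc[sub["group_id"] == g, "proportion"].to_numpy(float)
        if len(x) < 2:
            raise ValueError(
                f"group {g!r}: need >=2 samples with defined proportions, got {len(x)}"
            )
        vals[g] = x
    a, b = vals[group_a], vals[group_b]
    ta, tb = a, b
    if transform == "arcsine":
        ta, tb = np.arcsin(np.sqrt(a)), np.arcsin(np.sqrt(b))
    elif transform is not None:
        raise ValueError(f"unknown transform {transform!r}")
    t, p = _welch(ta, tb)
    return UsageComparison(
        promoter_id=promoter_id,
        group_a=group_a,
        group_b=group_b,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        t_stat=t,
        p_value=p,
        n_a=len(a),
        n_b=len(b),
    )


def compare_all(
    table: pd.DataFrame, group_a: str, group_b: str, transform: str | None = None
) -> pd.DataFrame:
    """compare_usage for every promoter; one row per promoter."""
    rows = [
        vars(compare_usage(table, group_a, group_b, pid, transform=transform))
        for pid in table["promoter_id"].unique()
    ]
    return pd.DataFrame(rows)
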