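"""Hypergeometric over-representation of annotation terms, with BH correction.

For a term annotating K of the N background genes, and a selected gene set of
size n with k members in the term, the enrichment p-value is the upper tail
P(X >= k) of the hypergeometric distribution — computed by log-space
summation of the pmf for numerical stability at extreme tails.  Raw p-values
over the tested terms are Benjamini–Hochberg adjusted, and each term gets a
richness factor k/K: the fraction of the term's background genes that the
selected set hits.

Only over-representation is tested (no depletion) and terms are treated
independently: no ontology-graph propagation is applied, so annotation maps
should be pre-propagated if parent-term inheritance is wanted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "AnnotationMap",
    "hypergeom_upper_tail",
    "bh_adjust",
    "enrich",
    "read_annotation_tsv",
]

DEFAULT_MIN_TERM_SIZE = 5


@dataclass
class AnnotationMap:
    """term_id -> annotated genes, with an explicit background population."""

    terms: dict[str, frozenset[str]]
    background: frozenset[str]

    def __post_init__(self) -> None:
        stray = set().union(*self.terms.values(), set()) - self.background
        if stray:
            raise ValueError(
                f"{len(stray)} annotated gene(s) missing from background, "
                f"e.g. {sorted(stray)[:5]}"
            )


def read_annotation_tsv(path: str, background: Iterable[str] | None = None) -> AnnotationMap:
    """Long-format annotation TSV (term_id <tab> gene_id, optional header).

    Without an explicit *background* the distinct annotated genes serve as
    the population.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["term_id", "gene_id"], dtype=str)
    if len(df) and df.iloc[0, 0] == "term_id":
        df = df.iloc[1:]
    terms = {
        t: frozenset(g)
        for t, g in df.groupby("term_id", sort=False)["gene_id"]
    }
    bg = frozenset(background) if background is not None else frozenset(df["gene_id"])
    return AnnotationMap(terms=terms, background=bg)


def _lchoose(a: int, b: int) -> float:
    return math.lgamma(a + 1) - math.lgamma(b + 1) - math.lgamma(a - b + 1)


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws).

    Summed in log space (log-pmf terms combined by a max-shifted exp sum) so
    extreme tails keep full relative precision.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"require 0 <= K,n <= N; got K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"require 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if k == 0:
        return 1.0
    lo, hi = max(k, n - (N - K)), min(K, n)
    if lo > hi:
        return 0.0 if k > 0 else 1.0
    denom = _lchoose(N, n)
    logs = [
        _lchoose(K, i) + _lchoose(N - K, n - i) - denom for i in range(lo, hi + 1)
    ]
    m = max(logs)
    p = math.exp(m) * sum(math.exp(x - m) for x in logs)
    return min(p, 1.0)


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, returned in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def enrich(
    gene_set: Iterable[str],
    annotation: AnnotationMap,
    min_term_size: int = DEFAULT_MIN_TERM_SIZE,
) -> pd.DataFrame:
    """Test every term with K >= min_term_size for over-representation.

    Genes outside the background are dropped with a warning.  Returns one row
    per tested term, ascending by p-value, with columns ``term_id, k, K, n,
    N, p_value, q_value, richness_factor``.
    """
    genes = set(gene_set)
    stray = genes - annotation.background
    if stray:
        warnings.warn(
            f"{len(stray)} gene(s) not in background dropped from the query set",
            stacklevel=2,
        )
        genes -= stray
    if not genes:
        raise ValueError("gene set is empty after intersecting with background")

    N = len(annotation.background)
    n = len(genes)
    rows = []
    for term, members in annotation.terms.items():
        K = len(members)
        if K < min_term_size:
            continue
        k = len(genes & members)
        rows.append(
            {
                "term_id": term,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_value": hypergeom_upper_tail(k, K, n, N),
                "richness_factor": k / K,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["term_id", "k", "K", "n", "N", "p_value", "q_value", "richness_factor"]
        )
    df = pd.DataFrame(rows)
    df["q_value"] = bh_adjust(df["p_value"])
    df = df.sort_values("p_value", kind="stable", ignore_index=True)
    return df[["term_id", "k", "K", "n", "N", "p_value", "q_value", "richness_factor"]]
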