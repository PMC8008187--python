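"""Fisher's-exact (hypergeometric) gene-set enrichment and the
per-week top-N / union / clustered heatmap construction.

Enrichment of a DEG list against a gene-set collection is the one-sided
hypergeometric tail ``P(X >= k)`` with the filtered expression universe
as background.  The temporal heatmap takes each week's top-N sets by raw
p, forms the union of rows over weeks, fills cells with ``-log10 p``,
and orders the week columns by average-linkage hierarchical clustering
on Euclidean distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist

from .containers import GeneSetCollection
from .errors import ValidationError
from .diffexpr import bh_adjust


@dataclass
class EnrichmentResult:
    """One tested gene set.

    k = DEGs in the set (within the universe), K = set size within the
    universe, n = DEGs in the universe, N = universe size.
    """

    name: str
    k: int
    K: int
    n: int
    N: int
    pvalue: float
    padj: float = float("nan")


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """One-sided enrichment p-value ``P(X >= k)`` for X ~ Hypergeom(N, K, n)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def fisher_enrichment(
    deg_set: set[str] | list[str],
    universe: set[str] | list[str],
    collection: GeneSetCollection,
) -> list[EnrichmentResult]:
    """Test every collection set for DEG over-representation.

    Sets are intersected with the universe first; empty intersections are
    skipped.  Results are BH-adjusted across tested sets and sorted by
    ascending p, ties by set name.
    """
    universe_set = set(universe)
    degs = set(deg_set)
    outside = degs - universe_set
    if outside:
        raise ValidationError(
            f"DEG(s) outside the universe: {sorted(outside)[:5]}"
        )
    N = len(universe_set)
    n = len(degs)
    results: list[EnrichmentResult] = []
    for name, members in collection:
        in_universe = set(members) & universe_set
        K = len(in_universe)
        if K == 0:
            continue
        k = len(in_universe & degs)
        results.append(
            EnrichmentResult(name, k, K, n, N, hypergeom_tail(k, N, K, n))
        )
    if results:
        padj = bh_adjust([r.pvalue for r in results])
        for r, q in zip(results, padj):
            r.padj = float(q)
    results.sort(key=lambda r: (r.pvalue, r.name))
    return results


def enrichment_heatmap(
    per_week: dict[int, list[EnrichmentResult]],
    top_n: int = 40,
) -> tuple[pd.DataFrame, list[str], list[int]]:
    """Sets x weeks matrix of ``-log10 raw p`` with clustered column order.

    Rows are the union over weeks of each week's ``top_n`` most
    significant sets (by raw p, ties by name); a set untested in a week
    (or with p = 1) contributes 0.  Columns are ordered by
    average-linkage clustering on Euclidean distance between column
    vectors (dendrogram leaf order; fewer than 3 weeks keep
    chronological order).

    Returns ``(matrix, row_names, column_order)``.
    """
    if not per_week:
        raise ValidationError("enrichment_heatmap needs at least one week")
    weeks = sorted(per_week)
    row_names: list[str] = []
    for w in weeks:
        ranked = sorted(per_week[w], key=lambda r: (r.pvalue, r.name))
        for r in ranked[:top_n]:
            if r.name not in row_names:
                row_names.append(r.name)
    row_names = sorted(row_names)
    mat = pd.DataFrame(0.0, index=row_names, columns=weeks)
    for w in weeks:
        for r in per_week[w]:
            if r.name in mat.index:
                mat.loc[r.name, w] = -np.log10(max(r.pvalue, 1e-300))
    if len(weeks) >= 3 and len(row_names) >= 1:
        cols = mat.to_numpy().T  # weeks x sets
        if np.ptp(cols) > 0:
            Z = average(pdist(cols, metric="euclidean"))
            order = [weeks[i] for i in leaves_list(Z)]
        else:
            order = weeks
    else:
        order = weeks
    return mat[order], row_names, order
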