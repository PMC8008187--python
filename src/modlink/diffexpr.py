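"""Per-time-point differential expression between diets.

Each week is tested independently: a two-sided Welch unequal-variance
t-test per gene on log2-normalized values (HFD vs CD), Benjamini-Hochberg
adjustment across genes within the week, and a DEG call at
``adjusted p < alpha`` and ``|log2fc| >= lfc_min``.  Cross-week overlap
(the Venn analysis) is computed by exact inclusion-exclusion region
counting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix
from .errors import ValidationError

log = logging.getLogger(__name__)


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch unequal-variance t-test; returns ``(t, df, p)`` (two-sided).

    Degenerate inputs follow the convention: both groups constant with
    equal means gives ``t = 0, p = 1``; both constant with unequal means
    gives ``p = 0`` with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("welch_t needs at least 2 observations per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        log.warning("welch_t: both groups constant with unequal means; p = 0")
        t = np.inf if a.mean() > b.mean() else -np.inf
        return t, float(a.size + b.size - 2), 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DEResult:
    """Differential-expression table for one (tissue, week) stratum.

    ``table`` has one row per gene: mean_hfd, mean_cd, log2fc (HFD minus
    CD on the log2-normalized scale), t, df, pvalue, padj, direction
    (up/down/ns).
    """

    week: int
    tissue: str
    alpha: float
    lfc_min: float
    table: pd.DataFrame

    @property
    def deg_genes(self) -> list[str]:
        return list(self.table.index[self.table["direction"] != "ns"])

    @property
    def n_up(self) -> int:
        return int((self.table["direction"] == "up").sum())

    @property
    def n_down(self) -> int:
        return int((self.table["direction"] == "down").sum())


def differential_expression(
    em_log: ExpressionMatrix,
    week: int,
    alpha: float = 0.05,
    lfc_min: float = 1.0,
    diets: tuple[str, str] = ("HFD", "CD"),
) -> DEResult:
    """Welch t per gene, HFD vs CD, at one week; BH across genes.

    ``em_log`` must be log2-normalized; both diets need at least two
    samples at the week.
    """
    if em_log.scale != "log2norm":
        raise ValidationError("differential_expression expects log2norm scale")
    meta = em_log.meta()
    if week not in set(meta["week"]):
        raise ValidationError(f"week {week} not present in the data")
    hfd_label, cd_label = diets
    masks = {}
    for diet in diets:
        mask = ((meta["week"] == week) & (meta["diet"] == diet)).to_numpy()
        if mask.sum() < 2:
            raise ValidationError(
                f"diet {diet!r} has {int(mask.sum())} sample(s) at week {week}; "
                "need >= 2"
            )
        masks[diet] = mask
    X = em_log.values.to_numpy(dtype=float)
    a = X[:, masks[hfd_label]]
    b = X[:, masks[cd_label]]
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    sa, sb = va / na, vb / nb
    denom = np.sqrt(sa + sb)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / denom
        df = (sa + sb) ** 2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
    p = np.where(
        np.isfinite(t),
        2.0 * stats.t.sf(np.abs(t), np.where(np.isfinite(df), df, 1.0)),
        0.0,
    )
    # both groups constant: equal means -> t=0, p=1; unequal -> p=0
    const = (va == 0) & (vb == 0)
    equal_const = const & (ma == mb)
    t = np.where(equal_const, 0.0, t)
    p = np.where(equal_const, 1.0, p)
    p = np.where(const & ~equal_const, 0.0, p)
    df = np.where(const, na + nb - 2, df)

    padj = bh_adjust(p)
    lfc = ma - mb
    sig = (padj < alpha) & (np.abs(lfc) >= lfc_min)
    direction = np.where(sig, np.where(lfc > 0, "up", "down"), "ns")
    table = pd.DataFrame(
        {
            "mean_hfd": ma,
            "mean_cd": mb,
            "log2fc": lfc,
            "t": t,
            "df": df,
            "pvalue": p,
            "padj": padj,
            "direction": direction,
        },
        index=em_log.values.index,
    )
    tissue = str(meta["tissue"].iloc[0]) if len(meta) else ""
    return DEResult(week=week, tissue=tissue, alpha=alpha, lfc_min=lfc_min, table=table)


def shared_degs(results: list[DEResult]) -> tuple[set[str], dict[tuple[int, ...], int]]:
    """DEGs shared across all weeks plus exact Venn region counts.

    Returns the intersection over all results and a dict mapping each
    non-empty week subset (tuple of weeks, sorted) to the number of genes
    DEG in exactly those weeks.  Region counts sum to the union size.
    """
    if len(results) < 2:
        raise ValidationError("shared_degs needs at least 2 results")
    sets = {r.week: set(r.deg_genes) for r in results}
    weeks = sorted(sets)
    union: set[str] = set().union(*sets.values())
    shared = set.intersection(*sets.values()) if sets else set()
    regions: dict[tuple[int, ...], int] = {}
    for r in range(1, len(weeks) + 1):
        for combo in combinations(weeks, r):
            inside = set.intersection(*(sets[w] for w in combo)) if combo else set()
            outside = set().union(*(sets[w] for w in weeks if w not in combo)) \
                if len(combo) < len(weeks) else set()
            count = len(inside - outside)
            if count:
                regions[combo] = count
    return shared, regions
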