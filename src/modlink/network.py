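"""Weighted co-expression network core, run independently per tissue.

The classical pipeline: Pearson correlation, soft-threshold power chosen
by scale-free topology fit, adjacency, topological overlap (TOM),
average-linkage clustering of ``1 - TOM`` with a static height cut,
module eigengenes (first principal component per module), eigengene-based
module merging, and module membership (kME).

The model-style entry point is :class:`CoexpressionNetwork` whose
``fit()`` returns a :class:`CoexpressionResults` carrying the partition,
eigengenes, membership matrix, and the soft-power fit table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .containers import ExpressionMatrix
from .errors import ConfigError, ValidationError

log = logging.getLogger(__name__)

UNASSIGNED = "unassigned"
FALLBACK_POWER = 6


@dataclass(frozen=True)
class NetworkConfig:
    """Parameters of the co-expression network construction.

    ``cut_height`` is a fraction of the tallest dendrogram merge;
    ``merge_cut_height`` is an eigengene dissimilarity (``1 - cor``).
    """

    signed: bool = False
    candidate_powers: tuple[int, ...] = tuple(range(1, 21))
    scale_free_r2_target: float = 0.80
    degree_bins: int = 10
    cut_height: float = 0.90
    min_module_size: int = 30
    merge_cut_height: float = 0.25

    def validate(self) -> None:
        if not (0.0 < self.cut_height < 1.0):
            raise ConfigError("cut_height must lie in (0, 1)")
        if not (0.0 <= self.merge_cut_height < 1.0):
            raise ConfigError("merge_cut_height must lie in [0, 1)")
        if self.min_module_size < 1:
            raise ConfigError("min_module_size must be >= 1")
        if not self.candidate_powers or min(self.candidate_powers) < 1:
            raise ConfigError("candidate_powers must be >= 1")
        if not (0.0 < self.scale_free_r2_target <= 1.0):
            raise ConfigError("scale_free_r2_target must lie in (0, 1]")
        if self.degree_bins < 3:
            raise ConfigError("degree_bins must be >= 3")


@dataclass
class ModulePartition:
    """Gene -> module label map; labels M1, M2, ... by decreasing size."""

    labels: pd.Series

    @property
    def module_names(self) -> list[str]:
        names = [l for l in self.labels.unique() if l != UNASSIGNED]
        return sorted(names, key=lambda l: int(l[1:]))

    def genes_in(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])

    @property
    def n_modules(self) -> int:
        return len(self.module_names)

    def sizes(self) -> pd.Series:
        return pd.Series(
            {m: len(self.genes_in(m)) for m in self.module_names}, dtype=int
        )


@dataclass
class EigengeneMatrix:
    """Module x sample eigengene values plus per-module variance explained.

    Each eigengene has unit variance and is oriented so the mean
    correlation with its member genes is non-negative.
    """

    values: pd.DataFrame
    variance_explained: pd.Series

    @property
    def module_names(self) -> list[str]:
        return list(self.values.index)


# -- elementary operations --------------------------------------------------


def pearson_matrix(X: pd.DataFrame) -> pd.DataFrame:
    """Gene x gene Pearson correlation (rows = genes, columns = samples)."""
    arr = X.to_numpy(dtype=float)
    if arr.shape[1] < 3:
        raise ValidationError("pearson_matrix needs at least 3 samples")
    sd = arr.std(axis=1)
    if (sd == 0).any():
        bad = X.index[np.flatnonzero(sd == 0)[0]]
        raise ValidationError(f"zero-variance gene {bad!r}")
    corr = np.corrcoef(arr)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(np.clip(corr, -1.0, 1.0), index=X.index, columns=X.index)


def adjacency(corr: pd.DataFrame, beta: int, signed: bool = False) -> pd.DataFrame:
    """Soft-threshold adjacency with zero diagonal.

    Unsigned: ``|r|^beta``; signed: ``((1 + r) / 2)^beta``.  The diagonal
    is set to 0 (the convention used for connectivity); TOM handles its
    own diagonal.
    """
    if beta < 1:
        raise ValidationError("beta must be >= 1")
    r = corr.to_numpy(dtype=float)
    a = ((1.0 + r) / 2.0) ** beta if signed else np.abs(r) ** beta
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=corr.index, columns=corr.columns)


def connectivity(adj: pd.DataFrame) -> pd.Series:
    """Per-gene connectivity ``k_i = sum_j a_ij`` (zero-diagonal adjacency)."""
    return adj.sum(axis=1)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Scale-free topology fit: regress log10 p(k) on log10 mean-k per bin.

    Returns ``(r2, slope)``; ``r2`` is reported as 0 when the slope is
    non-negative or the degree distribution is degenerate.
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size == 0 or np.ptp(k) == 0.0:
        return 0.0, 0.0
    logk = np.log10(k)
    edges = np.linspace(logk.min(), logk.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(logk, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(mask.sum() / k.size))
    if len(xs) < 3:
        return 0.0, 0.0
    res = stats.linregress(xs, ys)
    r2 = float(res.rvalue**2) if res.slope < 0 else 0.0
    return r2, float(res.slope)


def pick_soft_power(
    corr: pd.DataFrame, config: NetworkConfig | None = None
) -> tuple[int, pd.DataFrame]:
    """Smallest candidate power reaching the scale-free r2 target.

    Returns the chosen power and the fit table (power, r2, slope,
    mean connectivity).  Falls back to power 6 with a warning when no
    candidate reaches the target or the degree distribution is
    degenerate.
    """
    config = config or NetworkConfig()
    config.validate()
    rows = []
    chosen: int | None = None
    for beta in config.candidate_powers:
        adj = adjacency(corr, beta, signed=config.signed)
        k = connectivity(adj).to_numpy()
        r2, slope = scale_free_fit(k, config.degree_bins)
        rows.append(
            {"power": beta, "r2": r2, "slope": slope, "mean_k": float(k.mean())}
        )
        if chosen is None and r2 >= config.scale_free_r2_target:
            chosen = beta
    table = pd.DataFrame(rows).set_index("power")
    if chosen is None:
        log.warning(
            "no candidate power reached r2 >= %.2f; falling back to %d",
            config.scale_free_r2_target,
            FALLBACK_POWER,
        )
        chosen = FALLBACK_POWER
    return chosen, table


def tom_similarity(A: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of a zero-diagonal adjacency.

    ``TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)``
    with unit diagonal.
    """
    a = A.to_numpy(dtype=float).copy()
    if not np.allclose(a, a.T):
        raise ValidationError("adjacency must be symmetric")
    if a.min() < 0 or a.max() > 1:
        raise ValidationError("adjacency entries must lie in [0, 1]")
    np.fill_diagonal(a, 0.0)
    L = a @ a
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (L + a) / denom
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(np.clip(tom, 0.0, 1.0), index=A.index, columns=A.columns)


def _relabel_by_size(groups: dict[int, list[str]], all_genes: pd.Index,
                     min_size: int) -> pd.Series:
    """Assign M1.. labels by decreasing size (ties: smallest gene id)."""
    kept = [sorted(genes) for genes in groups.values() if len(genes) >= min_size]
    kept.sort(key=lambda genes: (-len(genes), genes[0]))
    labels = pd.Series(UNASSIGNED, index=all_genes, dtype=object, name="module")
    for i, genes in enumerate(kept):
        labels.loc[genes] = f"M{i + 1}"
    return labels


def detect_modules(
    tom: pd.DataFrame, config: NetworkConfig | None = None
) -> ModulePartition:
    """Average-linkage clustering of ``1 - TOM`` with a static height cut.

    The cut is at ``cut_height`` times the tallest merge.  Clusters below
    ``min_module_size`` become unassigned.  Genes are re-ordered
    canonically (lexicographic id) before clustering so the result is
    invariant to input order.
    """
    config = config or NetworkConfig()
    config.validate()
    order = sorted(tom.index)
    t = tom.loc[order, order].to_numpy(dtype=float)
    d = 1.0 - t
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    Z = average(squareform(d, checks=False))
    cut = config.cut_height * Z[:, 2].max()
    assignments = fcluster(Z, t=cut, criterion="distance")
    groups: dict[int, list[str]] = {}
    for gene, cl in zip(order, assignments):
        groups.setdefault(int(cl), []).append(gene)
    labels = _relabel_by_size(groups, tom.index, config.min_module_size)
    if (labels == UNASSIGNED).all():
        log.warning("all genes unassigned; empty partition returned")
    return ModulePartition(labels)


def module_eigengenes(
    X_log: pd.DataFrame | ExpressionMatrix,
    partition: ModulePartition,
    modules: list[str] | None = None,
) -> EigengeneMatrix:
    """First principal component per module on per-gene z-scored data.

    Each eigengene is scaled to unit variance and sign-oriented so its
    mean correlation with member genes is non-negative.
    """
    X = X_log.values if isinstance(X_log, ExpressionMatrix) else X_log
    modules = modules if modules is not None else partition.module_names
    known = set(partition.labels.unique())
    for m in modules:
        if m not in known:
            raise ValidationError(f"module {m!r} absent from partition")
    rows = {}
    var_exp = {}
    for m in modules:
        genes = partition.genes_in(m)
        block = X.loc[genes].to_numpy(dtype=float)
        mu = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, ddof=1, keepdims=True)
        if (sd == 0).any():
            bad = genes[int(np.flatnonzero(sd[:, 0] == 0)[0])]
            raise ValidationError(f"zero-variance gene {bad!r} in module {m}")
        z = (block - mu) / sd
        # first right singular vector = PC1 score profile over samples
        _, s, vt = np.linalg.svd(z, full_matrices=False)
        me = vt[0]
        me = me / me.std(ddof=1)
        corr_with_members = _rowwise_corr(z, me)
        if corr_with_members.mean() < 0:
            me = -me
        rows[m] = me
        var_exp[m] = float(s[0] ** 2 / (s**2).sum())
    values = pd.DataFrame(rows, index=X.columns).T
    return EigengeneMatrix(values, pd.Series(var_exp, dtype=float))


def _rowwise_corr(rows: np.ndarray, vec: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row with a vector."""
    rc = rows - rows.mean(axis=1, keepdims=True)
    vc = vec - vec.mean()
    denom = np.sqrt((rc**2).sum(axis=1) * (vc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return (rc @ vc) / denom


def module_membership(
    X_log: pd.DataFrame | ExpressionMatrix, me: EigengeneMatrix
) -> pd.DataFrame:
    """kME: correlation of every gene with every module eigengene."""
    X = X_log.values if isinstance(X_log, ExpressionMatrix) else X_log
    arr = X.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    if (sd == 0).any():
        bad = X.index[np.flatnonzero(sd == 0)[0]]
        raise ValidationError(f"zero-variance gene {bad!r}")
    gene_c = arr - arr.mean(axis=1, keepdims=True)
    me_arr = me.values.to_numpy(dtype=float)
    me_c = me_arr - me_arr.mean(axis=1, keepdims=True)
    num = gene_c @ me_c.T
    denom = np.outer(
        np.sqrt((gene_c**2).sum(axis=1)), np.sqrt((me_c**2).sum(axis=1))
    )
    kme = np.clip(num / denom, -1.0, 1.0)
    return pd.DataFrame(kme, index=X.index, columns=me.values.index)


def merge_modules(
    partition: ModulePartition,
    me: EigengeneMatrix,
    merge_cut_height: float = 0.25,
) -> ModulePartition:
    """Union modules whose eigengene dissimilarity ``1 - cor`` falls below
    the merge cut; labels are recomputed by size (eigengenes are the
    caller's to recompute)."""
    names = me.module_names
    if len(names) < 2:
        return ModulePartition(partition.labels.copy())
    corr = np.corrcoef(me.values.to_numpy(dtype=float))
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    Z = average(squareform(d, checks=False))
    assignments = fcluster(Z, t=merge_cut_height, criterion="distance")
    groups: dict[int, list[str]] = {}
    for name, cl in zip(names, assignments):
        groups.setdefault(int(cl), []).extend(partition.genes_in(name))
    labels = _relabel_by_size(groups, partition.labels.index, 1)
    labels[partition.labels == UNASSIGNED] = UNASSIGNED
    return ModulePartition(labels)


# -- model / results --------------------------------------------------------


@dataclass
class CoexpressionResults:
    """Fitted co-expression network for one tissue."""

    tissue: str
    power: int
    power_table: pd.DataFrame
    partition: ModulePartition
    eigengenes: EigengeneMatrix
    membership: pd.DataFrame
    config: NetworkConfig

    def summary(self) -> pd.DataFrame:
        """One row per module: size, variance explained, mean own-kME."""
        rows = []
        for m in self.partition.module_names:
            genes = self.partition.genes_in(m)
            rows.append(
                {
                    "module": m,
                    "size": len(genes),
                    "variance_explained": self.eigengenes.variance_explained[m],
                    "mean_kme": float(self.membership.loc[genes, m].mean()),
                }
            )
        return pd.DataFrame(rows).set_index("module") if rows else pd.DataFrame(
            columns=["size", "variance_explained", "mean_kme"]
        )

    def own_kme(self) -> pd.Series:
        """Each assigned gene's membership in its own module."""
        out = {}
        for m in self.partition.module_names:
            for g in self.partition.genes_in(m):
                out[g] = float(self.membership.loc[g, m])
        return pd.Series(out, dtype=float)


class CoexpressionNetwork:
    """Model object: build a co-expression network from one tissue's
    log2-normalized expression.

    Parameters
    ----------
    em_log
        Log2-normalized :class:`ExpressionMatrix` (or plain DataFrame).
    config
        :class:`NetworkConfig`; defaults are the package's standard
        unsigned network settings.
    """

    def __init__(
        self,
        em_log: ExpressionMatrix | pd.DataFrame,
        config: NetworkConfig | None = None,
    ):
        if isinstance(em_log, ExpressionMatrix):
            if em_log.scale != "log2norm":
                raise ValidationError("CoexpressionNetwork expects log2norm scale")
            self.tissue = (
                str(em_log.meta()["tissue"].iloc[0]) if em_log.n_samples else ""
            )
            self.X = em_log.values
        else:
            self.tissue = ""
            self.X = em_log
        self.config = config or NetworkConfig()
        self.config.validate()

    def fit(self) -> CoexpressionResults:
        corr = pearson_matrix(self.X)
        power, table = pick_soft_power(corr, self.config)
        adj = adjacency(corr, power, signed=self.config.signed)
        tom = tom_similarity(adj)
        partition = detect_modules(tom, self.config)
        if partition.n_modules == 0:
            empty_me = EigengeneMatrix(
                pd.DataFrame(columns=self.X.columns), pd.Series(dtype=float)
            )
            return CoexpressionResults(
                self.tissue, power, table, partition, empty_me,
                pd.DataFrame(index=self.X.index), self.config,
            )
        me = module_eigengenes(self.X, partition)
        merged = merge_modules(partition, me, self.config.merge_cut_height)
        me = module_eigengenes(self.X, merged)
        kme = module_membership(self.X, me)
        return CoexpressionResults(
            self.tissue, power, table, merged, me, kme, self.config
        )
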