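"""Readers, writers, normalization, gene filtering, and sample pairing.

File conventions
----------------
* counts: TSV, first column gene ids, header row of sample ids
* sample metadata: CSV with columns sample_id, subject_id, tissue, week,
  diet, replicate
* traits: CSV keyed by subject_id; categories: CSV with columns trait,
  category
* gene sets: GMT (name, description, tab-separated members)
* secretome: plain text, one gene id per line

Gene ids are opaque, case-sensitive strings; no annotation lookup is ever
performed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    SAMPLE_META_COLUMNS,
    ExpressionMatrix,
    GeneSetCollection,
    PairedDesign,
    TraitTable,
)
from .errors import FormatError, ValidationError

log = logging.getLogger(__name__)


def read_counts_tsv(path: str | Path, metadata_path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples count TSV plus its sample-metadata CSV.

    Raises :class:`FormatError` naming the offending row/column on
    duplicate ids, non-integer or negative counts, or samples missing
    metadata.
    """
    path = Path(path)
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    if values.index.duplicated().any():
        dupes = values.index[values.index.duplicated()].unique().tolist()
        raise FormatError(f"{path.name}: duplicated gene id(s) {dupes[:5]}")
    if values.columns.duplicated().any():
        dupes = values.columns[values.columns.duplicated()].unique().tolist()
        raise FormatError(f"{path.name}: duplicated sample id(s) {dupes[:5]}")
    arr = values.to_numpy()
    try:
        farr = arr.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path.name}: non-numeric count value ({exc})") from exc
    if np.isnan(farr).any():
        gi, si = np.argwhere(np.isnan(farr))[0]
        raise FormatError(
            f"{path.name}: missing count at gene {values.index[gi]!r}, "
            f"sample {values.columns[si]!r}"
        )
    if (farr < 0).any():
        gi, si = np.argwhere(farr < 0)[0]
        raise FormatError(
            f"{path.name}: negative count at gene {values.index[gi]!r}, "
            f"sample {values.columns[si]!r}"
        )
    if not np.allclose(farr, np.round(farr)):
        gi, si = np.argwhere(~np.isclose(farr, np.round(farr)))[0]
        raise FormatError(
            f"{path.name}: non-integer count at gene {values.index[gi]!r}, "
            f"sample {values.columns[si]!r}"
        )
    values = values.astype(np.int64)

    meta = pd.read_csv(metadata_path)
    if "sample_id" not in meta.columns:
        raise FormatError(f"{metadata_path}: missing sample_id column")
    meta = meta.set_index("sample_id")
    meta.index = meta.index.astype(str)
    missing_cols = [c for c in SAMPLE_META_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise FormatError(f"{metadata_path}: missing columns {missing_cols}")
    uncovered = [s for s in values.columns if s not in meta.index]
    if uncovered:
        raise FormatError(
            f"{path.name}: samples missing metadata: {uncovered[:5]}"
        )
    try:
        return ExpressionMatrix(values, meta, scale="counts")
    except ValidationError as exc:
        raise FormatError(str(exc)) from exc


def read_trait_table(path: str | Path, category_path: str | Path) -> TraitTable:
    """Read a subject x trait CSV and its trait-category CSV.

    Missing numeric cells are preserved as NaN (never imputed).
    """
    values = pd.read_csv(path, index_col=0)
    values.index = values.index.astype(str)
    if values.shape[1] == 0:
        raise FormatError(f"{path}: no traits found")
    cats = pd.read_csv(category_path)
    if not {"trait", "category"}.issubset(cats.columns):
        raise FormatError(f"{category_path}: needs columns trait,category")
    categories = cats.set_index("trait")["category"]
    uncategorized = [t for t in values.columns if t not in categories.index]
    if uncategorized:
        raise FormatError(f"traits without category: {uncategorized}")
    try:
        return TraitTable(values.astype(float), categories)
    except ValidationError as exc:
        raise FormatError(str(exc)) from exc


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file; members are deduplicated per set."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            name, desc, *members = fields
            if name in sets:
                raise FormatError(f"{path}: line {lineno}: duplicate set name {name!r}")
            seen: set[str] = set()
            sets[name] = [
                m for m in members if m and not (m in seen or seen.add(m))
            ]
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def read_gene_list(path: str | Path) -> list[str]:
    """Read a plain-text gene list (e.g. a secretome), one id per line."""
    out: list[str] = []
    seen: set[str] = set()
    with open(path) as fh:
        for line in fh:
            g = line.strip()
            if g and g not in seen:
                seen.add(g)
                out.append(g)
    return out


def normalize_counts(em: ExpressionMatrix) -> ExpressionMatrix:
    """Median-of-ratios normalization followed by log2(x + 1).

    The reference profile is the per-gene geometric mean over samples,
    computed over genes with no zero count; each sample's size factor is
    the median ratio of its counts to the reference.  Values become
    ``log2(count / size_factor + 1)``.
    """
    if em.scale != "counts":
        raise ValidationError("normalize_counts expects a counts-scale matrix")
    if em.n_samples < 2:
        raise ValidationError("normalization needs at least 2 samples")
    counts = em.values.to_numpy(dtype=float)
    usable = (counts > 0).all(axis=1)
    if not usable.any():
        raise ValidationError(
            "no gene without zeros available for the normalization reference"
        )
    logc = np.log(counts[usable])
    ref = logc.mean(axis=1)
    size_factors = np.exp(np.median(logc - ref[:, None], axis=0))
    values = pd.DataFrame(
        np.log2(counts / size_factors[None, :] + 1.0),
        index=em.values.index,
        columns=em.values.columns,
    )
    return ExpressionMatrix(values, em.samples, scale="log2norm")


def size_factors(em: ExpressionMatrix) -> pd.Series:
    """The median-of-ratios size factors used by :func:`normalize_counts`."""
    counts = em.values.to_numpy(dtype=float)
    usable = (counts > 0).all(axis=1)
    if not usable.any():
        raise ValidationError(
            "no gene without zeros available for the normalization reference"
        )
    logc = np.log(counts[usable])
    ref = logc.mean(axis=1)
    return pd.Series(
        np.exp(np.median(logc - ref[:, None], axis=0)), index=em.values.columns
    )


def filter_genes(
    em: ExpressionMatrix,
    min_count: int = 5,
    min_samples: int = 2,
    top_k_by_variance: int | None = None,
) -> ExpressionMatrix:
    """Count filter then variance filter, preserving gene order.

    Keeps genes with at least ``min_count`` (raw counts if available,
    otherwise the stored values) in at least ``min_samples`` samples, then
    the ``top_k_by_variance`` most variable genes on the log scale.  If
    ``top_k`` exceeds the surviving gene count a warning is logged and all
    survivors are kept.
    """
    vals = em.values.to_numpy(dtype=float)
    if em.scale == "counts":
        passing = (vals >= min_count).sum(axis=1) >= min_samples
        logvals = np.log2(vals + 1.0)
    else:
        passing = (vals >= np.log2(min_count + 1.0)).sum(axis=1) >= min_samples
        logvals = vals
    idx = np.flatnonzero(passing)
    if top_k_by_variance is not None:
        if top_k_by_variance > idx.size:
            log.warning(
                "top_k_by_variance=%d exceeds %d surviving genes; keeping all",
                top_k_by_variance,
                idx.size,
            )
        else:
            variances = logvals[idx].var(axis=1, ddof=1)
            order = np.argsort(-variances, kind="stable")[:top_k_by_variance]
            idx = np.sort(idx[order])
    return ExpressionMatrix(
        em.values.iloc[idx], em.samples, scale=em.scale
    )


def align_paired_samples(
    islet_em: ExpressionMatrix, liver_em: ExpressionMatrix
) -> PairedDesign:
    """Match subjects present in both tissues; order by (week, diet, replicate).

    Subjects missing a sample in either tissue are dropped with a logged
    warning; the count of dropped subjects is returned on the design.
    Raises :class:`ValidationError` if no subject matches.
    """
    maps = {}
    for name, em in (("islet", islet_em), ("liver", liver_em)):
        meta = em.meta().rename_axis("sample_id")
        if meta["subject_id"].duplicated().any():
            dupes = meta["subject_id"][meta["subject_id"].duplicated()].tolist()
            raise ValidationError(
                f"{name}: subject(s) with multiple samples: {dupes[:5]}"
            )
        maps[name] = meta.reset_index().set_index("subject_id")
    shared = maps["islet"].index.intersection(maps["liver"].index)
    n_total = len(set(maps["islet"].index) | set(maps["liver"].index))
    n_dropped = n_total - len(shared)
    if len(shared) == 0:
        raise ValidationError("no subject has samples in both tissues")
    if n_dropped:
        log.warning("dropped %d subject(s) unmatched across tissues", n_dropped)
    isl = maps["islet"].loc[shared]
    liv = maps["liver"].loc[shared]
    table = pd.DataFrame(
        {
            "subject_id": shared,
            "islet_sample": isl["sample_id"].to_numpy(),
            "liver_sample": liv["sample_id"].to_numpy(),
            "week": isl["week"].to_numpy(),
            "diet": isl["diet"].to_numpy(),
            "replicate": isl["replicate"].to_numpy(),
        }
    )
    table = table.sort_values(
        ["week", "diet", "replicate", "subject_id"], kind="stable"
    ).reset_index(drop=True)
    return PairedDesign(table, n_dropped=n_dropped)
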