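"""Core data containers shared by all pipeline stages.

The pipeline's universal carrier is :class:`ExpressionMatrix`: a genes x
samples value matrix plus per-sample metadata (subject, tissue, week, diet,
replicate) and a scale tag distinguishing raw counts from log2-normalized
values.  Traits live in :class:`TraitTable` (one row per subject, every
trait assigned to a category such as ``insulin_secretion``), and the
sample pairing across the two tissues is recorded in a
:class:`PairedDesign`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

SAMPLE_META_COLUMNS = ("subject_id", "tissue", "week", "diet", "replicate")

SCALE_COUNTS = "counts"
SCALE_LOG2 = "log2norm"


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with per-sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample id.
        Raw counts must be non-negative integers; log2-normalized values
        are unconstrained reals.
    samples
        DataFrame indexed by sample id with columns
        ``subject_id, tissue, week, diet, replicate``.
    scale
        ``"counts"`` or ``"log2norm"``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    scale: str = SCALE_COUNTS

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dupes = v.index[v.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dupes[:5]}")
        if v.columns.duplicated().any():
            dupes = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dupes[:5]}")
        arr = v.to_numpy()
        if arr.size and not np.isfinite(arr.astype(float)).all():
            bad = np.argwhere(~np.isfinite(arr.astype(float)))[0]
            raise ValidationError(
                f"non-finite value at gene {v.index[bad[0]]!r}, "
                f"sample {v.columns[bad[1]]!r}"
            )
        if self.scale not in (SCALE_COUNTS, SCALE_LOG2):
            raise ValidationError(f"unknown scale tag {self.scale!r}")
        if self.scale == SCALE_COUNTS and arr.size:
            farr = arr.astype(float)
            if (farr < 0).any():
                bad = np.argwhere(farr < 0)[0]
                raise ValidationError(
                    f"negative count at gene {v.index[bad[0]]!r}, "
                    f"sample {v.columns[bad[1]]!r}"
                )
            if not np.allclose(farr, np.round(farr)):
                bad = np.argwhere(~np.isclose(farr, np.round(farr)))[0]
                raise ValidationError(
                    f"non-integer count at gene {v.index[bad[0]]!r}, "
                    f"sample {v.columns[bad[1]]!r}"
                )
        missing_meta = [c for c in SAMPLE_META_COLUMNS if c not in self.samples.columns]
        if missing_meta:
            raise ValidationError(f"sample metadata missing columns {missing_meta}")
        meta_ids = set(self.samples.index)
        uncovered = [s for s in v.columns if s not in meta_ids]
        if uncovered:
            raise ValidationError(f"samples without metadata: {uncovered[:5]}")

    # -- convenience ---------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def meta(self) -> pd.DataFrame:
        """Metadata rows aligned to the value columns."""
        return self.samples.loc[self.values.columns]

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values[list(sample_ids)], self.samples, scale=self.scale
        )

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[list(gene_ids)], self.samples, scale=self.scale
        )


@dataclass
class TraitTable:
    """Per-subject trait measurements with trait-category annotations.

    ``values`` is subjects x traits (NaN = missing, never imputed);
    ``categories`` maps every trait to a category label.
    """

    values: pd.DataFrame
    categories: pd.Series

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate subject ids in trait table")
        if self.values.shape[1] == 0:
            raise ValidationError("trait table has no traits")
        uncategorized = [t for t in self.values.columns if t not in self.categories.index]
        if uncategorized:
            raise ValidationError(f"traits without category: {uncategorized}")

    @property
    def trait_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.values.index)

    def traits_in_category(self, category: str) -> list[str]:
        if category not in set(self.categories):
            raise ValidationError(f"unknown trait category {category!r}")
        return [t for t in self.values.columns if self.categories.get(t) == category]


@dataclass
class PairedDesign:
    """Subjects with one sample in each tissue, ordered by (week, diet, replicate).

    ``table`` columns: subject_id, islet_sample, liver_sample, week, diet.
    """

    table: pd.DataFrame
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.table["subject_id"].duplicated().any():
            raise ValidationError("subject appears more than once in paired design")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.table["subject_id"])

    @property
    def islet_samples(self) -> list[str]:
        return list(self.table["islet_sample"])

    @property
    def liver_samples(self) -> list[str]:
        return list(self.table["liver_sample"])

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics: members deduplicated, names unique)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(set(members)) != len(members):
                # preserve order, drop later duplicates
                seen: set[str] = set()
                self.sets[name] = [m for m in members if not (m in seen or seen.add(m))]

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())
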