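"""Module-eigengene / trait regression and module-of-interest selection.

Each (module, trait) cell is a univariate ordinary-least-squares fit with
the eigengene as the dependent variable and the (z-scored) trait as the
independent variable, on the subjects with a non-missing trait value.
Subjects — not samples — are the regression unit: each subject contributes
one eigengene value per tissue.

Modules of interest follow the two selection presets used for this
design: an islet module qualifies with a significant association to any
one insulin-secretion parameter (``min_hits=1``); a liver module must be
significantly associated with more than five of them (``min_hits=6``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import PairedDesign, TraitTable
from .errors import ValidationError
from .network import EigengeneMatrix

#: selection presets: category hit threshold per tissue
ISLET_MIN_HITS = 1
LIVER_MIN_HITS = 6  # "more than five"


@dataclass
class ModuleTraitResults:
    """Per-(module, trait) regression results.

    Each of ``slope``, ``intercept``, ``r``, ``pvalue``, ``n`` is a
    module x trait DataFrame; cells are NaN where a trait had fewer than
    3 non-missing values.
    """

    slope: pd.DataFrame
    intercept: pd.DataFrame
    r: pd.DataFrame
    pvalue: pd.DataFrame
    n: pd.DataFrame
    categories: pd.Series

    def summary(self) -> pd.DataFrame:
        """Long-format table: one row per (module, trait)."""
        rows = []
        for m in self.slope.index:
            for t in self.slope.columns:
                rows.append(
                    {
                        "module": m,
                        "trait": t,
                        "category": self.categories.get(t, ""),
                        "slope": self.slope.loc[m, t],
                        "r": self.r.loc[m, t],
                        "pvalue": self.pvalue.loc[m, t],
                        "n": self.n.loc[m, t],
                    }
                )
        return pd.DataFrame(rows)

    def select_modules(
        self,
        category: str,
        min_hits: int = ISLET_MIN_HITS,
        alpha: float = 0.05,
        adjust: bool = False,
    ) -> list[str]:
        return select_modules_of_interest(
            self, category, min_hits=min_hits, alpha=alpha, adjust=adjust
        )


def me_trait_regression(
    me: EigengeneMatrix,
    traits: TraitTable,
    design: PairedDesign,
    tissue: str = "islet",
) -> ModuleTraitResults:
    """OLS of each module eigengene on each trait across paired subjects.

    Traits are z-scored over their non-missing values before fitting.
    The slope p-value is the standard t-test on the regression slope; ``r``
    is the sample Pearson correlation.  Traits with fewer than 3
    non-missing values yield NaN cells rather than an error.
    """
    sample_col = "islet_sample" if tissue == "islet" else "liver_sample"
    samples = design.table[sample_col].tolist()
    subjects = design.table["subject_id"].tolist()
    missing = [s for s in samples if s not in me.values.columns]
    if missing:
        raise ValidationError(
            f"eigengene matrix lacks design samples: {missing[:5]}"
        )
    me_by_subject = me.values[samples].copy()
    me_by_subject.columns = subjects

    trait_vals = traits.values.reindex(subjects)
    zt = (trait_vals - trait_vals.mean()) / trait_vals.std(ddof=1)

    modules = list(me.values.index)
    names = list(trait_vals.columns)
    shape = (len(modules), len(names))
    slope = np.full(shape, np.nan)
    intercept = np.full(shape, np.nan)
    rmat = np.full(shape, np.nan)
    pmat = np.full(shape, np.nan)
    nmat = np.full(shape, np.nan)
    for j, t in enumerate(names):
        x_all = zt[t].to_numpy(dtype=float)
        ok = ~np.isnan(x_all)
        n_ok = int(ok.sum())
        if n_ok < 3:
            continue
        x = x_all[ok]
        for i, m in enumerate(modules):
            y = me_by_subject.loc[m].to_numpy(dtype=float)[ok]
            if np.ptp(x) == 0:
                continue
            res = stats.linregress(x, y)
            slope[i, j] = res.slope
            intercept[i, j] = res.intercept
            rmat[i, j] = res.rvalue
            pmat[i, j] = res.pvalue
            nmat[i, j] = n_ok

    def frame(a):
        return pd.DataFrame(a, index=modules, columns=names)

    return ModuleTraitResults(
        slope=frame(slope),
        intercept=frame(intercept),
        r=frame(rmat),
        pvalue=frame(pmat),
        n=frame(nmat),
        categories=traits.categories,
    )


def select_modules_of_interest(
    res: ModuleTraitResults,
    category: str,
    min_hits: int = ISLET_MIN_HITS,
    alpha: float = 0.05,
    adjust: bool = False,
) -> list[str]:
    """Modules with >= ``min_hits`` traits in ``category`` at ``p < alpha``.

    ``adjust=True`` applies Benjamini-Hochberg across the module x trait
    grid restricted to the category before thresholding (off by default,
    matching common practice of raw p < 0.05 for module-trait screens).
    """
    in_cat = [t for t in res.pvalue.columns if res.categories.get(t) == category]
    if not in_cat:
        raise ValidationError(f"unknown or empty trait category {category!r}")
    pv = res.pvalue[in_cat]
    if adjust:
        from .diffexpr import bh_adjust

        flat = pv.to_numpy().ravel()
        ok = ~np.isnan(flat)
        adj = flat.copy()
        adj[ok] = bh_adjust(flat[ok])
        pv = pd.DataFrame(
            adj.reshape(pv.shape), index=pv.index, columns=pv.columns
        )
    hits = (pv < alpha).sum(axis=1)
    return [m for m in pv.index if hits[m] >= min_hits]


class ModuleTraitModel:
    """Model object pairing one tissue's eigengenes with the trait table."""

    def __init__(
        self,
        me: EigengeneMatrix,
        traits: TraitTable,
        design: PairedDesign,
        tissue: str = "islet",
    ):
        self.me = me
        self.traits = traits
        self.design = design
        self.tissue = tissue

    def fit(self) -> ModuleTraitResults:
        return me_trait_regression(
            self.me, self.traits, self.design, tissue=self.tissue
        )
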