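"""Cross-tissue module integration: pair scores, key genes, secretome filter.

The central statistic is the membership-weighted combined coefficient of
an (islet module, liver module) pair.  With ``r_ij`` the Pearson
correlation of islet gene *i* and liver gene *j* across paired subjects,
and ``w_i`` each gene's membership (kME) in its own module clipped below
at zero:

    C = sum_ij w_i w_j |r_ij| / (sum_i w_i * sum_j w_j)

C is a weighted mean of |r|, hence bounded in [0, 1]; pairs tier as
strong (C > 0.4), moderate (0.35 < C <= 0.4), or none.  Key genes of a
pair are genes highly representative of their own module (kME > 0.9)
whose profile correlates above 0.5 in magnitude with the partner
module's eigengene.  A secretome filter restricts liver DEGs to genes
encoding secretable proteins, and interconnection candidates are ranked
by correlation to the islet DEG block's leading principal component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, PairedDesign
from .errors import ValidationError
from .network import CoexpressionResults, EigengeneMatrix, _rowwise_corr

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class XlinkConfig:
    """Thresholds of the cross-tissue stage."""

    strong_min: float = 0.4
    moderate_min: float = 0.35
    membership_min: float = 0.9
    partner_cor_min: float = 0.5
    absolute: bool = True          # use |r|; False keeps signed r
    partner_mode: str = "eigengene"  # or "mean_gene"


@dataclass
class CrossPairScore:
    """Combined coefficient of one (islet module, liver module) pair."""

    islet_module: str
    liver_module: str
    combined: float
    tier: str
    n_gene_pairs: int


@dataclass
class KeyGene:
    """A gene driving a cross-tissue module pair."""

    gene: str
    tissue: str
    module: str
    kme: float
    partner_module: str
    partner_corr: float
    is_deg: bool


def _paired_block(
    em: ExpressionMatrix | pd.DataFrame,
    genes: list[str],
    sample_ids: list[str],
) -> np.ndarray:
    X = em.values if isinstance(em, ExpressionMatrix) else em
    return X.loc[genes, sample_ids].to_numpy(dtype=float)


def _standardize_rows(arr: np.ndarray, genes: list[str], tissue: str) -> np.ndarray:
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)
    if (sd == 0).any():
        bad = genes[int(np.flatnonzero(sd[:, 0] == 0)[0])]
        raise ValidationError(f"zero-variance gene {bad!r} in {tissue}")
    return (arr - mu) / sd


def cross_correlation(
    X_islet: ExpressionMatrix | pd.DataFrame,
    X_liver: ExpressionMatrix | pd.DataFrame,
    design: PairedDesign,
) -> pd.DataFrame:
    """Islet gene x liver gene Pearson correlations across paired subjects.

    Rows of both inputs are genes; columns are matched through the design
    (islet sample and liver sample of the same subject, in design order).
    """
    if len(design) < 3:
        raise ValidationError("cross_correlation needs at least 3 paired subjects")
    Xi = X_islet.values if isinstance(X_islet, ExpressionMatrix) else X_islet
    Xl = X_liver.values if isinstance(X_liver, ExpressionMatrix) else X_liver
    gi = list(Xi.index)
    gl = list(Xl.index)
    ai = _standardize_rows(
        _paired_block(Xi, gi, design.islet_samples), gi, "islet"
    )
    al = _standardize_rows(
        _paired_block(Xl, gl, design.liver_samples), gl, "liver"
    )
    n = ai.shape[1]
    r = (ai @ al.T) / n
    return pd.DataFrame(np.clip(r, -1.0, 1.0), index=gi, columns=gl)


def combined_pair_score(
    crosscorr: pd.DataFrame,
    kme_islet: pd.Series,
    kme_liver: pd.Series,
    absolute: bool = True,
) -> float:
    """Membership-weighted mean of (absolute) cross-tissue correlations.

    Weights are each gene's kME in its own module, clipped below at 0.
    Returns NaN with a warning when either side's weights are all zero.
    """
    if list(crosscorr.index) != list(kme_islet.index) or list(
        crosscorr.columns
    ) != list(kme_liver.index):
        raise ValidationError(
            "combined_pair_score: correlation matrix and weights misaligned"
        )
    wa = np.clip(kme_islet.to_numpy(dtype=float), 0.0, None)
    wb = np.clip(kme_liver.to_numpy(dtype=float), 0.0, None)
    if wa.sum() == 0.0 or wb.sum() == 0.0:
        log.warning("combined_pair_score: all weights zero on one side")
        return float("nan")
    r = crosscorr.to_numpy(dtype=float)
    if absolute:
        r = np.abs(r)
    return float(wa @ r @ wb / (wa.sum() * wb.sum()))


def pair_network(
    islet_interest: list[str],
    liver_interest: list[str],
    scores: pd.DataFrame,
    n_gene_pairs: pd.DataFrame | None = None,
    strong_min: float = 0.4,
    moderate_min: float = 0.35,
) -> list[CrossPairScore]:
    """Tier every (islet, liver) module-of-interest pair by its score.

    ``scores`` is an islet-module x liver-module DataFrame of combined
    coefficients covering every cross pair.  Tiers: strong (C >
    strong_min), moderate (moderate_min < C <= strong_min), else none.
    Sorted by descending C, ties broken by (islet label, liver label).
    """
    out: list[CrossPairScore] = []
    for im in islet_interest:
        for lm in liver_interest:
            if im not in scores.index or lm not in scores.columns:
                raise ValidationError(f"pair ({im}, {lm}) missing from scores")
            c = float(scores.loc[im, lm])
            if np.isnan(c):
                tier = "none"
            elif c > strong_min:
                tier = "strong"
            elif c > moderate_min:
                tier = "moderate"
            else:
                tier = "none"
            n = (
                int(n_gene_pairs.loc[im, lm])
                if n_gene_pairs is not None
                else 0
            )
            out.append(CrossPairScore(im, lm, c, tier, n))
    out.sort(key=lambda s: (-(s.combined if not np.isnan(s.combined) else -1.0),
                            s.islet_module, s.liver_module))
    return out


def key_genes(
    pair: CrossPairScore,
    islet_em: ExpressionMatrix | pd.DataFrame,
    liver_em: ExpressionMatrix | pd.DataFrame,
    islet_results: CoexpressionResults,
    liver_results: CoexpressionResults,
    design: PairedDesign,
    membership_min: float = 0.9,
    partner_cor_min: float = 0.5,
    deg_sets: dict[str, set[str]] | None = None,
    partner_mode: str = "eigengene",
) -> list[KeyGene]:
    """Genes of either tissue driving one cross-tissue module pair.

    A key gene has own-module kME above ``membership_min`` and absolute
    correlation above ``partner_cor_min`` to the partner module across
    paired subjects — to the partner eigengene by default, or to the mean
    of per-gene correlations with ``partner_mode="mean_gene"``.
    """
    deg_sets = deg_sets or {}
    out: list[KeyGene] = []
    sides = (
        ("islet", pair.islet_module, islet_em, islet_results,
         pair.liver_module, liver_em, liver_results),
        ("liver", pair.liver_module, liver_em, liver_results,
         pair.islet_module, islet_em, islet_results),
    )
    for (tissue, module, em, res, partner_module, partner_em,
         partner_res) in sides:
        genes = res.partition.genes_in(module)
        if not genes:
            raise ValidationError(f"module {module!r} has no genes in {tissue}")
        kme = res.membership.loc[genes, module]
        own_samples = (
            design.islet_samples if tissue == "islet" else design.liver_samples
        )
        partner_samples = (
            design.liver_samples if tissue == "islet" else design.islet_samples
        )
        block = _paired_block(em, genes, own_samples)
        if partner_mode == "eigengene":
            me_vec = (
                partner_res.eigengenes.values.loc[partner_module, partner_samples]
                .to_numpy(dtype=float)
            )
            pcor = _rowwise_corr(block, me_vec)
        elif partner_mode == "mean_gene":
            pgenes = partner_res.partition.genes_in(partner_module)
            pblock = _standardize_rows(
                _paired_block(partner_em, pgenes, partner_samples),
                pgenes, "partner",
            )
            zblock = _standardize_rows(block, genes, tissue)
            pcor = (zblock @ pblock.T / block.shape[1]).mean(axis=1)
        else:
            raise ValidationError(f"unknown partner_mode {partner_mode!r}")
        degs = deg_sets.get(tissue, set())
        for g, k, pc in zip(genes, kme.to_numpy(), pcor):
            if k > membership_min and abs(pc) > partner_cor_min:
                out.append(
                    KeyGene(g, tissue, module, float(k), partner_module,
                            float(pc), g in degs)
                )
    out.sort(key=lambda kg: (kg.tissue, -kg.kme, kg.gene))
    return out


def secretome_filter(liver_degs: list[str], secretome: list[str]) -> list[str]:
    """Liver DEGs encoding secretable proteins, in DEG order."""
    if not secretome:
        log.warning("empty secretome list; secretome filter returns no genes")
        return []
    allowed = set(secretome)
    return [g for g in liver_degs if g in allowed]


def rank_interconnected(
    islet_degs: list[str],
    liver_secreted_degs: list[str],
    islet_em: ExpressionMatrix | pd.DataFrame,
    liver_em: ExpressionMatrix | pd.DataFrame,
    design: PairedDesign,
) -> pd.DataFrame:
    """Rank liver secreted DEGs by coupling to the islet DEG signature.

    The islet DEG block is summarized by its leading principal component
    over paired subjects (genes z-scored first); each liver candidate is
    scored by the absolute Pearson correlation of its profile with that
    component.  Descending score, ties broken by gene id.
    """
    if not islet_degs or not liver_secreted_degs:
        return pd.DataFrame(columns=["gene", "score"]).set_index("gene")
    iblock = _standardize_rows(
        _paired_block(islet_em, islet_degs, design.islet_samples),
        islet_degs, "islet",
    )
    _, _, vt = np.linalg.svd(iblock, full_matrices=False)
    signature = vt[0]
    lblock = _paired_block(liver_em, liver_secreted_degs, design.liver_samples)
    scores = np.abs(_rowwise_corr(lblock, signature))
    table = pd.DataFrame({"gene": liver_secreted_degs, "score": scores})
    table = table.sort_values(
        ["score", "gene"], ascending=[False, True], kind="stable"
    ).set_index("gene")
    return table


# -- model / results --------------------------------------------------------


@dataclass
class CrossTissueResults:
    """Fitted cross-tissue integration for one pair of tissue networks."""

    pair_scores: list[CrossPairScore]
    key_genes_per_pair: dict[tuple[str, str], list[KeyGene]]
    config: XlinkConfig

    def pairs_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "islet_module": s.islet_module,
                    "liver_module": s.liver_module,
                    "combined": s.combined,
                    "tier": s.tier,
                    "n_gene_pairs": s.n_gene_pairs,
                }
                for s in self.pair_scores
            ]
        )

    def key_genes_table(self) -> pd.DataFrame:
        rows = []
        for (im, lm), genes in self.key_genes_per_pair.items():
            for kg in genes:
                rows.append(
                    {
                        "islet_module": im,
                        "liver_module": lm,
                        "gene": kg.gene,
                        "tissue": kg.tissue,
                        "module": kg.module,
                        "kme": kg.kme,
                        "partner_module": kg.partner_module,
                        "partner_corr": kg.partner_corr,
                        "is_deg": kg.is_deg,
                    }
                )
        cols = ["islet_module", "liver_module", "gene", "tissue", "module",
                "kme", "partner_module", "partner_corr", "is_deg"]
        return pd.DataFrame(rows, columns=cols)

    def tier_counts(self) -> dict[str, int]:
        out = {"strong": 0, "moderate": 0, "none": 0}
        for s in self.pair_scores:
            out[s.tier] += 1
        return out

    def summary(self) -> pd.DataFrame:
        return self.pairs_table()


class CrossTissueModel:
    """Model object scoring all module-of-interest pairs across tissues.

    Parameters
    ----------
    islet_results, liver_results
        Fitted :class:`~modlink.network.CoexpressionResults` per tissue.
    islet_em, liver_em
        The log2-normalized expression each network was fitted on.
    design
        Paired-subject design linking the two tissues.
    islet_interest, liver_interest
        Modules of interest (default: all modules of each partition).
    """

    def __init__(
        self,
        islet_results: CoexpressionResults,
        liver_results: CoexpressionResults,
        islet_em: ExpressionMatrix | pd.DataFrame,
        liver_em: ExpressionMatrix | pd.DataFrame,
        design: PairedDesign,
        islet_interest: list[str] | None = None,
        liver_interest: list[str] | None = None,
        config: XlinkConfig | None = None,
        deg_sets: dict[str, set[str]] | None = None,
    ):
        self.islet_results = islet_results
        self.liver_results = liver_results
        self.islet_em = islet_em
        self.liver_em = liver_em
        self.design = design
        self.islet_interest = (
            islet_interest
            if islet_interest is not None
            else islet_results.partition.module_names
        )
        self.liver_interest = (
            liver_interest
            if liver_interest is not None
            else liver_results.partition.module_names
        )
        self.config = config or XlinkConfig()
        self.deg_sets = deg_sets or {}

    def score_matrix(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Combined coefficient and gene-pair count per cross pair."""
        Xi = (
            self.islet_em.values
            if isinstance(self.islet_em, ExpressionMatrix)
            else self.islet_em
        )
        Xl = (
            self.liver_em.values
            if isinstance(self.liver_em, ExpressionMatrix)
            else self.liver_em
        )
        igenes = {
            m: self.islet_results.partition.genes_in(m)
            for m in self.islet_interest
        }
        lgenes = {
            m: self.liver_results.partition.genes_in(m)
            for m in self.liver_interest
        }
        all_i = [g for genes in igenes.values() for g in genes]
        all_l = [g for genes in lgenes.values() for g in genes]
        big = cross_correlation(Xi.loc[all_i], Xl.loc[all_l], self.design)
        scores = pd.DataFrame(
            np.nan, index=self.islet_interest, columns=self.liver_interest
        )
        npairs = pd.DataFrame(
            0, index=self.islet_interest, columns=self.liver_interest
        )
        for im, gi in igenes.items():
            kme_i = self.islet_results.membership.loc[gi, im]
            for lm, gl in lgenes.items():
                kme_l = self.liver_results.membership.loc[gl, lm]
                scores.loc[im, lm] = combined_pair_score(
                    big.loc[gi, gl], kme_i, kme_l,
                    absolute=self.config.absolute,
                )
                npairs.loc[im, lm] = len(gi) * len(gl)
        return scores, npairs

    def fit(self) -> CrossTissueResults:
        scores, npairs = self.score_matrix()
        pairs = pair_network(
            self.islet_interest,
            self.liver_interest,
            scores,
            n_gene_pairs=npairs,
            strong_min=self.config.strong_min,
            moderate_min=self.config.moderate_min,
        )
        kg: dict[tuple[str, str], list[KeyGene]] = {}
        for pair in pairs:
            if pair.tier == "strong":
                kg[(pair.islet_module, pair.liver_module)] = key_genes(
                    pair,
                    self.islet_em,
                    self.liver_em,
                    self.islet_results,
                    self.liver_results,
                    self.design,
                    membership_min=self.config.membership_min,
                    partner_cor_min=self.config.partner_cor_min,
                    deg_sets=self.deg_sets,
                    partner_mode=self.config.partner_mode,
                )
        return CrossTissueResults(pairs, kg, self.config)
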