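"""Recovery and calibration benchmarks on the synthetic study conditions.

Every function here regenerates its data from scratch at the stated
conditions and measures how well the pipeline recovers the planted
structure: module partitions (adjusted Rand index), eigengene-factor
tracking, cross-tissue coupled-pair ranking, key-gene identification,
differential-expression calibration and power, and module-trait
regression calibration.  They are used by the validation test-suite and
the reproduction script alike.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import io as mio
from . import simulate
from .crosslink import CrossTissueModel
from .diffexpr import differential_expression
from .modtrait import me_trait_regression
from .network import (
    CoexpressionNetwork,
    CoexpressionResults,
    ModulePartition,
    module_eigengenes,
    module_membership,
)

COUPLED_PLANTED = ("M1", "M2", "M3")  # planted coupled module labels


def _logged_pair(config):
    islet, liver, traits, truth = simulate.generate_dataset(config)
    isl_log = mio.normalize_counts(mio.filter_genes(islet))
    liv_log = mio.normalize_counts(mio.filter_genes(liver))
    design = mio.align_paired_samples(isl_log, liv_log)
    return isl_log, liv_log, traits, truth, design


def fit_planted_networks(seed: int = 1):
    """Fit both tissue networks on the planted-modules conditions."""
    cfg = simulate.planted_modules_config(seed)
    isl_log, liv_log, traits, truth, design = _logged_pair(cfg)
    results = {
        "islet": CoexpressionNetwork(isl_log).fit(),
        "liver": CoexpressionNetwork(liv_log).fit(),
    }
    return isl_log, liv_log, traits, truth, design, results


def module_recovery_metrics(
    truth, results: dict[str, CoexpressionResults], ems: dict[str, object]
) -> dict:
    """ARI per tissue (assigned genes) and ME-factor correlation range."""
    out: dict = {}
    for tissue, res in results.items():
        detected = res.partition.labels
        planted = truth.partition_per_tissue[tissue].reindex(detected.index)
        mask = detected != "unassigned"
        out[f"ari_{tissue}"] = float(
            adjusted_rand_score(planted[mask], detected[mask])
        )
        subj = ems[tissue].meta()["subject_id"]
        factors = truth.factor_matrix_per_tissue[tissue]
        me = res.eigengenes.values
        cors = []
        for m in factors.index:
            # a planted module counts as recovered if some detected module
            # is majority-composed of its genes
            f = factors.loc[m, subj].to_numpy()
            best = max(
                abs(np.corrcoef(f, me.loc[d].to_numpy())[0, 1])
                for d in me.index
            )
            cors.append(best)
        out[f"me_factor_cor_min_{tissue}"] = float(min(cors))
    return out


def planted_pair_scores(seed: int) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Combined coefficients for all 8 x 8 planted module pairs.

    Uses the planted partitions (not a fitted network) so the coupling
    statistic itself is isolated from module detection.
    """
    cfg = simulate.planted_modules_config(seed)
    isl_log, liv_log, _, truth, design = _logged_pair(cfg)
    results = {}
    for tissue, em in (("islet", isl_log), ("liver", liv_log)):
        part = ModulePartition(truth.partition_per_tissue[tissue])
        me = module_eigengenes(em.values, part)
        kme = module_membership(em.values, me)
        results[tissue] = CoexpressionResults(
            tissue, 0, pd.DataFrame(), part, me, kme, None
        )
    model = CrossTissueModel(
        results["islet"], results["liver"], isl_log, liv_log, design
    )
    scores, _ = model.score_matrix()
    coupled = [(m, m) for m in COUPLED_PLANTED]
    return scores, coupled


def coupled_pairs_separate(scores: pd.DataFrame,
                           coupled: list[tuple[str, str]]) -> bool:
    """True when every coupled pair outranks every uncoupled pair."""
    cvals = [scores.loc[i, j] for i, j in coupled]
    mask = pd.DataFrame(True, index=scores.index, columns=scores.columns)
    for i, j in coupled:
        mask.loc[i, j] = False
    uncoupled_max = scores.to_numpy()[mask.to_numpy()].max()
    return min(cvals) > uncoupled_max


def key_gene_recovery(seed: int = 1) -> dict:
    """Precision/recall of key-gene calls against planted hub genes."""
    cfg = simulate.key_gene_config(seed)
    isl_log, liv_log, _, truth, design = _logged_pair(cfg)
    ri = CoexpressionNetwork(isl_log).fit()
    rl = CoexpressionNetwork(liv_log).fit()
    xres = CrossTissueModel(ri, rl, isl_log, liv_log, design).fit()
    predicted = set(xres.key_genes_table()["gene"])
    hubs: set[str] = set()
    for tissue in ("islet", "liver"):
        load = truth.loadings_per_tissue[tissue]
        part = truth.partition_per_tissue[tissue]
        for m in COUPLED_PLANTED:
            hubs |= set(part.index[(part == m) & (load >= 0.95)])
    tp = len(predicted & hubs)
    return {
        "n_predicted": len(predicted),
        "n_true_hubs": len(hubs),
        "precision": tp / len(predicted) if predicted else 0.0,
        "recall": tp / len(hubs) if hubs else 0.0,
    }


def de_null_calibration(seeds) -> float:
    """Mean fraction of raw Welch p < 0.05 on null data, over seeds."""
    fracs = []
    for seed in seeds:
        cfg = simulate.de_calibration_config(seed)
        islet, *_ = simulate.null_dataset(cfg)
        em = mio.normalize_counts(islet)
        res = differential_expression(em, week=cfg.weeks[0])
        fracs.append(float((res.table["pvalue"] < 0.05).mean()))
    return float(np.mean(fracs))


def de_power(seed: int = 1) -> dict:
    """Recall and false positives for the planted |log2fc|=3 block."""
    cfg = simulate.de_calibration_config(seed)
    islet, _, _, truth = simulate.generate_dataset(cfg)
    em = mio.normalize_counts(islet)
    week = cfg.weeks[0]
    res = differential_expression(em, week=week)
    truth_genes = {g for g, t, _ in truth.de_genes_per_week[week] if t == "islet"}
    called = set(res.deg_genes)
    return {
        "recall": len(called & truth_genes) / len(truth_genes),
        "false_positives": len(called - truth_genes),
        "n_true": len(truth_genes),
    }


def trait_calibration(seeds) -> dict:
    """Planted-trait detection and null rejection rate of ME-trait fits.

    The planted check is the trait with loading 0.8 on islet module M1;
    null pairs are uncoupled islet modules (M4..M8) crossed with every
    trait not driven by that same module.
    """
    seeds = list(seeds)
    hits = 0
    null_ps: list[float] = []
    for seed in seeds:
        cfg = simulate.planted_modules_config(seed)
        isl_log, liv_log, traits, truth, design = _logged_pair(cfg)
        part = ModulePartition(truth.partition_per_tissue["islet"])
        me = module_eigengenes(isl_log.values, part)
        res = me_trait_regression(me, traits, design, tissue="islet")
        hits += int(res.pvalue.loc["M1", "auc_insulin"] < 0.01)
        for m in ("M4", "M5", "M6", "M7", "M8"):
            for t in res.pvalue.columns:
                tissue, module, _ = truth.trait_loadings[t]
                if tissue == "islet" and module is not None and \
                        f"M{module + 1}" == m:
                    continue
                null_ps.append(float(res.pvalue.loc[m, t]))
    return {
        "planted_hits": hits,
        "n_seeds": len(seeds),
        "null_rejection_rate": float(np.mean(np.array(null_ps) < 0.05)),
        "n_null_pairs": len(null_ps),
    }
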