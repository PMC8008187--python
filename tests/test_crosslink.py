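"""Cross-tissue correlation, combined pair scores, key genes, secretome."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from modlink.containers import PairedDesign
from modlink.crosslink import (
    CrossPairScore,
    CrossTissueModel,
    combined_pair_score,
    cross_correlation,
    key_genes,
    pair_network,
    rank_interconnected,
    secretome_filter,
)
from modlink.errors import ValidationError
from modlink.network import CoexpressionNetwork


def design_of(n=5):
    subjects = [f"sub{i}" for i in range(n)]
    return PairedDesign(
        pd.DataFrame(
            {
                "subject_id": subjects,
                "islet_sample": [f"isl_{s}" for s in subjects],
                "liver_sample": [f"liv_{s}" for s in subjects],
                "week": [4] * n,
                "diet": ["HFD"] * n,
                "replicate": list(range(1, n + 1)),
            }
        )
    )


def tissue_frame(arr, design, tissue, prefix):
    cols = design.islet_samples if tissue == "islet" else design.liver_samples
    arr = np.asarray(arr, float)
    return pd.DataFrame(
        arr, index=[f"{prefix}{i}" for i in range(arr.shape[0])], columns=cols
    )


class TestCrossCorrelation:
    def test_duplicated_gene_across_tissues(self):
        design = design_of()
        rng = np.random.default_rng(0)
        prof = rng.normal(size=5)
        Xi = tissue_frame([prof], design, "islet", "ig")
        Xl = tissue_frame([prof, -prof], design, "liver", "lg")
        r = cross_correlation(Xi, Xl, design)
        assert r.loc["ig0", "lg0"] == pytest.approx(1.0)
        assert r.loc["ig0", "lg1"] == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        design = design_of()
        rng = np.random.default_rng(1)
        Xi = tissue_frame(rng.normal(size=(2, 5)), design, "islet", "ig")
        Xl = tissue_frame(rng.normal(size=(2, 5)), design, "liver", "lg")
        r = cross_correlation(Xi, Xl, design)
        for i in range(2):
            for j in range(2):
                expected = np.corrcoef(Xi.to_numpy()[i], Xl.to_numpy()[j])[0, 1]
                assert r.iloc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_named_with_tissue(self):
        design = design_of()
        Xi = tissue_frame(np.ones((1, 5)), design, "islet", "ig")
        Xl = tissue_frame(np.random.default_rng(0).normal(size=(1, 5)),
                          design, "liver", "lg")
        with pytest.raises(ValidationError, match="islet"):
            cross_correlation(Xi, Xl, design)

    def test_needs_three_pairs(self):
        design = design_of(2)
        X = tissue_frame(np.random.default_rng(0).normal(size=(2, 2)),
                         design, "islet", "g")
        with pytest.raises(ValidationError, match="3 paired"):
            cross_correlation(X, X, design)


class TestCombinedScore:
    def test_constant_correlation_returns_constant(self):
        r = pd.DataFrame(0.3, index=["a", "b"], columns=["c", "d"])
        w1 = pd.Series([0.9, 0.2], index=["a", "b"])
        w2 = pd.Series([0.5, 0.7], index=["c", "d"])
        assert combined_pair_score(r, w1, w2) == pytest.approx(0.3)

    def test_single_positive_weight_row_mean(self):
        rng = np.random.default_rng(0)
        r = pd.DataFrame(rng.uniform(-1, 1, size=(3, 4)),
                         index=list("abc"), columns=list("wxyz"))
        w1 = pd.Series([1.0, 0.0, 0.0], index=list("abc"))
        w2 = pd.Series([0.25, 0.25, 0.25, 0.25], index=list("wxyz"))
        expected = np.abs(r.to_numpy()[0]).mean()
        assert combined_pair_score(r, w1, w2) == pytest.approx(expected)

    def test_matches_bruteforce_double_loop(self):
        rng = np.random.default_rng(42)
        genes_a = [f"a{i}" for i in range(20)]
        genes_b = [f"b{i}" for i in range(20)]
        r = pd.DataFrame(rng.uniform(-1, 1, size=(20, 20)),
                         index=genes_a, columns=genes_b)
        wa = pd.Series(rng.uniform(-0.5, 1, size=20), index=genes_a)
        wb = pd.Series(rng.uniform(-0.5, 1, size=20), index=genes_b)
        num = den_a = den_b = 0.0
        for i, ga in enumerate(genes_a):
            for j, gb in enumerate(genes_b):
                wi = max(wa[ga], 0.0)
                wj = max(wb[gb], 0.0)
                num += wi * wj * abs(r.iloc[i, j])
        den_a = sum(max(w, 0.0) for w in wa)
        den_b = sum(max(w, 0.0) for w in wb)
        expected = num / (den_a * den_b)
        assert combined_pair_score(r, wa, wb) == pytest.approx(expected,
                                                               abs=1e-12)

    def test_all_zero_weights_missing(self, caplog):
        r = pd.DataFrame(0.5, index=["a"], columns=["b"])
        with caplog.at_level("WARNING"):
            c = combined_pair_score(
                r, pd.Series({"a": -0.2}), pd.Series({"b": 1.0})
            )
        assert np.isnan(c)

    def test_invariance_to_weight_rescaling(self):
        rng = np.random.default_rng(3)
        r = pd.DataFrame(rng.uniform(-1, 1, size=(5, 5)),
                         index=[f"a{i}" for i in range(5)],
                         columns=[f"b{i}" for i in range(5)])
        wa = pd.Series(rng.uniform(0, 1, 5), index=r.index)
        wb = pd.Series(rng.uniform(0, 1, 5), index=r.columns)
        c1 = combined_pair_score(r, wa, wb)
        c2 = combined_pair_score(r, 3.7 * wa, 0.2 * wb)
        assert c1 == pytest.approx(c2, abs=1e-12)

    def test_invariance_to_gene_relabeling(self):
        rng = np.random.default_rng(4)
        r = pd.DataFrame(rng.uniform(-1, 1, size=(4, 4)),
                         index=list("abcd"), columns=list("wxyz"))
        wa = pd.Series(rng.uniform(0, 1, 4), index=r.index)
        wb = pd.Series(rng.uniform(0, 1, 4), index=r.columns)
        perm = [2, 0, 3, 1]
        r2 = r.iloc[perm, :]
        assert combined_pair_score(r, wa, wb) == pytest.approx(
            combined_pair_score(r2, wa.iloc[perm], wb), abs=1e-12
        )

    def test_signed_mode_keeps_cancellation(self):
        r = pd.DataFrame([[0.5, -0.5]], index=["a"], columns=["b", "c"])
        w1 = pd.Series({"a": 1.0})
        w2 = pd.Series({"b": 1.0, "c": 1.0})
        assert combined_pair_score(r, w1, w2, absolute=False) == pytest.approx(0.0)
        assert combined_pair_score(r, w1, w2, absolute=True) == pytest.approx(0.5)


class TestPairNetwork:
    def test_8x26_gives_208_pairs(self):
        islet = [f"I{i}" for i in range(8)]
        liver = [f"L{i}" for i in range(26)]
        scores = pd.DataFrame(0.1, index=islet, columns=liver)
        pairs = pair_network(islet, liver, scores)
        assert len(pairs) == 208

    @pytest.mark.parametrize(
        "c, tier", [(0.45, "strong"), (0.38, "moderate"), (0.35, "none"),
                    (0.401, "strong"), (0.4, "moderate")]
    )
    def test_tier_boundaries(self, c, tier):
        scores = pd.DataFrame([[c]], index=["I1"], columns=["L1"])
        pairs = pair_network(["I1"], ["L1"], scores)
        assert pairs[0].tier == tier

    def test_empty_interest_list(self):
        scores = pd.DataFrame(index=[], columns=[])
        assert pair_network([], [], scores) == []

    def test_sorted_by_score_then_labels(self):
        scores = pd.DataFrame(
            [[0.2, 0.5], [0.5, 0.2]], index=["I1", "I2"], columns=["L1", "L2"]
        )
        pairs = pair_network(["I1", "I2"], ["L1", "L2"], scores)
        combos = [(p.islet_module, p.liver_module) for p in pairs]
        assert combos == [("I1", "L2"), ("I2", "L1"), ("I1", "L1"), ("I2", "L2")]


@pytest.fixture(scope="module")
def fitted_pair(demo_logged):
    isl_log, liv_log, traits, truth, design = demo_logged
    ri = CoexpressionNetwork(isl_log).fit()
    rl = CoexpressionNetwork(liv_log).fit()
    model = CrossTissueModel(ri, rl, isl_log, liv_log, design)
    return model, model.fit(), truth, design


class TestKeyGenes:
    def test_thresholds_respected(self, fitted_pair, demo_logged):
        model, xres, *_ = fitted_pair
        for kgs in xres.key_genes_per_pair.values():
            for kg in kgs:
                assert kg.kme > model.config.membership_min
                assert abs(kg.partner_corr) > model.config.partner_cor_min

    def test_strong_pair_has_key_genes(self, fitted_pair):
        _, xres, *_ = fitted_pair
        strong = [p for p in xres.pair_scores if p.tier == "strong"]
        assert strong, "demo data should produce a strong coupled pair"
        assert any(xres.key_genes_per_pair.get(
            (p.islet_module, p.liver_module)) for p in strong)

    def test_mean_gene_mode_close_to_eigengene_mode(self, fitted_pair,
                                                    demo_logged):
        model, xres, _, design = fitted_pair
        isl_log, liv_log, *_ = demo_logged
        strong = [p for p in xres.pair_scores if p.tier == "strong"][0]
        kg_e = key_genes(strong, isl_log, liv_log, model.islet_results,
                         model.liver_results, design, partner_mode="eigengene")
        kg_m = key_genes(strong, isl_log, liv_log, model.islet_results,
                         model.liver_results, design, partner_mode="mean_gene")
        genes_e = {k.gene for k in kg_e}
        genes_m = {k.gene for k in kg_m}
        # the two readings of "correlation to a partner module" agree broadly
        assert genes_e and genes_m
        overlap = len(genes_e & genes_m) / max(len(genes_e | genes_m), 1)
        assert overlap >= 0.5


class TestSecretome:
    def test_intersection_preserving_order(self):
        assert secretome_filter(["g1", "g2", "g3"], ["g2", "g4"]) == ["g2"]

    def test_disjoint(self):
        assert secretome_filter(["g1"], ["g9"]) == []

    def test_superset_is_identity(self):
        degs = ["g3", "g1", "g2"]
        assert secretome_filter(degs, ["g1", "g2", "g3", "g4"]) == degs

    def test_empty_secretome_warns(self, caplog):
        with caplog.at_level("WARNING"):
            assert secretome_filter(["g1"], []) == []
        assert "empty secretome" in caplog.text


class TestRankInterconnected:
    def test_gene_matching_signature_ranks_first(self):
        design = design_of(10)
        rng = np.random.default_rng(0)
        Xi = tissue_frame(rng.normal(size=(5, 10)), design, "islet", "ig")
        # build the islet-signature eigengene and plant it as a liver gene
        zi = (Xi - Xi.mean(axis=1).to_numpy()[:, None])
        zi = zi / zi.std(axis=1, ddof=1).to_numpy()[:, None]
        _, _, vt = np.linalg.svd(
            (Xi.to_numpy() - Xi.to_numpy().mean(1, keepdims=True))
            / Xi.to_numpy().std(1, keepdims=True)
        )
        sig = vt[0]
        Xl = tissue_frame(
            np.vstack([sig, rng.normal(size=10)]), design, "liver", "lg"
        )
        table = rank_interconnected(
            list(Xi.index), list(Xl.index), Xi, Xl, design
        )
        assert table.index[0] == "lg0"
        assert table.iloc[0, 0] == pytest.approx(1.0, abs=1e-8)

    def test_noise_gene_scores_low(self):
        scores = []
        for seed in range(10):
            design = design_of(48)
            rng = np.random.default_rng(seed)
            Xi = tissue_frame(rng.normal(size=(8, 48)), design, "islet", "ig")
            Xl = tissue_frame(rng.normal(size=(1, 48)), design, "liver", "lg")
            t = rank_interconnected(list(Xi.index), ["lg0"], Xi, Xl, design)
            scores.append(t.iloc[0, 0])
        assert np.median(scores) < 0.3

    def test_empty_inputs_give_empty_table(self):
        design = design_of()
        t = rank_interconnected([], [], pd.DataFrame(), pd.DataFrame(), design)
        assert len(t) == 0

    def test_deterministic_ordering(self):
        design = design_of(12)
        rng = np.random.default_rng(5)
        Xi = tissue_frame(rng.normal(size=(4, 12)), design, "islet", "ig")
        Xl = tissue_frame(rng.normal(size=(6, 12)), design, "liver", "lg")
        t1 = rank_interconnected(list(Xi.index), list(Xl.index), Xi, Xl, design)
        t2 = rank_interconnected(list(Xi.index), list(Xl.index), Xi, Xl, design)
        assert list(t1.index) == list(t2.index)
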