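"""Ranking metrics, separability, importance attribution, model comparison."""

import numpy as np
import pytest

from cdrank.classify import ClassifierSpec, FeatureAssembly, train_classifier
from cdrank.evaluate import (
    coefficient_stability,
    compare_models,
    evaluate_prioritizations,
    feature_importance,
    group_similarity,
    precision_at_k_cancer,
    precision_at_k_cell,
)
from cdrank.io import EmbeddingSet, PrioritizationResult


def _result(drug_ids, scores=None):
    n = len(drug_ids)
    scores = scores or [1.0 - i / (n + 1) for i in range(n)]
    return PrioritizationResult(
        cell_id="c", ranked_drugs=[(d, s, i + 1) for i, (d, s) in
                                   enumerate(zip(drug_ids, scores))])


class TestPrecisionAtK:
    def test_all_top_k_effective_is_one(self):
        res = _result(["a", "b", "c", "d"])
        assert precision_at_k_cell(res, {"a", "b", "c"}, 3) == 1.0

    def test_counting_example(self):
        res = _result(["a", "b", "c", "d", "e"])
        assert precision_at_k_cell(res, {"a", "d", "zz"}, 5) == pytest.approx(2 / 5)

    def test_empty_effective_set_is_zero(self):
        assert precision_at_k_cell(_result(["a", "b"]), set(), 2) == 0.0

    @pytest.mark.parametrize("k", [0, -1, 5])
    def test_k_out_of_range_rejected(self, k):
        with pytest.raises(ValueError):
            precision_at_k_cell(_result(["a", "b", "c"]), {"a"}, k)

    def test_agrees_with_brute_force_on_random_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            drugs = [f"d{i:02d}" for i in range(30)]
            rng.shuffle(drugs)
            res = _result(drugs)
            effective = set(rng.choice(drugs, size=rng.integers(0, 31), replace=False))
            for k in range(1, 31):
                brute = sum(1 for d in drugs[:k] if d in effective) / k
                assert precision_at_k_cell(res, effective, k) == pytest.approx(brute)

    def test_full_pool_k_equals_effective_fraction(self):
        drugs = [f"d{i}" for i in range(12)]
        res = _result(drugs)
        eff = {"d0", "d5", "d11"}
        assert precision_at_k_cell(res, eff, 12) == pytest.approx(len(eff) / 12)


class TestPrecisionAtKCancer:
    def test_mean_pooling(self):
        out = precision_at_k_cancer({"c1": 1.0, "c2": 0.5, "c3": 0.25},
                                    {"c1": "Lung", "c2": "Lung", "c3": "Skin"})
        assert out == {"Lung": 0.75, "Skin": 0.25}

    def test_missing_cancer_label_rejected(self):
        with pytest.raises(ValueError, match="no cancer label"):
            precision_at_k_cancer({"c1": 1.0}, {})

    def test_cell_order_invariance(self):
        per_cell = {"a": 0.2, "b": 0.8, "c": 0.5}
        cancer = {"a": "X", "b": "X", "c": "X"}
        rev = dict(reversed(list(per_cell.items())))
        assert precision_at_k_cancer(per_cell, cancer) == \
               precision_at_k_cancer(rev, cancer)


def test_evaluate_prioritizations_report_consistency():
    results = {
        "c1": _result(["a", "b", "c", "d"]),
        "c2": _result(["d", "c", "b", "a"]),
        "c3": _result(["b", "a", "d", "c"]),
    }
    effective = {"c1": {"a"}, "c2": {"a"}, "c3": {"a", "b"}}
    cancer_of = {"c1": "Lung", "c2": "Lung", "c3": "Skin"}
    rep = evaluate_prioritizations(results, effective, cancer_of,
                                   k_cell=(1, 2, 4), k_cancer=(1, 2))
    assert rep.per_cell.loc["c1", 1] == 1.0
    assert rep.per_cell.loc["c2", 1] == 0.0
    # per-cancer value equals the mean of its cells' per-cell values
    for k in (1, 2):
        assert rep.per_cancer.loc["Lung", k] == pytest.approx(
            rep.per_cell.loc[["c1", "c2"], k].mean())
    assert rep.n_effective == {"c1": 1, "c2": 1, "c3": 2}
    assert rep.cells_per_cancer == {"Lung": 2, "Skin": 1}
    assert ((rep.per_cell.values >= 0) & (rep.per_cell.values <= 1)).all()


class TestGroupSimilarity:
    def test_identical_embeddings_give_unit_metrics(self):
        emb = EmbeddingSet("cell", ["a", "b", "c", "d"], np.ones((4, 3)))
        rep = group_similarity(emb, {"a": "g1", "b": "g1", "c": "g2", "d": "g2"})
        assert rep.mean_intra == pytest.approx(1.0)
        assert rep.mean_inter == pytest.approx(1.0)
        assert rep.mean_separability == pytest.approx(1.0)

    def test_hand_computed_two_group_example(self):
        V = np.array([[1, 0], [1, 0], [0.6, 0.8], [0.6, 0.8]])
        emb = EmbeddingSet("cell", list("abcd"), V)
        rep = group_similarity(emb, {"a": "A", "b": "A", "c": "B", "d": "B"})
        assert rep.intra["'A'"] == pytest.approx(1.0)
        assert rep.inter["'A'"] == pytest.approx(0.6)
        assert rep.mean_separability == pytest.approx(1 / 0.6)

    def test_near_zero_inter_capped_with_warning(self):
        V = np.array([[1, 0], [1, 0], [0, 1], [0, 1]])
        emb = EmbeddingSet("cell", list("abcd"), V)
        with pytest.warns(UserWarning, match="capped"):
            rep = group_similarity(emb, {"a": "A", "b": "A", "c": "B", "d": "B"},
                                   max_separability=50.0)
        assert rep.separability["'A'"] == 50.0

    def test_zero_norm_vector_rejected(self):
        emb = EmbeddingSet("cell", ["a", "b", "c"],
                           np.array([[0.0, 0.0], [1, 0], [0, 1]]))
        with pytest.raises(ValueError, match="zero-norm"):
            group_similarity(emb, {"a": "A", "b": "A", "c": "B"})

    def test_singleton_group_skipped_for_intra_with_warning(self):
        emb = EmbeddingSet("cell", ["a", "b", "c"], np.eye(3))
        with pytest.warns(UserWarning, match="single member"):
            rep = group_similarity(emb, {"a": "A", "b": "A", "c": "B"})
        assert "'B'" not in rep.intra and "'B'" in rep.inter

    def test_invariant_to_uniform_positive_rescaling(self):
        rng = np.random.default_rng(4)
        V = rng.normal(size=(10, 5)) + 3.0
        groups = {f"e{i}": i % 2 for i in range(10)}
        emb1 = EmbeddingSet("cell", list(groups), V)
        emb2 = EmbeddingSet("cell", list(groups), 7.5 * V)
        r1 = group_similarity(emb1, groups)
        r2 = group_similarity(emb2, groups)
        assert r1.mean_separability == pytest.approx(r2.mean_separability)


class TestFeatureImportance:
    def _signal_data(self, n=400, seed=0):
        # feature 0 carries the label; features 1-3 are noise
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, size=n)
        X = rng.normal(size=(n, 4))
        X[:, 0] += 3.0 * y
        return X, y

    def test_forest_native_importances_sum_to_one_and_find_signal(self):
        X, y = self._signal_data()
        asm = FeatureAssembly(drug_block_len=2, cell_block_len=2)
        model = train_classifier(X, y, ClassifierSpec(kind="random_forest", seed=0))
        rep = feature_importance(model, asm)
        assert rep.raw.sum() == pytest.approx(1.0)
        assert rep.scaled[0] == 1.0 and rep.raw[0] > rep.raw[1:].max()
        assert rep.sources == ["drug", "drug", "cell", "cell"]

    def test_dense_network_permutation_importance_finds_signal(self):
        X, y = self._signal_data(seed=2)
        asm = FeatureAssembly(drug_block_len=2, cell_block_len=2)
        model = train_classifier(
            X, y, ClassifierSpec(kind="dense_network",
                                 hyperparameters={"max_epochs": 40}, seed=2))
        rep = feature_importance(model, asm, seed=0)
        assert rep.method == "permutation"
        assert np.argmax(rep.raw) == 0

    def test_logistic_requires_stability_acknowledgement(self):
        X, y = self._signal_data(seed=3)
        asm = FeatureAssembly(drug_block_len=2, cell_block_len=2)
        model = train_classifier(X, y, ClassifierSpec(kind="logistic"))
        with pytest.warns(UserWarning, match="coefficient_stability"):
            rep = feature_importance(model, asm)
        assert np.argmax(rep.raw) == 0
        with pytest.raises(ValueError, match="unstable"):
            feature_importance(model, asm, coef_stable=False)

    def test_per_source_mean_uses_scaled_values(self):
        X, y = self._signal_data()
        asm = FeatureAssembly(drug_block_len=2, cell_block_len=2)
        model = train_classifier(X, y, ClassifierSpec(kind="random_forest", seed=1))
        rep = feature_importance(model, asm)
        means = rep.per_source_mean()
        assert means["drug"] == pytest.approx(rep.scaled[:2].mean())
        assert means["cell"] == pytest.approx(rep.scaled[2:].mean())


class TestCoefficientStability:
    def test_identical_folds_are_stable(self):
        M = np.tile([1.0, -2.0, 0.5], (4, 1))
        mean_abs, mean_var, stable = coefficient_stability(M)
        assert mean_var == 0.0 and stable

    def test_sign_flipping_folds_unstable(self):
        M = np.array([[1.0, -1.0], [-1.0, 1.0]])
        _, mean_var, stable = coefficient_stability(M)
        assert not stable and mean_var == pytest.approx(1.0)

    def test_two_orders_of_magnitude_gap_is_stable(self):
        # mirrors the stable-coefficients situation qualitatively:
        # mean variance ~ 8e-3 against mean magnitude ~ 0.38
        rng = np.random.default_rng(0)
        base = rng.normal(scale=0.5, size=50)
        M = base + rng.normal(scale=0.08, size=(5, 50))
        mean_abs, mean_var, stable = coefficient_stability(M)
        assert mean_var < 1e-1 * mean_abs and stable

    def test_single_fold_rejected(self):
        with pytest.raises(ValueError, match="2 folds"):
            coefficient_stability(np.ones((1, 3)))


class TestCompareModels:
    def test_identical_samples_corrected_p_is_one(self):
        t, p, corrected, tier = compare_models([0.5, 0.5, 0.5], [0.5, 0.5, 0.5])
        assert corrected == 1.0 and tier == ""

    def test_bonferroni_cap(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=5)
        b = rng.normal(size=5)
        _, p, corrected, _ = compare_models(a, b, n_comparisons=4)
        assert corrected == min(1.0, p * 4)

    def test_textbook_pooled_t(self):
        t, p, _, _ = compare_models([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert p == pytest.approx(0.0214, abs=2e-3)

    def test_tiers_follow_star_convention(self):
        from cdrank.evaluate import significance_tier
        assert significance_tier(0.0005) == "****"
        assert significance_tier(0.005) == "***"
        assert significance_tier(0.03) == "**"
        assert significance_tier(0.08) == "*"
        assert significance_tier(0.2) == ""
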