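"""Feature fusion, random-forest classification, ROC, and clustering."""

import numpy as np
import pandas as pd
import pytest

from mitoscope import classify as cl
from mitoscope import synthetic as syn
from conftest import oracle_auc

TREES = 100  # enough for stable AUCs at test problem sizes


@pytest.fixture(scope="module")
def cohort():
    return syn.simulate_condition_cohort(syn.CohortSpec(n_per_condition=1000, seed=8))


class TestAssemble:
    def test_inner_join_complete(self):
        a = pd.DataFrame({"object_id": range(10), "solidity": np.ones(10)})
        b = pd.DataFrame({"object_id": range(10), "viscosity_fraction": np.zeros(10)})
        t = cl.assemble_feature_table({"morph": a, "bio": b})
        assert len(t) == 10 and "solidity" in t and "viscosity_fraction" in t

    def test_missing_motility_flagged(self):
        a = pd.DataFrame({"object_id": range(5), "solidity": np.ones(5)})
        d = pd.DataFrame({"object_id": [0, 1], "speed_px_s": [1.0, 2.0],
                          "directionality": [0.5, 0.6], "net_displacement_px": [3, 4]})
        t = cl.assemble_feature_table({"morph": a, "dyn": d})
        assert len(t) == 5
        assert t.motility_missing.sum() == 3

    def test_no_overlap_rejected(self):
        a = pd.DataFrame({"object_id": [1, 2], "x": [0.0, 1.0]})
        b = pd.DataFrame({"object_id": [5, 6], "y": [0.0, 1.0]})
        with pytest.raises(ValueError):
            cl.assemble_feature_table({"a": a, "b": b})

    def test_duplicate_ids_rejected(self):
        a = pd.DataFrame({"object_id": [1, 1], "x": [0.0, 1.0]})
        with pytest.raises(ValueError):
            cl.assemble_feature_table({"a": a})


class TestSplit:
    def test_seventy_thirty_on_ten_thousand(self):
        table = syn.simulate_condition_cohort(syn.CohortSpec(n_per_condition=5000, seed=0))
        train, test = cl.split_train_test(table, seed=0)
        assert len(table) == 10000
        assert abs(len(train) - 7000) <= 2
        assert abs(len(test) - 3000) <= 2

    def test_reproducible(self, cohort):
        a1, b1 = cl.split_train_test(cohort, seed=3)
        a2, b2 = cl.split_train_test(cohort, seed=3)
        assert list(a1.index) == list(a2.index)
        assert list(b1.index) == list(b2.index)

    def test_stratified(self, cohort):
        train, test = cl.split_train_test(cohort, seed=1)
        p_train = (train.condition == "hypoxia").mean()
        p_test = (test.condition == "hypoxia").mean()
        assert abs(p_train - p_test) < 0.01


class TestForest:
    def test_separable_signal_high_accuracy(self):
        rng = np.random.default_rng(0)
        n = 1000
        x = np.concatenate([rng.normal(0, 1, n // 2), rng.normal(5, 1, n // 2)])
        table = pd.DataFrame({
            "object_id": range(n), "x": x,
            "condition": ["a"] * (n // 2) + ["b"] * (n // 2),
        })
        tr, te = cl.split_train_test(table, seed=0)
        model = cl.train_random_forest(tr, seed=0, n_estimators=TREES)
        proba = cl.predict(model, te)
        acc = (model.classes_[proba.argmax(axis=1)] == te.condition).mean()
        assert acc >= 0.95

    def test_deterministic_per_seed(self, cohort):
        tr, te = cl.split_train_test(cohort, seed=0)
        p1 = cl.predict(cl.train_random_forest(tr, seed=4, n_estimators=50), te)
        p2 = cl.predict(cl.train_random_forest(tr, seed=4, n_estimators=50), te)
        assert np.array_equal(p1, p2)

    def test_single_class_rejected(self):
        t = pd.DataFrame({"object_id": range(4), "x": np.arange(4.0), "condition": ["a"] * 4})
        with pytest.raises(ValueError):
            cl.train_random_forest(t, seed=0)


class TestROC:
    def test_perfect_and_reversed(self):
        labels = np.array([0, 0, 1, 1])
        assert cl.evaluate_roc([0.1, 0.2, 0.8, 0.9], labels)[2] == 1.0
        assert cl.evaluate_roc([0.9, 0.8, 0.2, 0.1], labels)[2] == 0.0

    def test_worked_pair_counting_example(self):
        _, _, auc = cl.evaluate_roc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert auc == pytest.approx(0.75)

    def test_oracle_equivalence_random_sets(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 200))
            scores = rng.normal(size=n).round(2)  # rounding forces ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            _, _, auc = cl.evaluate_roc(scores, labels)
            assert auc == pytest.approx(oracle_auc(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            cl.evaluate_roc([0.1, 0.2], [1, 1])


class TestImportances:
    def test_sum_to_one_and_informative_first(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 400
            y = rng.integers(0, 2, n)
            data = {f"noise_{i}": rng.normal(size=n) for i in range(5)}
            data["signal"] = y * 2.0 + rng.normal(size=n) * 0.5
            t = pd.DataFrame({"object_id": range(n), **data,
                              "condition": np.where(y == 1, "b", "a")})
            model = cl.train_random_forest(t, seed=seed, n_estimators=TREES)
            imp = cl.feature_importances(model)
            assert imp.sum() == pytest.approx(1.0, abs=1e-9)
            if imp.index[0] == "signal":
                hits += 1
        assert hits >= 19

    def test_duplicated_feature_shares_importance(self):
        rng = np.random.default_rng(1)
        n = 600
        y = rng.integers(0, 2, n)
        signal = y * 2.0 + rng.normal(size=n) * 0.6
        base = pd.DataFrame({
            "object_id": range(n), "signal": signal,
            "noise": rng.normal(size=n),
            "condition": np.where(y == 1, "b", "a"),
        })
        dup = base.copy()
        dup.insert(2, "signal_copy", signal)
        m1 = cl.train_random_forest(base, seed=0, n_estimators=TREES)
        m2 = cl.train_random_forest(dup, seed=0, n_estimators=TREES)
        i1 = cl.feature_importances(m1)
        i2 = cl.feature_importances(m2)
        combined = i2["signal"] + i2["signal_copy"]
        assert combined == pytest.approx(i1["signal"], abs=0.2 * i1["signal"])


class TestCrossValidation:
    def test_fold_partition_and_separable(self):
        table = syn.simulate_condition_cohort(syn.CohortSpec(n_per_condition=300, seed=2))
        scores = cl.cross_validate(table, k=5, seeds=(0,), n_estimators=TREES)
        assert scores.shape == (1, 5)
        assert (scores >= 0.8).all()

    def test_null_folds_near_half(self):
        table = syn.simulate_condition_cohort(
            syn.CohortSpec(n_per_condition=300, effect_scale=0.0, seed=3)
        )
        scores = cl.cross_validate(table, k=5, seeds=(0, 1), n_estimators=TREES)
        assert 0.4 < scores.mean() < 0.6

    def test_k_larger_than_class_rejected(self):
        t = pd.DataFrame({"object_id": range(6), "x": np.arange(6.0),
                          "condition": ["a", "a", "a", "b", "b", "b"]})
        with pytest.raises(ValueError):
            cl.cross_validate(t, k=5)


class TestClustering:
    def test_two_blobs_recovered(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 0.5, size=(100, 3))
        b = rng.normal(5, 0.5, size=(100, 3))
        t = pd.DataFrame(np.vstack([a, b]), columns=["x", "y", "z"])
        t.insert(0, "object_id", range(200))
        rep = cl.cluster_subpopulations(t, k=2, seed=0)
        assert rep.silhouette >= 0.6
        first, second = rep.labels[:100], rep.labels[100:]
        assert len(set(first)) == 1 and len(set(second)) == 1 and first[0] != second[0]

    def test_single_blob_low_silhouette(self):
        rng = np.random.default_rng(5)
        t = pd.DataFrame(rng.normal(size=(200, 3)), columns=["x", "y", "z"])
        t.insert(0, "object_id", range(200))
        rep = cl.cluster_subpopulations(t, k=2, seed=0)
        assert rep.silhouette <= 0.3

    def test_probabilities_rows_sum_to_one(self, cohort):
        rep = cl.cluster_subpopulations(cohort.drop(columns="condition"), k=2, seed=0)
        assert np.allclose(rep.probabilities.sum(axis=1), 1.0)
        assert (rep.probabilities >= 0).all()

    def test_pca_variance_monotone(self, cohort):
        rep = cl.cluster_subpopulations(cohort.drop(columns="condition"), k=2, seed=0)
        ev = rep.explained_variance_ratio
        assert ev[0] >= ev[1] and ev.sum() <= 1.0 + 1e-9

    def test_constant_features_rejected(self):
        t = pd.DataFrame({"object_id": range(10), "x": np.ones(10)})
        with pytest.raises(ValueError):
            cl.cluster_subpopulations(t, k=2)

    def test_augmentation_adds_one_column(self, cohort):
        rep = cl.cluster_subpopulations(cohort.drop(columns="condition"), k=2, seed=0)
        out = cl.augment_with_cluster_probability(cohort, rep)
        assert out.shape[1] == cohort.shape[1] + 1
        assert "cluster_probability" in out.columns

    def test_augmentation_row_mismatch(self, cohort):
        rep = cl.cluster_subpopulations(cohort.drop(columns="condition"), k=2, seed=0)
        with pytest.raises(ValueError):
            cl.augment_with_cluster_probability(cohort.iloc[:10], rep)


class TestMacroAUC:
    def test_perfectly_ordered(self):
        labels = np.repeat(["a", "b", "c", "d"], 10)
        scores = np.zeros((40, 4))
        for i in range(4):
            scores[10 * i : 10 * (i + 1), i] = 1.0
        assert cl.macro_auc_multiclass(scores, labels, classes=np.array(list("abcd"))) == 1.0

    def test_random_scores_near_half(self):
        aucs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            labels = rng.choice(list("abcd"), size=400)
            scores = rng.uniform(size=(400, 4))
            aucs.append(cl.macro_auc_multiclass(scores, labels, classes=np.array(list("abcd"))))
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_single_level_rejected(self):
        with pytest.raises(ValueError):
            cl.macro_auc_multiclass(np.ones((5, 2)), np.array(["a"] * 5),
                                    classes=np.array(["a", "b"]))
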