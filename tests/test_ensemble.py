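"""Selection rule, stacking, confusion-matrix metrics, feature selection, K-fold."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import confusion_matrix, matthews_corrcoef
from sklearn.tree import DecisionTreeClassifier

from mammocad import (
    DEFAULT_K_VALUES,
    MODEL_ORDER,
    REFERENCE_TEST_ACCURACIES,
    AccuracyThresholdStackingClassifier,
    EnsembleSpec,
    FeatureSelectionConfig,
    FeatureTableSpec,
    ModelBankConfig,
    generate_feature_table,
    kfold_sweep,
    make_model_bank,
    metrics_from_confusion,
    select_by_accuracy,
    select_features,
    split_dataset,
    train_bank,
    train_stacked,
)
from mammocad.features import minmax_normalize


def _separable_split(seed=0, n_per_class=40, separation=6.0, noise=0):
    table = generate_feature_table(
        FeatureTableSpec(n_per_class=n_per_class, class_separation=separation,
                         noise_features=noise, rng_seed=seed)
    )
    train, test = split_dataset(table, 0.2, seed)
    train_n, scaler = minmax_normalize(train)
    test_n, _ = minmax_normalize(test, scaler)
    return train_n, test_n


class TestSplit:
    def test_80_20_sizes(self):
        table = generate_feature_table(FeatureTableSpec(n_per_class=25))
        train, test = split_dataset(table, 0.2, 0)
        assert len(train) == 80 and len(test) == 20

    def test_deterministic(self):
        table = generate_feature_table(FeatureTableSpec(n_per_class=20))
        a_train, a_test = split_dataset(table, 0.2, 5)
        b_train, b_test = split_dataset(table, 0.2, 5)
        assert a_train.equals(b_train) and a_test.equals(b_test)

    def test_stratified_proportions(self):
        table = generate_feature_table(FeatureTableSpec(n_per_class=50))
        train, test = split_dataset(table, 0.2, 1)
        for part in (train, test):
            props = part["label"].value_counts(normalize=True)
            assert np.allclose(props, 0.25, atol=0.02)


class TestMetrics:
    def test_perfect_diagonal(self):
        m = metrics_from_confusion(np.diag([5, 7, 3, 9]))
        assert m["accuracy"] == 1.0
        assert m["mcc"] == pytest.approx(1.0)
        assert m["f1_macro"] == pytest.approx(1.0)

    def test_binary_balanced_random(self):
        # TP=TN=FP=FN=1
        m = metrics_from_confusion(np.array([[1, 1], [1, 1]]))
        assert m["accuracy"] == 0.5
        assert m["mcc"] == pytest.approx(0.0)
        assert m["f1_macro"] == pytest.approx(0.5)

    def test_multiclass_mcc_matches_sklearn(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            y_true = rng.integers(0, 4, 200)
            y_pred = np.where(rng.random(200) < 0.6, y_true, rng.integers(0, 4, 200))
            cm = confusion_matrix(y_true, y_pred, labels=[0, 1, 2, 3])
            m = metrics_from_confusion(cm)
            assert m["mcc"] == pytest.approx(matthews_corrcoef(y_true, y_pred))
            assert m["accuracy"] == pytest.approx((y_true == y_pred).mean())
            assert -1.0 <= m["mcc"] <= 1.0

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(1)
        cm = rng.integers(0, 30, (4, 4))
        perm = np.array([2, 0, 3, 1])
        cm_p = cm[np.ix_(perm, perm)]
        a, b = metrics_from_confusion(cm), metrics_from_confusion(cm_p)
        assert a["accuracy"] == pytest.approx(b["accuracy"])
        assert a["mcc"] == pytest.approx(b["mcc"])
        assert a["f1_macro"] == pytest.approx(b["f1_macro"])

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            metrics_from_confusion(np.zeros((0, 0)))
        with pytest.raises(ValueError):
            metrics_from_confusion(np.array([[1, -2], [0, 1]]))


class TestSelectionRule:
    def test_published_accuracies_threshold_90(self):
        spec = select_by_accuracy(REFERENCE_TEST_ACCURACIES, 90)
        assert set(spec.selected_members) == {"KNN", "SVC", "DT", "RF", "XGB"}
        assert len(spec.selected_members) == 5

    def test_published_accuracies_threshold_93(self):
        spec = select_by_accuracy(REFERENCE_TEST_ACCURACIES, 93)
        assert set(spec.selected_members) == {"DT", "RF", "XGB"}

    def test_published_accuracies_threshold_95(self):
        spec = select_by_accuracy(REFERENCE_TEST_ACCURACIES, 95)
        assert set(spec.selected_members) == {"RF", "XGB"}

    def test_order_preserves_bank_declaration(self):
        spec = select_by_accuracy(REFERENCE_TEST_ACCURACIES, 90)
        order = [MODEL_ORDER.index(m) for m in spec.selected_members]
        assert order == sorted(order)

    def test_empty_selection_raises(self):
        with pytest.raises(ValueError):
            select_by_accuracy(REFERENCE_TEST_ACCURACIES, 100)

    def test_strictly_greater(self):
        # a member exactly at the threshold is excluded
        spec = select_by_accuracy({"RF": 95.91, "XGB": 95.40}, 95.40)
        assert spec.selected_members == ("RF",)
        with pytest.raises(ValueError):
            select_by_accuracy({"RF": 95.91}, 95.91)


class TestBankAndStack:
    def test_bank_has_eleven_members(self):
        bank = make_model_bank(0)
        assert tuple(bank) == MODEL_ORDER
        assert len(bank) == 11

    def test_tree_models_ace_separable_table(self):
        train_n, test_n = _separable_split(seed=0)
        report = train_bank(train_n, test_n,
                            ModelBankConfig(members=("DT", "RF", "XGB")))
        for name in ("DT", "RF", "XGB"):
            assert report[name]["te_acc"] > 95.0

    def test_single_member_stack_close_to_member(self):
        train_n, test_n = _separable_split(seed=1, separation=2.0, noise=8)
        report = train_bank(train_n, test_n, ModelBankConfig(members=("RF",)))
        stacked = train_stacked(train_n, test_n, EnsembleSpec(0.0, ("RF",)),
                                seed=1, cv=5)
        assert abs(stacked["te_acc"] - report["RF"]["te_acc"]) <= 8.0

    def test_rf_xgb_stack_on_separable_table(self):
        for seed in range(3):
            train_n, test_n = _separable_split(seed=seed)
            stacked = train_stacked(train_n, test_n,
                                    EnsembleSpec(95.0, ("RF", "XGB")),
                                    seed=seed, cv=5)
            assert stacked["te_acc"] >= 95.0

    def test_stack_predictions_are_valid_labels(self):
        train_n, test_n = _separable_split(seed=2)
        clf = AccuracyThresholdStackingClassifier(
            members=("RF", "XGB"), accuracy_threshold=None, stack_cv=3
        )
        X = train_n.drop(columns="label").to_numpy()
        y = train_n["label"].to_numpy()
        clf.fit(X, y)
        preds = clf.predict(test_n.drop(columns="label").to_numpy())
        assert set(preds) <= set(y)
        proba = clf.predict_proba(test_n.drop(columns="label").to_numpy())
        assert np.allclose(proba.sum(axis=1), 1.0)

    def test_estimator_selects_by_internal_cv(self):
        train_n, _ = _separable_split(seed=3)
        clf = AccuracyThresholdStackingClassifier(
            members=("RF", "GNB"), accuracy_threshold=90.0,
            selection_cv=3, stack_cv=3,
        )
        X = train_n.drop(columns="label").to_numpy()
        y = train_n["label"].to_numpy()
        clf.fit(X, y)
        assert "RF" in clf.selected_members_
        assert clf.member_scores_["RF"] > 90.0

    def test_accuracy_monotone_in_separation(self):
        means = []
        for sep in (0.5, 2.0, 6.0):
            accs = []
            for seed in range(3):
                train_n, test_n = _separable_split(seed=seed, separation=sep,
                                                   noise=8)
                rep = train_bank(train_n, test_n, ModelBankConfig(members=("RF",)))
                accs.append(rep["RF"]["te_acc"])
            means.append(np.mean(accs))
        assert means[0] < means[1] + 5 and means[1] < means[2] + 5
        assert means[2] > means[0]


class TestFeatureSelection:
    def test_rf_importance_zero_threshold_keeps_all(self):
        train_n, _ = _separable_split(seed=0)
        cfg = select_features(train_n,
                              FeatureSelectionConfig("rf_importance", threshold=0.0))
        assert len(cfg.selected) == 16

    @pytest.mark.parametrize(
        "method_cfg",
        [
            FeatureSelectionConfig("rf_importance", threshold=0.045),
            FeatureSelectionConfig("univariate", k=4),
            FeatureSelectionConfig("correlation", threshold=0.05),
            FeatureSelectionConfig("wrapper", threshold=0.01),
        ],
        ids=lambda c: c.method,
    )
    def test_informative_features_found(self, method_cfg):
        # 2 informative + 14 noise columns: f00 marks class 0, f01 class 1
        for seed in range(5):
            table = generate_feature_table(
                FeatureTableSpec(n_per_class=40, n_features=16,
                                 class_separation=4.0, noise_features=14,
                                 rng_seed=seed)
            )
            train, _ = split_dataset(table, 0.2, seed)
            train_n, _ = minmax_normalize(train)
            cfg = select_features(train_n, method_cfg)
            assert {"f00", "f01"} <= set(cfg.selected)

    def test_pca_components_named(self):
        train_n, _ = _separable_split(seed=0)
        cfg = select_features(train_n,
                              FeatureSelectionConfig("pca", n_components=10))
        assert cfg.selected == tuple(f"PC{i}" for i in range(1, 11))

    def test_threshold_monotone(self):
        train_n, _ = _separable_split(seed=4)
        kept = [
            len(select_features(
                train_n, FeatureSelectionConfig("rf_importance", threshold=t)
            ).selected)
            for t in (0.0, 0.02, 0.05)
        ]
        assert kept[0] >= kept[1] >= kept[2]

    def test_impossible_threshold_raises(self):
        train_n, _ = _separable_split(seed=0)
        with pytest.raises(ValueError):
            select_features(train_n,
                            FeatureSelectionConfig("rf_importance", threshold=2.0))


class TestKFoldSweep:
    def test_twelve_default_k_values_span_3_to_30(self):
        assert len(DEFAULT_K_VALUES) == 12
        assert min(DEFAULT_K_VALUES) == 3 and max(DEFAULT_K_VALUES) == 30

    def test_sweep_on_separable_table_is_stable(self):
        table = generate_feature_table(
            FeatureTableSpec(n_per_class=40, class_separation=6.0,
                             noise_features=0, rng_seed=0)
        )
        table_n, _ = minmax_normalize(table)
        sweep = kfold_sweep(table_n, DecisionTreeClassifier(random_state=0),
                            (3, 5, 10, 20, 30), seed=0)
        assert sweep["mean_acc"].max() - sweep["mean_acc"].min() <= 3.0

    def test_leave_one_out_boundary(self):
        table = generate_feature_table(
            FeatureTableSpec(n_per_class=5, class_separation=6.0,
                             noise_features=0, rng_seed=1)
        )
        sweep = kfold_sweep(table, DecisionTreeClassifier(random_state=0),
                            (len(table),), seed=0)
        assert len(sweep) == 1

    def test_k_exceeding_class_count_raises(self):
        table = generate_feature_table(FeatureTableSpec(n_per_class=5))
        with pytest.raises(ValueError):
            kfold_sweep(table, DecisionTreeClassifier(), (7,), seed=0)
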