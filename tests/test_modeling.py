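"""Grouped folds, undersampling, feature selection, SVM tuning, nested CV."""

import numpy as np
import pandas as pd
import pytest

from oxipulse.config import ModelingParams
from oxipulse.features import FEATURE_NAMES
from oxipulse.modeling import (
    FEATURE_SETS,
    make_grouped_folds,
    run_nested_cv,
    select_features_rfecv,
    tune_and_train,
    undersample,
)

FAST = ModelingParams(rf_n_estimators=25)


def planted_table(
    n_subjects=10,
    segs_per_subject=40,
    informative=("Var_Sp", "Min_Sp"),
    effect=2.0,
    pos_frac=0.3,
    seed=0,
    columns=FEATURE_SETS["SpO2"],
):
    """Feature table with a planted effect in the chosen columns only."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        labels = (rng.uniform(size=segs_per_subject) < pos_frac).astype(int)
        for i, y in enumerate(labels):
            row = {
                "subject_id": f"subj-{s:02d}",
                "start_s": 60.0 * i,
                "label": int(y),
                "arousal": bool(rng.uniform() < 0.5),
                "quality": "ok",
            }
            for c in columns:
                row[c] = rng.standard_normal() + (effect * y if c in informative else 0.0)
            rows.append(row)
    return pd.DataFrame(rows)


class TestGroupedFolds:
    def test_ninety_subjects_split_into_equal_folds(self):
        subjects = np.array([f"s{i}" for i in range(90)])
        folds = make_grouped_folds(subjects, k=5, seed=0)
        counts = np.bincount(list(folds.values()))
        assert counts.tolist() == [18] * 5  # 72 train / 18 test per fold

    def test_deterministic_for_fixed_seed(self):
        subjects = np.array([f"s{i}" for i in range(13)])
        assert make_grouped_folds(subjects, 5, 3) == make_grouped_folds(subjects, 5, 3)

    def test_sizes_differ_by_at_most_one(self):
        folds = make_grouped_folds(np.array([f"s{i}" for i in range(13)]), k=5, seed=1)
        counts = np.bincount(list(folds.values()))
        assert counts.max() - counts.min() <= 1

    def test_more_folds_than_subjects_rejected(self):
        with pytest.raises(ValueError):
            make_grouped_folds(np.array(["a", "b"]), k=3, seed=0)


class TestUndersample:
    def test_majority_thinned_to_minority(self):
        y = np.array([0] * 100 + [1] * 30)
        idx = undersample(y, seed=0)
        assert (y[idx] == 0).sum() == 30 and (y[idx] == 1).sum() == 30

    def test_balanced_input_unchanged(self):
        y = np.array([0, 1] * 25)
        assert set(undersample(y, seed=0)) == set(range(50))

    def test_reproducible_for_fixed_seed(self):
        y = np.array([0] * 80 + [1] * 20)
        np.testing.assert_array_equal(undersample(y, seed=5), undersample(y, seed=5))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            undersample(np.zeros(10), seed=0)


class TestFeatureSelection:
    def test_planted_informative_features_retained(self):
        tab = planted_table(seed=1)
        X, y = tab[list(FEATURE_SETS["SpO2"])], tab["label"].to_numpy()
        hits = 0
        for seed in range(5):
            selected, _ = select_features_rfecv(X, y, seed=seed, params=FAST)
            hits += {"Var_Sp", "Min_Sp"} <= set(selected)
        assert hits >= 4

    def test_single_column_returned_as_is(self):
        tab = planted_table(seed=2)
        selected, _ = select_features_rfecv(tab[["Var_Sp"]], tab["label"].to_numpy(),
                                            seed=0, params=FAST)
        assert selected == ["Var_Sp"]

    def test_constant_columns_dropped_with_warning(self):
        tab = planted_table(seed=3)
        tab["Fuzz_Sp"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            selected, _ = select_features_rfecv(
                tab[list(FEATURE_SETS["SpO2"])], tab["label"].to_numpy(),
                seed=0, params=FAST,
            )
        assert "Fuzz_Sp" not in selected


class TestSvmTuning:
    def test_separable_blobs_fit_perfectly(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(
            np.vstack([rng.normal(-3, 0.3, (40, 2)), rng.normal(3, 0.3, (40, 2))]),
            columns=["a", "b"],
        )
        y = np.array([0] * 40 + [1] * 40)
        clf, best = tune_and_train(X, y, seed=0)
        assert (clf.predict(X.values) == y).all()
        assert best["C"] in (0.1, 1.0) and best["kernel"] in ("rbf", "poly")

    def test_permuted_labels_give_chance_auc(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.standard_normal((300, 4)), columns=list("abcd"))
        y = rng.integers(0, 2, size=300)
        clf, _ = tune_and_train(X.iloc[:200], y[:200], seed=0)
        auc = roc_auc_score(y[200:], clf.decision_function(X.iloc[200:].values))
        assert auc == pytest.approx(0.5, abs=0.12)

    def test_hyperparameters_deterministic(self):
        tab = planted_table(n_subjects=4, seed=4)
        X, y = tab[["Var_Sp", "Min_Sp"]], tab["label"].to_numpy()
        assert tune_and_train(X, y, seed=9)[1] == tune_and_train(X, y, seed=9)[1]


class TestNestedCv:
    def test_predictions_cover_every_held_out_segment_once(self):
        tab = planted_table(seed=5)
        results = run_nested_cv(tab, ["SpO2"], k=5, seed=0, params=FAST)["SpO2"]
        covered = pd.concat([fr.predictions for fr in results])
        assert len(covered) == len(tab)
        key = ["subject_id", "start_s"]
        assert (
            covered[key].sort_values(key).reset_index(drop=True)
            .equals(tab[key].sort_values(key).reset_index(drop=True))
        )
        for fr in results:
            assert set(fr.predictions["subject_id"]) == set(fr.test_subjects)

    def test_deterministic_fold_results(self):
        tab = planted_table(n_subjects=6, segs_per_subject=30, seed=6)
        a = run_nested_cv(tab, ["SpO2"], k=3, seed=11, params=FAST)["SpO2"]
        b = run_nested_cv(tab, ["SpO2"], k=3, seed=11, params=FAST)["SpO2"]
        for fa, fb in zip(a, b):
            assert fa.selected_features == fb.selected_features
            assert fa.hyperparameters == fb.hyperparameters
            np.testing.assert_array_equal(
                fa.predictions["score"].to_numpy(), fb.predictions["score"].to_numpy()
            )

    def test_unknown_feature_set_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            run_nested_cv(planted_table(seed=7), ["Nope"], k=3, seed=0, params=FAST)

    def test_planted_effect_recovered_above_chance(self):
        from sklearn.metrics import roc_auc_score

        tab = planted_table(seed=8, effect=2.5)
        results = run_nested_cv(tab, ["SpO2"], k=5, seed=0, params=FAST)["SpO2"]
        pooled = pd.concat([fr.predictions for fr in results])
        auc = roc_auc_score(pooled["label"], pooled["score"])
        assert auc > 0.9

    def test_held_out_label_shuffle_leaves_training_artifacts_unchanged(self):
        """Leakage audit: labels of fold-0 test subjects cannot influence the
        features or hyperparameters chosen on the training side of fold 0."""
        tab = planted_table(seed=9)
        results = run_nested_cv(tab, ["SpO2"], k=5, seed=3, params=FAST)["SpO2"]
        fold0 = results[0]
        rng = np.random.default_rng(0)
        shuffled = tab.copy()
        mask = shuffled["subject_id"].isin(fold0.test_subjects)
        shuffled.loc[mask, "label"] = rng.permutation(
            shuffled.loc[mask, "label"].to_numpy()
        )
        results2 = run_nested_cv(shuffled, ["SpO2"], k=5, seed=3, params=FAST)["SpO2"]
        assert results2[0].selected_features == fold0.selected_features
        assert results2[0].hyperparameters == fold0.hyperparameters
        np.testing.assert_array_equal(
            results2[0].predictions["score"].to_numpy(),
            fold0.predictions["score"].to_numpy(),
        )


def test_feature_set_census_matches_families():
    assert set(FEATURE_SETS) == {"SpO2", "PWA+SpO2", "PPI+SpO2", "PWA+PPI", "PWA+PPI+SpO2"}
    assert set(FEATURE_SETS["PWA+PPI+SpO2"]) == set(FEATURE_NAMES)
    assert len(FEATURE_SETS["SpO2"]) == 7
    assert len(FEATURE_SETS["PWA+PPI"]) == 30
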