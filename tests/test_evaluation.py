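"""Metrics, AHI estimation, screening decisions and importance ranking."""

import numpy as np
import pandas as pd
import pytest

from oxipulse.evaluation import (
    arousal_stratified_detection,
    compare_feature_sets,
    estimate_ahi,
    feature_importance,
    screen_subjects,
    segment_metrics,
    severity_class,
)
from oxipulse.modeling import FoldResult


def fold(labels, preds, scores=None, arousal=None, fold_idx=0):
    n = len(labels)
    return FoldResult(
        fold=fold_idx,
        feature_set="t",
        selected_features=["f"],
        hyperparameters={},
        test_subjects=["s"],
        predictions=pd.DataFrame(
            {
                "subject_id": ["s"] * n,
                "start_s": 60.0 * np.arange(n),
                "label": labels,
                "arousal": arousal if arousal is not None else [False] * n,
                "score": scores if scores is not None else np.asarray(preds, float),
                "pred": preds,
            }
        ),
    )


class TestSegmentMetrics:
    def test_perfect_predictions(self):
        y = [0, 1, 0, 1, 1, 0]
        m = segment_metrics([fold(y, y)]).per_fold.iloc[0]
        assert m["accuracy"] == m["sensitivity"] == m["specificity"] == 100.0
        assert m["auc"] == 1.0

    def test_all_negative_predictor_on_imbalanced_data(self):
        y = [1] * 22 + [0] * 78
        m = segment_metrics([fold(y, [0] * 100)]).per_fold.iloc[0]
        assert m["specificity"] == 100.0
        assert m["sensitivity"] == 0.0
        assert m["accuracy"] == 78.0

    def test_random_scores_give_chance_auc(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 1000)
        scores = rng.standard_normal(1000)
        m = segment_metrics([fold(y, (scores > 0).astype(int), scores)]).per_fold.iloc[0]
        assert m["auc"] == pytest.approx(0.5, abs=0.05)

    def test_mean_sd_aggregation_across_folds(self):
        folds = [fold([0, 1, 1, 0], [0, 1, 1, 0], fold_idx=0),
                 fold([0, 1, 1, 0], [0, 1, 0, 0], fold_idx=1)]
        sm = segment_metrics(folds)
        assert sm.mean["sensitivity"] == 75.0
        assert sm.sd["sensitivity"] == pytest.approx(np.std([100, 50], ddof=1))


class TestArousalStratification:
    def test_all_detected_gives_full_recall_in_both_strata(self):
        out = arousal_stratified_detection([1, 1, 1, 0], [1, 1, 1, 0],
                                           [True, False, True, False])
        assert out == {"with_arousal": 100.0, "no_arousal": 100.0}

    def test_desaturation_only_detector_misses_arousal_stratum(self):
        # positives: 10 arousal-only (undetected), 10 desaturating (detected)
        labels = [1] * 20
        arousal = [True] * 10 + [False] * 10
        preds = [0] * 10 + [1] * 10
        out = arousal_stratified_detection(labels, preds, arousal)
        assert out["no_arousal"] > out["with_arousal"]
        assert out == {"with_arousal": 0.0, "no_arousal": 100.0}

    def test_overall_recall_is_weighted_stratum_mean(self):
        rng = np.random.default_rng(1)
        labels = np.ones(200, dtype=int)
        arousal = rng.uniform(size=200) < 0.4
        preds = (rng.uniform(size=200) < 0.7).astype(int)
        out = arousal_stratified_detection(labels, preds, arousal)
        n_a, n_n = arousal.sum(), (~arousal).sum()
        weighted = (out["with_arousal"] * n_a + out["no_arousal"] * n_n) / 200
        assert weighted == pytest.approx(100.0 * preds.mean(), abs=1e-9)

    def test_empty_stratum_is_nan(self):
        out = arousal_stratified_detection([1, 1], [1, 0], [True, True])
        assert np.isnan(out["no_arousal"])


class TestAhi:
    @pytest.mark.parametrize(
        "preds,hours,expected",
        [([0, 0, 0], 1.0, 0.0), ([1] * 120, 2.0, 60.0), ([1] * 30 + [0] * 420, 7.5, 4.0)],
    )
    def test_estimate_arithmetic(self, preds, hours, expected):
        assert estimate_ahi(np.array(preds), hours) == expected

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            estimate_ahi(np.array([1]), 0.0)


class TestSeverity:
    @pytest.mark.parametrize(
        "ahi,expected",
        [(0.0, "none"), (4.9, "none"), (5.0, "mild"), (14.9, "mild"),
         (15.0, "moderate"), (30.0, "moderate"), (30.01, "severe"), (31.0, "severe")],
    )
    def test_bins(self, ahi, expected):
        assert severity_class(ahi) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            severity_class(-1.0)


class TestScreening:
    def test_perfect_estimates(self):
        ref = {f"s{i}": float(a) for i, a in enumerate([3, 8, 20, 40, 12, 17])}
        rep = screen_subjects(ref, ref)
        assert rep.sensitivity_pct == 100.0 and rep.specificity_pct == 100.0
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.confusion.sum() == 6

    def test_systematic_underestimation_creates_false_negatives(self):
        ref = {f"s{i}": float(a) for i, a in enumerate([10, 16, 18, 25, 40])}
        est = {k: v - 5.0 for k, v in ref.items()}
        rep = screen_subjects(est, ref)
        # subjects with reference in [15, 20) drop below threshold
        fn = rep.confusion[1, 0]
        assert fn == 2  # 16 and 18
        assert rep.sensitivity_pct == pytest.approx(100.0 * 2 / 4)

    def test_threshold_boundary_inclusive(self):
        rep = screen_subjects({"a": 15.0, "b": 14.999, "c": 20.0, "d": 3.0},
                              {"a": 20.0, "b": 20.0, "c": 25.0, "d": 2.0})
        decisions = dict(zip(rep.table["subject_id"], rep.table["decision"]))
        assert decisions["a"] and not decisions["b"]

    def test_raising_threshold_monotone_in_sens_spec(self):
        rng = np.random.default_rng(2)
        ref = {f"s{i}": float(v) for i, v in enumerate(rng.uniform(0, 45, 40))}
        est = {k: v + rng.normal(0, 5) for k, v in ref.items()}
        # fixed truth, varying decision threshold: classic ROC monotonicity
        truth = np.array([ref[k] >= 15 for k in sorted(ref)])
        scores = np.array([est[k] for k in sorted(ref)])
        senss, specs = [], []
        for thr in (5.0, 15.0, 30.0):
            dec = scores >= thr
            senss.append((dec & truth).sum() / truth.sum())
            specs.append((~dec & ~truth).sum() / (~truth).sum())
        assert senss == sorted(senss, reverse=True)
        assert specs == sorted(specs)

    def test_comorbidity_strata_recomputed(self):
        rng = np.random.default_rng(3)
        ref = {f"s{i}": float(v) for i, v in enumerate(rng.uniform(0, 45, 20))}
        com = {k: i % 2 == 0 for i, k in enumerate(sorted(ref))}
        rep = screen_subjects(ref, ref, comorbidity=com)
        assert "with_comorbidities" in rep.strata
        sub = rep.strata["with_comorbidities"]
        assert sub.confusion.sum() == sum(com.values())

    def test_mismatched_subjects_rejected(self):
        with pytest.raises(ValueError):
            screen_subjects({"a": 1.0}, {"b": 1.0})


class TestFeatureImportance:
    @staticmethod
    def _fitted_fold(seed, informative="Var_Sp"):
        from sklearn.ensemble import RandomForestClassifier

        rng = np.random.default_rng(seed)
        cols = ["Var_Sp", "Min_Sp", "Std_Sp"]
        y = rng.integers(0, 2, 200)
        X = rng.standard_normal((200, 3))
        X[:, 0] += 3.0 * y  # plant the effect in the first column
        forest = RandomForestClassifier(n_estimators=25, random_state=seed).fit(X, y)
        fr = fold(y.tolist(), y.tolist(), fold_idx=seed)
        fr.selected_features = cols
        fr.forest = forest
        return fr

    def test_planted_feature_ranked_first(self):
        folds = [self._fitted_fold(s) for s in range(5)]
        imp = feature_importance(folds)
        assert imp.index[0] == "Var_Sp"

    def test_importances_normalized_per_fold(self):
        fr = self._fitted_fold(0)
        assert fr.forest.feature_importances_.sum() == pytest.approx(1.0)
        assert (fr.forest.feature_importances_ >= 0).all()

    def test_missing_feature_contributes_zero(self):
        f1, f2 = self._fitted_fold(0), self._fitted_fold(1)
        f2.selected_features = ["Other_A", "Other_B", "Other_C"]
        imp = feature_importance([f1, f2])
        assert imp["Var_Sp"] == pytest.approx(
            dict(zip(f1.selected_features, f1.forest.feature_importances_))["Var_Sp"] / 2
        )


def test_compare_feature_sets_reports_anova_and_paired_tests():
    from oxipulse.evaluation import SegmentMetrics

    rng = np.random.default_rng(4)
    metrics = {}
    for name, shift in (("SpO2", 0.0), ("PPI+SpO2", 0.03)):
        per_fold = pd.DataFrame(
            {"fold": range(5), "auc": 0.84 + shift + rng.normal(0, 0.01, 5)}
        )
        metrics[name] = SegmentMetrics(per_fold)
    out = compare_feature_sets(metrics, metric="auc")
    assert out.iloc[0]["comparison"] == "rm-ANOVA"
    assert "PPI+SpO2 vs SpO2" in set(out["comparison"])
    assert ((out["p_corrected"] >= 0) & (out["p_corrected"] <= 1)).all()


def test_plotting_helpers_return_axes(tmp_path):
    import matplotlib.pyplot as plt

    from oxipulse.plotting import plot_ahi_scatter, plot_confusion

    rng = np.random.default_rng(5)
    ref = {f"s{i}": float(v) for i, v in enumerate(rng.uniform(0, 45, 15))}
    est = {k: max(0.0, v + rng.normal(0, 4)) for k, v in ref.items()}
    rep = screen_subjects(est, ref)
    ax1 = plot_ahi_scatter(rep)
    ax2 = plot_confusion(rep)
    assert ax1.get_xlabel() and ax2.get_xlabel()
    plt.close("all")
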