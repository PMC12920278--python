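"""Per-segment and per-subject evaluation surfaces.

Segment level: accuracy, sensitivity, specificity, precision and AUC per
outer fold, aggregated as mean +/- SD, plus recall stratified by whether
positive segments carry an arousal. Subject level: the estimated AHI is
the count of positive-classified segments divided by recording hours;
subjects with estimated AHI >= 15 screen positive for moderate-to-severe
OSA, scored against the reference AHI with a 2x2 confusion matrix, per-
subject sensitivity/specificity and the Pearson correlation between
estimated and reference AHI (optionally within comorbidity strata).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .modeling import FoldResult

SEVERITY_LABELS = ("none", "mild", "moderate", "severe")


@dataclass
class SegmentMetrics:
    """Per-fold segment-level metrics with mean +/- SD aggregation."""

    per_fold: pd.DataFrame  # columns: fold, accuracy, sensitivity, specificity, precision, auc

    @property
    def mean(self) -> pd.Series:
        return self.per_fold.drop(columns="fold").mean()

    @property
    def sd(self) -> pd.Series:
        return self.per_fold.drop(columns="fold").std(ddof=1)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "sd": self.sd})


@dataclass
class ScreeningReport:
    """Per-subject AHI estimates and moderate-to-severe screening outcome."""

    table: pd.DataFrame  # subject_id, estimated_ahi, reference_ahi, comorbidity, decision, truth
    threshold: float
    sensitivity_pct: float
    specificity_pct: float
    confusion: np.ndarray  # rows: true {neg,pos}; cols: predicted {neg,pos}
    pearson_r: float
    strata: dict[str, "ScreeningReport"] = field(default_factory=dict)


def _binary_metrics(labels: np.ndarray, preds: np.ndarray) -> dict[str, float]:
    tp = int(np.sum((labels == 1) & (preds == 1)))
    tn = int(np.sum((labels == 0) & (preds == 0)))
    fp = int(np.sum((labels == 0) & (preds == 1)))
    fn = int(np.sum((labels == 1) & (preds == 0)))
    n = tp + tn + fp + fn
    return {
        "accuracy": 100.0 * (tp + tn) / n if n else float("nan"),
        "sensitivity": 100.0 * tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": 100.0 * tn / (tn + fp) if tn + fp else float("nan"),
        "precision": 100.0 * tp / (tp + fp) if tp + fp else float("nan"),
    }


def segment_metrics(fold_results: Sequence[FoldResult]) -> SegmentMetrics:
    """Classification metrics per outer fold from held-out predictions."""
    rows = []
    for fr in fold_results:
        y = fr.predictions["label"].to_numpy()
        pred = fr.predictions["pred"].to_numpy()
        score = fr.predictions["score"].to_numpy()
        m = _binary_metrics(y, pred)
        m["auc"] = roc_auc_score(y, score) if len(np.unique(y)) == 2 else float("nan")
        rows.append({"fold": fr.fold, **m})
    return SegmentMetrics(pd.DataFrame(rows))


def arousal_stratified_detection(
    labels: np.ndarray, preds: np.ndarray, arousal: np.ndarray
) -> dict[str, float]:
    """Recall (%) among positive segments, split by arousal presence."""
    labels = np.asarray(labels)
    preds = np.asarray(preds)
    arousal = np.asarray(arousal, dtype=bool)
    out = {}
    for name, mask in (
        ("with_arousal", (labels == 1) & arousal),
        ("no_arousal", (labels == 1) & ~arousal),
    ):
        out[name] = (
            float(100.0 * preds[mask].mean()) if mask.any() else float("nan")
        )
    return out


def estimate_ahi(segment_predictions: np.ndarray, recording_time_h: float) -> float:
    """Estimated AHI = positive-classified segments / recording hours."""
    if recording_time_h <= 0:
        raise ValueError("recording_time_h must be positive")
    return float(np.sum(np.asarray(segment_predictions) == 1) / recording_time_h)


def severity_class(ahi: float) -> str:
    """AHI severity bin: <5 none, 5-15 mild, 15-30 moderate, >30 severe.

    Boundaries follow the clinical convention: 15 and 30 both fall in the
    moderate bin; anything strictly above 30 is severe.
    """
    if ahi < 0:
        raise ValueError("AHI cannot be negative")
    if ahi < 5:
        return "none"
    if ahi < 15:
        return "mild"
    if ahi <= 30:
        return "moderate"
    return "severe"


def screen_subjects(
    estimated: Mapping[str, float],
    reference: Mapping[str, float],
    threshold: float = 15.0,
    comorbidity: Mapping[str, bool] | None = None,
) -> ScreeningReport:
    """Moderate-to-severe screening: positive iff estimated AHI >= threshold.

    Sensitivity/specificity are computed against reference AHI >= threshold;
    ``pearson_r`` correlates raw estimated with reference AHI. When
    comorbidity flags are provided, the report carries a recomputed
    sub-report per stratum (strata with a single class of reference are
    omitted with a warning).
    """
    subjects = sorted(estimated)
    if sorted(reference) != subjects:
        raise ValueError("estimated and reference AHIs must cover the same subjects")
    est = np.array([estimated[s] for s in subjects], dtype=float)
    ref = np.array([reference[s] for s in subjects], dtype=float)
    decision = est >= threshold
    truth = ref >= threshold
    tp = int(np.sum(decision & truth))
    tn = int(np.sum(~decision & ~truth))
    fp = int(np.sum(decision & ~truth))
    fn = int(np.sum(~decision & truth))
    confusion = np.array([[tn, fp], [fn, tp]])
    r = float(stats.pearsonr(est, ref)[0]) if len(subjects) > 2 and est.std() > 0 and ref.std() > 0 else float("nan")
    table = pd.DataFrame(
        {
            "subject_id": subjects,
            "estimated_ahi": est,
            "reference_ahi": ref,
            "decision": decision,
            "truth": truth,
            "comorbidity": [
                bool(comorbidity[s]) if comorbidity else False for s in subjects
            ],
        }
    )
    report = ScreeningReport(
        table=table,
        threshold=threshold,
        sensitivity_pct=100.0 * tp / (tp + fn) if tp + fn else float("nan"),
        specificity_pct=100.0 * tn / (tn + fp) if tn + fp else float("nan"),
        confusion=confusion,
        pearson_r=r,
    )
    if comorbidity:
        for name, flag in (("with_comorbidities", True), ("without_comorbidities", False)):
            ids = [s for s in subjects if bool(comorbidity[s]) == flag]
            if len(ids) < 3:
                continue
            sub_ref = {s: reference[s] for s in ids}
            if len({sub_ref[s] >= threshold for s in ids}) < 2:
                import warnings

                warnings.warn(f"stratum {name} has a single reference class; omitted")
                continue
            report.strata[name] = screen_subjects(
                {s: estimated[s] for s in ids}, sub_ref, threshold
            )
    return report


def feature_importance(fold_results: Sequence[FoldResult]) -> pd.Series:
    """Mean random-forest importance per feature across outer folds.

    Each fold's forest importances (normalized, nonnegative) are averaged;
    a feature missing from a fold's selection contributes zero that fold.
    Returned sorted descending.
    """
    if not fold_results:
        raise ValueError("need at least one fold result")
    all_names = sorted({n for fr in fold_results for n in fr.selected_features})
    mat = np.zeros((len(fold_results), len(all_names)))
    for i, fr in enumerate(fold_results):
        imp = dict(zip(fr.selected_features, fr.forest.feature_importances_))
        for j, name in enumerate(all_names):
            mat[i, j] = imp.get(name, 0.0)
    return pd.Series(mat.mean(axis=0), index=all_names).sort_values(ascending=False)


def compare_feature_sets(
    metrics_by_set: Mapping[str, SegmentMetrics], metric: str = "auc"
) -> pd.DataFrame:
    """Repeated-measures comparison of per-fold metric vectors across sets.

    One-way repeated-measures ANOVA across feature sets, then Bonferroni-
    corrected paired t-tests of every set against the first (reference) set.
    A reporting utility; returns a table of raw and corrected p-values.
    """
    names = list(metrics_by_set)
    vectors = {n: metrics_by_set[n].per_fold[metric].to_numpy() for n in names}
    k = len(names)
    if k < 2:
        raise ValueError("need at least two feature sets to compare")
    data = np.vstack([vectors[n] for n in names])  # sets x folds
    n_folds = data.shape[1]
    grand = data.mean()
    ss_sets = n_folds * ((data.mean(axis=1) - grand) ** 2).sum()
    ss_folds = k * ((data.mean(axis=0) - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_sets - ss_folds
    df_sets, df_err = k - 1, (k - 1) * (n_folds - 1)
    f_stat = (ss_sets / df_sets) / (ss_err / df_err) if ss_err > 0 else float("inf")
    p_anova = float(stats.f.sf(f_stat, df_sets, df_err))
    rows = [{"comparison": "rm-ANOVA", "stat": f_stat, "p_raw": p_anova, "p_corrected": p_anova}]
    ref = names[0]
    n_tests = k - 1
    for name in names[1:]:
        t, p = stats.ttest_rel(vectors[name], vectors[ref])
        rows.append(
            {
                "comparison": f"{name} vs {ref}",
                "stat": float(t),
                "p_raw": float(p),
                "p_corrected": min(1.0, float(p) * n_tests),
            }
        )
    return pd.DataFrame(rows)
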