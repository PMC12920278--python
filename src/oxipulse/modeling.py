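"""Segment classifiers under subject-grouped nested cross-validation.

Outer loop: subjects split into k folds; all of a subject's segments stay
on one side of every split, so no within-subject leakage. Within each
training fold: recursive feature elimination with inner 5-fold CV (random
forest importance ranking, AUC scoring, one-standard-error parsimony rule),
random undersampling of the majority class, then an exhaustive search of
the small SVM grid (C in {0.1, 1} x kernel in {RBF, polynomial}) with
another inner 5-fold CV. Features are z-scored with training-fit scalers
inside the SVM pipeline. Everything is seeded and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE, RFECV
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .config import ModelingParams, derive_seed
from .features import FEATURE_FAMILIES, FEATURE_NAMES

FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "SpO2": FEATURE_FAMILIES["SpO2"],
    "PWA+SpO2": FEATURE_FAMILIES["PWA"] + FEATURE_FAMILIES["SpO2"],
    "PPI+SpO2": FEATURE_FAMILIES["PPI"] + FEATURE_FAMILIES["SpO2"],
    "PWA+PPI": FEATURE_FAMILIES["PWA"] + FEATURE_FAMILIES["PPI"],
    "PWA+PPI+SpO2": FEATURE_FAMILIES["PWA"] + FEATURE_FAMILIES["PPI"] + FEATURE_FAMILIES["SpO2"],
}


@dataclass
class FoldResult:
    """Everything produced by one outer fold for one feature set."""

    fold: int
    feature_set: str
    selected_features: list[str]
    hyperparameters: dict
    test_subjects: list[str]
    predictions: pd.DataFrame  # subject_id, start_s, label, arousal, score, pred
    forest: RandomForestClassifier = field(repr=False, default=None)  # type: ignore

    def subject_positive_counts(self) -> pd.Series:
        return self.predictions.groupby("subject_id")["pred"].sum()


def make_grouped_folds(subject_ids: np.ndarray, k: int = 5, seed: int = 0) -> dict[str, int]:
    """Partition unique subjects into k folds of near-equal size.

    Returns a subject -> fold mapping; segments inherit their subject's
    fold, so held-out subjects are disjoint from training subjects.
    """
    subjects = np.unique(np.asarray(subject_ids))
    if k > subjects.size:
        raise ValueError(f"k={k} exceeds the {subjects.size} available subjects")
    rng = np.random.default_rng(seed)
    order = rng.permutation(subjects)
    return {str(s): i % k for i, s in enumerate(order)}


def undersample(y: np.ndarray, seed: int = 0) -> np.ndarray:
    """Indices of a class-balanced subsample (majority class thinned).

    The minority class is kept whole; the majority class is sampled without
    replacement down to the minority count. Returned indices are sorted so
    row order stays stable.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("both classes must be present to undersample")
    n_min = counts.min()
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for cls, cnt in zip(classes, counts):
        idx = np.flatnonzero(y == cls)
        if cnt > n_min:
            idx = rng.choice(idx, size=n_min, replace=False)
        keep.append(idx)
    return np.sort(np.concatenate(keep))


def select_features_rfecv(
    X: pd.DataFrame,
    y: np.ndarray,
    seed: int = 0,
    params: ModelingParams | None = None,
) -> tuple[list[str], RandomForestClassifier]:
    """Recursive feature elimination with inner CV and a 1-SE rule.

    A random forest ranks features; one is dropped per step; the inner
    5-fold AUC is scored for every subset size, and the smallest subset
    whose mean score is within one standard error of the best is kept
    (parsimony over raw maximum). Constant columns are dropped up front.
    Also returns the forest refit on the selected columns for importance
    reporting.
    """
    p = params or ModelingParams()
    variable = X.columns[X.nunique() > 1].tolist()
    if len(variable) < len(X.columns):
        import warnings

        warnings.warn(f"dropping constant columns: {set(X.columns) - set(variable)}")
    X = X[variable]
    if len(variable) == 1:
        forest = RandomForestClassifier(
            n_estimators=p.rf_n_estimators, random_state=seed, n_jobs=1
        ).fit(X.values, y)
        return variable, forest

    rf = RandomForestClassifier(n_estimators=p.rf_n_estimators, random_state=seed, n_jobs=1)
    cv = StratifiedKFold(n_splits=p.rfecv_inner_folds, shuffle=True, random_state=seed)
    rfecv = RFECV(rf, step=1, cv=cv, scoring="roc_auc", min_features_to_select=1, n_jobs=1)
    rfecv.fit(X.values, y)
    mean = rfecv.cv_results_["mean_test_score"]
    std = rfecv.cv_results_["std_test_score"]
    sizes = np.arange(1, len(mean) + 1)
    best = int(np.argmax(mean))
    threshold = mean[best] - std[best] / np.sqrt(p.rfecv_inner_folds)
    n_keep = int(sizes[np.flatnonzero(mean >= threshold)[0]])
    rfe = RFE(
        RandomForestClassifier(n_estimators=p.rf_n_estimators, random_state=seed, n_jobs=1),
        n_features_to_select=n_keep,
        step=1,
    ).fit(X.values, y)
    selected = [c for c, keep in zip(variable, rfe.support_) if keep]
    forest = RandomForestClassifier(
        n_estimators=p.rf_n_estimators, random_state=seed, n_jobs=1
    ).fit(X[selected].values, y)
    return selected, forest


def tune_and_train(
    X: pd.DataFrame,
    y: np.ndarray,
    seed: int = 0,
    params: ModelingParams | None = None,
) -> tuple[Pipeline, dict]:
    """Exhaustive search of the 4-cell SVM grid with inner 5-fold CV.

    The grid {C: 0.1, 1} x {RBF, polynomial} is small enough that the
    randomized search degenerates to full enumeration. The winning model is
    refit on all provided rows; it exposes a continuous decision score via
    ``decision_function`` and binary predictions at score 0.
    """
    p = params or ModelingParams()
    pipe = Pipeline(
        [
            ("scale", StandardScaler()),
            ("svm", SVC(degree=3, gamma="scale", random_state=seed)),
        ]
    )
    grid = {"svm__C": list(p.svm_c_grid), "svm__kernel": list(p.svm_kernels)}
    cv = StratifiedKFold(n_splits=p.svm_inner_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(pipe, grid, scoring="roc_auc", cv=cv, refit=True, n_jobs=1)
    search.fit(X.values, y)
    best = {"C": search.best_params_["svm__C"], "kernel": search.best_params_["svm__kernel"]}
    return search.best_estimator_, best


def run_nested_cv(
    table: pd.DataFrame,
    feature_sets: list[str] | None = None,
    k: int = 5,
    seed: int = 0,
    params: ModelingParams | None = None,
) -> dict[str, list[FoldResult]]:
    """Nested subject-grouped CV over the requested feature combinations.

    ``table`` is the normalized feature table (one row per quality-ok
    segment). Returns per-feature-set lists of :class:`FoldResult` whose
    pooled predictions cover every subject exactly once.
    """
    p = params or ModelingParams()
    sets = feature_sets or list(FEATURE_SETS)
    unknown = set(sets) - set(FEATURE_SETS)
    if unknown:
        raise ValueError(f"unknown feature sets: {unknown}")
    folds = make_grouped_folds(table["subject_id"].to_numpy(), k=k, seed=seed)
    fold_of_row = table["subject_id"].map(folds).to_numpy()
    results: dict[str, list[FoldResult]] = {name: [] for name in sets}
    for name in sets:
        columns = list(FEATURE_SETS[name])
        for fold in range(k):
            train = table[fold_of_row != fold]
            test = table[fold_of_row == fold]
            if train["label"].nunique() < 2 or len(test) == 0:
                raise RuntimeError(f"fold {fold}: degenerate train/test split")
            fold_seed = derive_seed(seed, f"{name}:fold{fold}")
            selected, forest = select_features_rfecv(
                train[columns], train["label"].to_numpy(), seed=fold_seed, params=p
            )
            keep = undersample(train["label"].to_numpy(), seed=fold_seed)
            bal = train.iloc[keep]
            clf, hyper = tune_and_train(
                bal[selected], bal["label"].to_numpy(), seed=fold_seed, params=p
            )
            scores = clf.decision_function(test[selected].values)
            preds = (scores > 0).astype(int)
            results[name].append(
                FoldResult(
                    fold=fold,
                    feature_set=name,
                    selected_features=selected,
                    hyperparameters=hyper,
                    test_subjects=sorted(test["subject_id"].unique()),
                    predictions=pd.DataFrame(
                        {
                            "subject_id": test["subject_id"].to_numpy(),
                            "start_s": test["start_s"].to_numpy(),
                            "label": test["label"].to_numpy(),
                            "arousal": test["arousal"].to_numpy(),
                            "score": scores,
                            "pred": preds,
                        }
                    ),
                    forest=forest,
                )
            )
    return results
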