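"""Model/Results facade over the screening pipeline.

``OsaScreeningModel`` is constructed from data (either a ready segment
feature table or a cohort of raw recordings) and ``fit()`` runs the nested
cross-validated classifier, returning an ``OsaScreeningResults`` object
that carries per-segment metrics, arousal-stratified detection, per-subject
AHI estimates, the screening report, feature importances and a printable
``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import FeatureParams, ModelingParams, PreprocessingParams, SegmentationParams
from .evaluation import (
    ScreeningReport,
    SegmentMetrics,
    arousal_stratified_detection,
    estimate_ahi,
    feature_importance,
    screen_subjects,
    segment_metrics,
)
from .features import extract_features, normalize_per_subject
from .modeling import FEATURE_SETS, FoldResult, run_nested_cv
from .preprocessing import preprocess_recording
from .segmentation import segment_recording
from .synth import RawRecording


class OsaScreeningModel:
    """Per-segment OSA classifier + per-subject AHI screening, fit by nested CV.

    Parameters
    ----------
    feature_table : DataFrame
        One row per quality-ok 60-s segment: metadata columns
        (subject_id, start_s, label, arousal, quality) plus the 37 features,
        already per-subject normalized.
    subject_info : mapping
        Per subject: ``recording_time_h``, ``reference_ahi``, ``comorbidity``.
    feature_sets : sequence of str
        Which of the five feature combinations to fit (default: all).
    """

    def __init__(
        self,
        feature_table: pd.DataFrame,
        subject_info: Mapping[str, dict],
        feature_sets: Sequence[str] | None = None,
        k_folds: int = 5,
        modeling_params: ModelingParams | None = None,
        ahi_threshold: float = 15.0,
    ) -> None:
        missing = {"subject_id", "label"} - set(feature_table.columns)
        if missing:
            raise ValueError(f"feature table lacks columns {missing}")
        self.feature_table = feature_table.reset_index(drop=True)
        self.subject_info = dict(subject_info)
        self.feature_sets = list(feature_sets or FEATURE_SETS)
        self.k_folds = k_folds
        self.modeling_params = modeling_params or ModelingParams()
        self.ahi_threshold = ahi_threshold

    @classmethod
    def from_cohort(
        cls,
        recordings: Sequence[RawRecording],
        feature_sets: Sequence[str] | None = None,
        k_folds: int = 5,
        preprocessing_params: PreprocessingParams | None = None,
        segmentation_params: SegmentationParams | None = None,
        feature_params: FeatureParams | None = None,
        modeling_params: ModelingParams | None = None,
        ahi_threshold: float = 15.0,
    ) -> "OsaScreeningModel":
        """Build the model from raw recordings: preprocess each subject,
        segment, extract the 37 features and normalize per subject."""
        tables = []
        info = {}
        for rec in recordings:
            pre = preprocess_recording(rec, preprocessing_params)
            segments = segment_recording(rec, segmentation_params)
            tables.append(extract_features(segments, pre, feature_params))
            info[rec.subject_id] = {
                "recording_time_h": rec.recording_time_h,
                "reference_ahi": rec.reference_ahi,
                "comorbidity": rec.comorbidity,
            }
        table = pd.concat(tables, ignore_index=True)
        table = normalize_per_subject(table)
        return cls(
            table,
            info,
            feature_sets=feature_sets,
            k_folds=k_folds,
            modeling_params=modeling_params,
            ahi_threshold=ahi_threshold,
        )

    def fit(self, seed: int = 0) -> "OsaScreeningResults":
        """Run nested subject-grouped CV for every requested feature set."""
        folds = run_nested_cv(
            self.feature_table,
            feature_sets=self.feature_sets,
            k=self.k_folds,
            seed=seed,
            params=self.modeling_params,
        )
        return OsaScreeningResults(model=self, fold_results=folds, seed=seed)


@dataclass
class OsaScreeningResults:
    """Fitted-pipeline results across feature sets."""

    model: OsaScreeningModel
    fold_results: dict[str, list[FoldResult]]
    seed: int
    _cache: dict = field(default_factory=dict, repr=False)

    def pooled_predictions(self, feature_set: str) -> pd.DataFrame:
        """Held-out predictions pooled across outer folds (every subject
        appears in exactly one test fold)."""
        return pd.concat(
            [fr.predictions for fr in self.fold_results[feature_set]],
            ignore_index=True,
        )

    def segment_metrics(self, feature_set: str) -> SegmentMetrics:
        key = ("seg", feature_set)
        if key not in self._cache:
            self._cache[key] = segment_metrics(self.fold_results[feature_set])
        return self._cache[key]

    def arousal_detection(self, feature_set: str) -> dict[str, float]:
        pooled = self.pooled_predictions(feature_set)
        return arousal_stratified_detection(
            pooled["label"].to_numpy(),
            pooled["pred"].to_numpy(),
            pooled["arousal"].to_numpy(),
        )

    def estimated_ahi(self, feature_set: str) -> dict[str, float]:
        pooled = self.pooled_predictions(feature_set)
        out = {}
        for subject, grp in pooled.groupby("subject_id"):
            hours = self.model.subject_info[subject]["recording_time_h"]
            out[str(subject)] = estimate_ahi(grp["pred"].to_numpy(), hours)
        return out

    def screening(self, feature_set: str) -> ScreeningReport:
        key = ("screen", feature_set)
        if key not in self._cache:
            est = self.estimated_ahi(feature_set)
            ref = {s: self.model.subject_info[s]["reference_ahi"] for s in est}
            com = {s: self.model.subject_info[s]["comorbidity"] for s in est}
            self._cache[key] = screen_subjects(
                est, ref, threshold=self.model.ahi_threshold, comorbidity=com
            )
        return self._cache[key]

    def feature_importance(self, feature_set: str) -> pd.Series:
        return feature_importance(self.fold_results[feature_set])

    def selected_feature_counts(self) -> pd.DataFrame:
        rows = [
            {
                "feature_set": name,
                "mean_n_features": float(
                    np.mean([len(fr.selected_features) for fr in frs])
                ),
                "sd_n_features": float(
                    np.std([len(fr.selected_features) for fr in frs], ddof=1)
                ),
            }
            for name, frs in self.fold_results.items()
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "OSA screening results (nested %d-fold CV, seed %d)"
            % (self.model.k_folds, self.seed),
            "=" * 64,
        ]
        for name in self.fold_results:
            sm = self.segment_metrics(name)
            mean, sd = sm.mean, sm.sd
            scr = self.screening(name)
            det = self.arousal_detection(name)
            lines += [
                f"[{name}]",
                "  per-segment: acc %.1f±%.1f%%  sen %.1f±%.1f%%  spec %.1f±%.1f%%  "
                "prec %.1f±%.1f%%  AUC %.2f±%.2f"
                % (
                    mean["accuracy"], sd["accuracy"], mean["sensitivity"], sd["sensitivity"],
                    mean["specificity"], sd["specificity"], mean["precision"], sd["precision"],
                    mean["auc"], sd["auc"],
                ),
                "  positive-segment recall: with arousal %.1f%%, without %.1f%%"
                % (det["with_arousal"], det["no_arousal"]),
                "  screening (AHI >= %g): sens %.1f%%  spec %.1f%%  Pearson r %.2f"
                % (scr.threshold, scr.sensitivity_pct, scr.specificity_pct, scr.pearson_r),
                "  confusion [[TN FP][FN TP]]: %s" % scr.confusion.tolist(),
            ]
        return "\n".join(lines)
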