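"""End-to-end reproducible run: synth -> preprocess -> segment -> features
-> nested CV -> evaluation, driven by one RunConfig and one master seed.

One global seed fans out into stage-specific seeds via stable hashing of
stage names (see :func:`oxipulse.config.derive_seed`), so any stage can be
rerun in isolation with the stream it saw inside the full pipeline.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig, derive_seed
from .model import OsaScreeningModel, OsaScreeningResults
from .synth import generate_cohort

log = logging.getLogger("oxipulse")


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def run_pipeline(config: RunConfig) -> OsaScreeningResults:
    """Execute the full pipeline and write a report bundle to
    ``config.out_dir`` (resolved config, metrics JSON, confusion matrices,
    AHI scatter data, feature importances)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    synth_seed = derive_seed(config.seed, "synth")
    log.info("generating cohort: %d subjects, %.1f h each", config.n_subjects,
             config.synth.duration_h)
    cohort = generate_cohort(
        config.n_subjects, config.severity_mix, seed=synth_seed, base_config=config.synth
    )
    model = OsaScreeningModel.from_cohort(
        cohort,
        feature_sets=list(config.feature_sets),
        k_folds=config.modeling.k_folds,
        preprocessing_params=config.preprocessing,
        segmentation_params=config.segmentation,
        feature_params=config.features,
        modeling_params=config.modeling,
        ahi_threshold=config.evaluation.ahi_threshold,
    )
    n_total = sum(
        int(np.floor(r.recording_time_h * 3600.0 / config.segmentation.seg_len_s))
        for r in cohort
    )
    n_ok = len(model.feature_table)
    log.info("segments: %d total, %d quality-ok (%d excluded)", n_total, n_ok,
             n_total - n_ok)
    results = model.fit(seed=derive_seed(config.seed, "modeling"))

    report = {}
    for name in config.feature_sets:
        sm = results.segment_metrics(name)
        scr = results.screening(name)
        report[name] = {
            "segment_metrics_mean": {k: float(v) for k, v in sm.mean.items()},
            "segment_metrics_sd": {k: float(v) for k, v in sm.sd.items()},
            "arousal_detection": results.arousal_detection(name),
            "screening_sensitivity_pct": scr.sensitivity_pct,
            "screening_specificity_pct": scr.specificity_pct,
            "pearson_r": scr.pearson_r,
            "confusion": scr.confusion.tolist(),
        }
        scr.table.to_csv(out / f"ahi_{name.replace('+', '_')}.csv", index=False)
        results.feature_importance(name).rename("importance").to_csv(
            out / f"importance_{name.replace('+', '_')}.csv"
        )
    (out / "metrics.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=_jsonable)
    )
    (out / "summary.txt").write_text(results.summary() + "\n")
    log.info("report bundle written to %s", out)
    return results
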