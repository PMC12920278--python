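"""Configuration objects shared across pipeline stages.

Every stage of the pipeline is driven by a small frozen dataclass; a
:class:`RunConfig` bundles them all and can be round-tripped through YAML so
that a run is fully reproducible from its config file plus one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional
import hashlib

import yaml


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic overnight-recording generator.

    The defaults encode the study conditions the generator emulates: a
    finger-PPG AC waveform with beat-to-beat amplitude (PWA) and interval
    (PPI) modulation, arousal-locked PWA drops and PPI shortening, and SpO2
    desaturations trailing apneas and the desaturating subset of hypopneas.

    Parameters
    ----------
    duration_h : float
        Recording length in hours.
    ppg_fs, spo2_fs : float
        Sampling rates in Hz of the PPG and SpO2 channels.
    base_pulse_rate : float
        Resting pulse rate in beats per minute.
    base_pwa : float
        Baseline pulse wave amplitude, arbitrary units.
    event_rate_per_h : float
        Scheduled respiratory events per hour; this IS the ground-truth AHI.
    frac_apnea : float
        Fraction of scheduled events that are obstructive apneas (the rest
        are hypopneas).
    frac_hypopnea_arousal_only : float
        Fraction of hypopneas that terminate in an arousal but cause no
        desaturation - the phenotype SpO2-only screening misses.
    pwa_drop_frac : float
        Fractional PWA reduction at the peak of the arousal response
        (0.4 means PWA transiently drops to 60% of baseline).
    ppi_shortening_frac : float
        Fractional PPI reduction at the peak of the arousal response.
    desat_depth_pct : float
        SpO2 drop in percentage points at the desaturation nadir after an
        apnea; desaturating hypopneas get 60% of this depth.
    desat_lag_s : float
        Delay from event end to desaturation nadir, seconds.
    noise_sd : float
        Gaussian measurement-noise SD added to the PPG waveform, in the same
        arbitrary units as ``base_pwa``.
    seed : int
        Seed for the generator's private random stream.
    """

    duration_h: float = 2.0
    ppg_fs: float = 128.0
    spo2_fs: float = 16.0
    base_pulse_rate: float = 70.0
    base_pwa: float = 1.0
    event_rate_per_h: float = 20.0
    frac_apnea: float = 0.15
    frac_hypopnea_arousal_only: float = 0.30
    pwa_drop_frac: float = 0.4
    ppi_shortening_frac: float = 0.15
    desat_depth_pct: float = 4.0
    desat_lag_s: float = 20.0
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "duration_h": self.duration_h,
            "ppg_fs": self.ppg_fs,
            "spo2_fs": self.spo2_fs,
            "base_pulse_rate": self.base_pulse_rate,
            "base_pwa": self.base_pwa,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        if self.event_rate_per_h < 0:
            raise ValueError("event_rate_per_h must be non-negative")
        fractions = {
            "frac_apnea": self.frac_apnea,
            "frac_hypopnea_arousal_only": self.frac_hypopnea_arousal_only,
            "pwa_drop_frac": self.pwa_drop_frac,
            "ppi_shortening_frac": self.ppi_shortening_frac,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.desat_depth_pct < 0 or self.desat_lag_s < 0 or self.noise_sd < 0:
            raise ValueError("desat_depth_pct, desat_lag_s and noise_sd must be >= 0")

    @property
    def n_scheduled_events(self) -> int:
        """Exact scheduled apnea+hypopnea count (not Poisson-drawn)."""
        return int(round(self.event_rate_per_h * self.duration_h))


@dataclass(frozen=True)
class EntropyParams:
    """Parameters for the template-matching entropy measures.

    ``m`` is the embedding dimension, ``r`` the tolerance as a fraction of
    the series SD, ``c`` the number of dispersion-entropy classes and
    ``delay`` the embedding delay in samples. ``fuzzy_exponent`` is the
    exponent of the fuzzy membership function exp(-(d/r)^n).
    """

    m: int = 2
    r: float = 0.2
    c: int = 6
    delay: int = 1
    fuzzy_exponent: float = 2.0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if self.r <= 0:
            raise ValueError("tolerance r must be > 0")
        if self.c < 2:
            raise ValueError("dispersion classes c must be >= 2")
        if self.delay < 1:
            raise ValueError("delay must be >= 1")


@dataclass(frozen=True)
class BandDefinition:
    """Variability frequency bands (Hz): VLF 0.003-0.04, LF 0.04-0.15, HF 0.15-0.4."""

    vlf: tuple[float, float] = (0.003, 0.04)
    lf: tuple[float, float] = (0.04, 0.15)
    hf: tuple[float, float] = (0.15, 0.4)

    def __post_init__(self) -> None:
        edges = [*self.vlf, *self.lf, *self.hf]
        if any(b <= a for a, b in zip(edges[:-1], edges[1:])):
            # contiguity is not required, strictly increasing edges are
            if not (self.vlf[0] < self.vlf[1] <= self.lf[0] < self.lf[1] <= self.hf[0] < self.hf[1]):
                raise ValueError("bands must be increasing and non-overlapping")


@dataclass(frozen=True)
class PreprocessingParams:
    band_low_hz: float = 0.7
    band_high_hz: float = 20.0
    filter_order: int = 4
    target_ppg_fs: float = 128.0
    artifact_window_s: float = 60.0
    artifact_k: float = 1.5
    min_ppi_s: float = 0.33
    max_ppi_s: float = 2.0
    max_ppi_jump_frac: float = 0.30
    beat_fs_out: float = 4.0


@dataclass(frozen=True)
class SegmentationParams:
    seg_len_s: float = 60.0
    min_overlap_s: float = 10.0
    cumulative_overlap: bool = True


@dataclass(frozen=True)
class FeatureParams:
    entropy: EntropyParams = field(default_factory=EntropyParams)
    bands: BandDefinition = field(default_factory=BandDefinition)
    spo2_entropy_fs: float = 1.0
    normalize_ppi: bool = True  # per-subject min-max also on PPI features


@dataclass(frozen=True)
class ModelingParams:
    k_folds: int = 5
    svm_c_grid: tuple[float, ...] = (0.1, 1.0)
    svm_kernels: tuple[str, ...] = ("rbf", "poly")
    rf_n_estimators: int = 50
    rfecv_inner_folds: int = 5
    svm_inner_folds: int = 5


@dataclass(frozen=True)
class EvaluationParams:
    ahi_threshold: float = 15.0


@dataclass
class RunConfig:
    """Full end-to-end run configuration; YAML-serializable."""

    out_dir: str = "runs/demo"
    seed: int = 0
    n_subjects: int = 12
    severity_mix: tuple[float, float, float, float] = (0.122, 0.244, 0.356, 0.278)
    synth: SynthConfig = field(default_factory=SynthConfig)
    preprocessing: PreprocessingParams = field(default_factory=PreprocessingParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    features: FeatureParams = field(default_factory=FeatureParams)
    modeling: ModelingParams = field(default_factory=ModelingParams)
    evaluation: EvaluationParams = field(default_factory=EvaluationParams)
    feature_sets: tuple[str, ...] = ("PWA+PPI+SpO2",)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "synth" in kwargs and isinstance(kwargs["synth"], dict):
            kwargs["synth"] = SynthConfig(**kwargs["synth"])
        if "preprocessing" in kwargs and isinstance(kwargs["preprocessing"], dict):
            kwargs["preprocessing"] = PreprocessingParams(**kwargs["preprocessing"])
        if "segmentation" in kwargs and isinstance(kwargs["segmentation"], dict):
            kwargs["segmentation"] = SegmentationParams(**kwargs["segmentation"])
        if "features" in kwargs and isinstance(kwargs["features"], dict):
            fk = dict(kwargs["features"])
            if isinstance(fk.get("entropy"), dict):
                fk["entropy"] = EntropyParams(**fk["entropy"])
            if isinstance(fk.get("bands"), dict):
                fk["bands"] = BandDefinition(**{k: tuple(v) for k, v in fk["bands"].items()})
            kwargs["features"] = FeatureParams(**fk)
        if "modeling" in kwargs and isinstance(kwargs["modeling"], dict):
            mk = dict(kwargs["modeling"])
            for key in ("svm_c_grid", "svm_kernels"):
                if key in mk:
                    mk[key] = tuple(mk[key])
            kwargs["modeling"] = ModelingParams(**mk)
        if "evaluation" in kwargs and isinstance(kwargs["evaluation"], dict):
            kwargs["evaluation"] = EvaluationParams(**kwargs["evaluation"])
        for key in ("severity_mix", "feature_sets"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def derive_seed(master_seed: int, stage: str) -> int:
    """Derive a stable stage-specific seed from one master seed.

    Uses a hash of the stage name so stages can be rerun in isolation with
    the same stream they saw inside the full pipeline. Result is < 2**31.
    """
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)
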