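"""The 37-feature catalogue per 60-s segment, plus per-subject scaling.

Families (names follow the field's HRV/PRV conventions, computed from PPG
pulse-to-pulse intervals rather than ECG RR):

* PPI time-domain (13): Mean_NN, Max_PR, Min_PR, SDNN, CVNNI, SDSD, CVSD,
  NN50, pNN50, NN20, pNN20, RMSSD, Range_NN
* PPI nonlinear (3): Samp_NN, Fuzz_NN, Disp_NN
* PPI frequency-domain (7): VLF, LF, HF, LFnu, HFnu, LF_HF, SpecEnt
* PWA (7): Max_PWA, Min_PWA, Std_PWA, CV_PWA, VLF_PWA, LF_PWA, HF_PWA
* SpO2 (7): Min_Sp, Mean_Sp, Std_Sp, Var_Sp, Samp_Sp, Fuzz_Sp, Disp_Sp

Spectral powers come from a Welch PSD of the 4 Hz beat series (120-sample
sub-windows, 50% overlap, linear detrend) integrated over VLF/LF/HF.
PWA- and PPI-family features are min-max scaled within each subject so
amplitude changes compare across subjects without fixed thresholds; SpO2
features stay on their physical scale.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .config import BandDefinition, EntropyParams, FeatureParams
from .entropy import dispersion_entropy, fuzzy_entropy, sample_entropy
from .preprocessing import BeatSeries, UniformSeries
from .segmentation import SegmentRecord

PPI_TIME_FEATURES = (
    "Mean_NN", "Max_PR", "Min_PR", "SDNN", "CVNNI", "SDSD", "CVSD",
    "NN50", "pNN50", "NN20", "pNN20", "RMSSD", "Range_NN",
)
PPI_NONLINEAR_FEATURES = ("Samp_NN", "Fuzz_NN", "Disp_NN")
PPI_FREQ_FEATURES = ("VLF", "LF", "HF", "LFnu", "HFnu", "LF_HF", "SpecEnt")
PWA_FEATURES = ("Max_PWA", "Min_PWA", "Std_PWA", "CV_PWA", "VLF_PWA", "LF_PWA", "HF_PWA")
SPO2_FEATURES = ("Min_Sp", "Mean_Sp", "Std_Sp", "Var_Sp", "Samp_Sp", "Fuzz_Sp", "Disp_Sp")

PPI_FAMILY = PPI_TIME_FEATURES + PPI_NONLINEAR_FEATURES + PPI_FREQ_FEATURES
FEATURE_NAMES = PPI_FAMILY + PWA_FEATURES + SPO2_FEATURES
assert len(FEATURE_NAMES) == 37

FEATURE_FAMILIES = {
    "PPI": PPI_FAMILY,
    "PWA": PWA_FEATURES,
    "SpO2": SPO2_FEATURES,
}

META_COLUMNS = ("subject_id", "start_s", "label", "arousal", "quality")


def ppi_time_features(nn: np.ndarray) -> dict[str, float]:
    """13 time-domain statistics of artifact-free NN intervals (seconds)."""
    nn = np.asarray(nn, dtype=float)
    if nn.size < 5:
        raise ValueError("need at least 5 NN intervals")
    diff = np.diff(nn)
    nn50 = int(np.count_nonzero(np.abs(diff) > 0.050))
    nn20 = int(np.count_nonzero(np.abs(diff) > 0.020))
    return {
        "Mean_NN": float(nn.mean()),
        "Max_PR": float(60.0 / nn.min()),
        "Min_PR": float(60.0 / nn.max()),
        "SDNN": float(nn.std(ddof=1)),
        "CVNNI": float(nn.std(ddof=1) / nn.mean()),
        "SDSD": float(diff.std(ddof=1)) if diff.size > 1 else 0.0,
        "CVSD": float(np.sqrt(np.mean(diff**2)) / nn.mean()),
        "NN50": float(nn50),
        "pNN50": float(100.0 * nn50 / diff.size),
        "NN20": float(nn20),
        "pNN20": float(100.0 * nn20 / diff.size),
        "RMSSD": float(np.sqrt(np.mean(diff**2))),
        "Range_NN": float(nn.max() - nn.min()),
    }


def welch_psd(
    u: UniformSeries, nperseg: int = 120, overlap_frac: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD with linear detrend; sub-windows clipped to series length."""
    n = u.values.size
    nper = min(nperseg, n)
    f, p = signal.welch(
        u.values,
        fs=u.fs,
        nperseg=nper,
        noverlap=int(nper * overlap_frac),
        detrend="linear",
    )
    return f, p


def band_powers(
    u: UniformSeries, bands: BandDefinition | None = None
) -> dict[str, float]:
    """VLF/LF/HF band powers (trapezoidal integration of the Welch PSD),
    normalized LF/HF and their ratio.

    On a 60-s window the VLF band edge (0.003 Hz) lies below the spectral
    resolution; the nominal band is integrated regardless and the result is
    resolution-limited by construction.
    """
    b = bands or BandDefinition()
    f, p = welch_psd(u)

    def integrate(lo: float, hi: float) -> float:
        # integrate on a fine grid through the interpolated PSD so bands
        # narrower than the spectral resolution (VLF on a 60-s window) stay
        # defined; they remain resolution-limited, not exact
        if hi <= f[0] or lo >= f[-1]:
            return 0.0
        grid = np.linspace(max(lo, f[0]), min(hi, f[-1]), 64)
        return float(np.trapezoid(np.interp(grid, f, p), grid))

    vlf = integrate(*b.vlf)
    lf = integrate(*b.lf)
    hf = integrate(*b.hf)
    tot = lf + hf
    if tot > 0:
        lfnu, hfnu, ratio = lf / tot, hf / tot, (lf / hf if hf > 0 else float("inf"))
    else:
        lfnu = hfnu = ratio = float("nan")
    return {"VLF": vlf, "LF": lf, "HF": hf, "LFnu": lfnu, "HFnu": hfnu, "LF_HF": ratio}


def spectral_entropy(u: UniformSeries, f_max: float = 2.0) -> float:
    """Normalized Shannon entropy of the PSD over 0..f_max (in [0, 1])."""
    f, p = welch_psd(u)
    mask = (f >= 0) & (f <= f_max)
    p = p[mask]
    total = p.sum()
    if total <= 0 or p.size < 2:
        return float("nan")
    q = p / total
    q = q[q > 0]
    return float(-(q * np.log(q)).sum() / np.log(p.size))


def pwa_features(
    pwa_beats: np.ndarray,
    pwa_uniform: UniformSeries,
    bands: BandDefinition | None = None,
) -> dict[str, float]:
    """Amplitude statistics from beat-wise PWA; band powers from 4 Hz PWA."""
    pwa = np.asarray(pwa_beats, dtype=float)
    if pwa.size < 2:
        raise ValueError("need at least 2 valid PWA beats")
    bp = band_powers(pwa_uniform, bands)
    return {
        "Max_PWA": float(pwa.max()),
        "Min_PWA": float(pwa.min()),
        "Std_PWA": float(pwa.std(ddof=1)),
        "CV_PWA": float(pwa.std(ddof=1) / pwa.mean()),
        "VLF_PWA": bp["VLF"],
        "LF_PWA": bp["LF"],
        "HF_PWA": bp["HF"],
    }


def _decimate_mean(x: np.ndarray, factor: int) -> np.ndarray:
    n = (x.size // factor) * factor
    return x[:n].reshape(-1, factor).mean(axis=1)


def spo2_features(
    spo2: UniformSeries,
    entropy_params: EntropyParams | None = None,
    entropy_fs: float = 1.0,
) -> dict[str, float]:
    """Saturation statistics plus entropies of the 1 Hz mean-decimated trace.

    Entropies at the native 16 Hz would mostly measure oversampling
    redundancy; the trace is block-averaged to ``entropy_fs`` first.
    """
    x = spo2.values
    if x.size < spo2.fs * 30:
        raise ValueError("need at least 30 s of SpO2 samples")
    factor = max(int(round(spo2.fs / entropy_fs)), 1)
    xe = _decimate_mean(x, factor)
    p = entropy_params or EntropyParams()
    return {
        "Min_Sp": float(x.min()),
        "Mean_Sp": float(x.mean()),
        "Std_Sp": float(x.std(ddof=1)),
        "Var_Sp": float(x.std(ddof=1) ** 2),
        "Samp_Sp": sample_entropy(xe, p),
        "Fuzz_Sp": fuzzy_entropy(xe, p),
        "Disp_Sp": dispersion_entropy(xe, p),
    }


def extract_segment_features(
    seg: SegmentRecord,
    beats: BeatSeries,
    ppi_4hz: UniformSeries,
    pwa_4hz: UniformSeries,
    spo2: UniformSeries,
    params: FeatureParams | None = None,
) -> dict[str, float] | None:
    """All 37 features for one segment, or None if quality is too low.

    Low quality: fewer than 5 valid NN intervals, more than half the beats
    invalid, or missing SpO2 coverage. The segment's ``quality`` field is
    updated in place.
    """
    p = params or FeatureParams()
    t0, t1 = seg.start, seg.stop
    in_win = (beats.peak_times >= t0) & (beats.peak_times < t1)
    valid_in_win = in_win & beats.valid_mask
    pair_ok = valid_in_win[:-1] & valid_in_win[1:] if beats.n_beats > 1 else np.empty(0, bool)
    nn = beats.ppi[pair_ok]
    nn = nn[(nn > 0)]
    n_beats_win = int(in_win.sum())
    if (
        nn.size < 5
        or n_beats_win == 0
        or valid_in_win.sum() < 0.5 * n_beats_win
    ):
        seg.quality = "low"
        return None
    spo2_seg = spo2.slice(t0, t1)
    if spo2_seg.values.size < 0.9 * seg.length * spo2.fs:
        seg.quality = "low"
        return None
    ppi_seg = ppi_4hz.slice(t0, t1)
    pwa_seg = pwa_4hz.slice(t0, t1)
    pwa_vals = beats.pwa[valid_in_win]

    feats: dict[str, float] = {}
    feats.update(ppi_time_features(nn))
    ep = p.entropy
    feats["Samp_NN"] = sample_entropy(ppi_seg.values, ep)
    feats["Fuzz_NN"] = fuzzy_entropy(ppi_seg.values, ep)
    feats["Disp_NN"] = dispersion_entropy(ppi_seg.values, ep)
    feats.update(band_powers(ppi_seg, p.bands))
    feats["SpecEnt"] = spectral_entropy(ppi_seg)
    feats.update(pwa_features(pwa_vals, pwa_seg, p.bands))
    feats.update(spo2_features(spo2_seg, ep, p.spo2_entropy_fs))
    if not all(np.isfinite(v) for v in feats.values()):
        seg.quality = "low"
        return None
    return feats


def extract_features(
    segments: Sequence[SegmentRecord],
    preprocessed: dict,
    params: FeatureParams | None = None,
) -> pd.DataFrame:
    """Feature table for one subject: one row per quality-ok segment,
    37 feature columns plus segment metadata."""
    rows = []
    for seg in segments:
        feats = extract_segment_features(
            seg,
            preprocessed["beats"],
            preprocessed["ppi_4hz"],
            preprocessed["pwa_4hz"],
            preprocessed["spo2"],
            params,
        )
        if feats is None:
            continue
        rows.append(
            {
                "subject_id": seg.subject_id,
                "start_s": seg.start,
                "label": seg.label,
                "arousal": seg.arousal,
                "quality": seg.quality,
                **feats,
            }
        )
    return pd.DataFrame(rows, columns=list(META_COLUMNS) + list(FEATURE_NAMES))


def normalize_per_subject(
    table: pd.DataFrame, columns: Sequence[str] | None = None
) -> pd.DataFrame:
    """Min-max scale the given feature columns within each subject.

    Defaults to the PWA and PPI families (SpO2 features keep their physical
    scale). Constant columns map to 0. Requires >= 2 segments per subject.
    """
    if columns is None:
        columns = list(PPI_FAMILY + PWA_FEATURES)
    out = table.copy()
    for subject, idx in table.groupby("subject_id").groups.items():
        if len(idx) < 2:
            raise ValueError(f"subject {subject} has a single segment; range undefined")
        block = out.loc[idx, columns]
        lo, hi = block.min(), block.max()
        span = (hi - lo).replace(0.0, np.nan)
        out.loc[idx, columns] = ((block - lo) / span).fillna(0.0)
    return out
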