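"""Raw waveform conditioning and beat-series extraction.

Pipeline order on the PPG channel: resample to the working rate (128 Hz),
zero-phase 0.7-20 Hz Butterworth band-pass, per-window artifact flagging
(|x - mean| > 1.5 SD on 60-s windows), systolic-peak detection, beat
cleaning to artifact-free NN intervals, and cubic-spline resampling of the
beat-indexed PPI/PWA sequences onto a uniform 4 Hz grid for spectral
analysis. SpO2 is used at its native 16 Hz.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal
from scipy.interpolate import CubicSpline

from .config import PreprocessingParams
from .synth import EventAnnotation, RawRecording
from .edf import read_edf_channel


@dataclass
class BeatSeries:
    """Per-beat systolic peaks with pulse intervals and amplitudes.

    ``ppi[i]`` is the interval between ``peak_times[i]`` and
    ``peak_times[i+1]`` ("time between successive systolic peaks"); ``pwa[i]``
    the peak-to-trough amplitude of beat ``i``. ``valid_mask`` marks beats
    surviving artifact rejection and NN cleaning.
    """

    peak_times: np.ndarray
    trough_times: np.ndarray
    pwa: np.ndarray
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        self.trough_times = np.asarray(self.trough_times, dtype=float)
        self.pwa = np.asarray(self.pwa, dtype=float)
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.peak_times.size, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.peak_times.size:
            if np.any(np.diff(self.peak_times) <= 0):
                raise ValueError("peak_times must be strictly increasing")
            if np.any(self.trough_times >= self.peak_times):
                raise ValueError("each trough must precede its paired peak")

    @property
    def ppi(self) -> np.ndarray:
        """Intervals between successive peaks; length len(peak_times) - 1."""
        return np.diff(self.peak_times)

    @property
    def n_beats(self) -> int:
        return int(self.peak_times.size)

    def valid_nn(self) -> np.ndarray:
        """NN intervals: PPIs whose two bounding beats are both valid."""
        if self.n_beats < 2:
            return np.empty(0)
        ok = self.valid_mask[:-1] & self.valid_mask[1:]
        return self.ppi[ok]


@dataclass
class UniformSeries:
    """Uniformly sampled series (4 Hz PPI/PWA, native 16 Hz SpO2)."""

    values: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.fs

    def slice(self, start_s: float, stop_s: float) -> "UniformSeries":
        i0 = int(np.ceil((start_s - self.t0) * self.fs - 1e-9))
        i1 = int(np.ceil((stop_s - self.t0) * self.fs - 1e-9))
        i0, i1 = max(i0, 0), min(i1, self.values.size)
        return UniformSeries(self.values[i0:i1], self.fs, self.t0 + i0 / self.fs)


def bandpass_ppg(
    ppg: np.ndarray,
    fs: float,
    low: float = 0.7,
    high: float = 20.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass of the PPG waveform.

    Forward-backward (``sosfiltfilt``) application avoids the phase shifts
    that would bias beat timings.
    """
    if fs <= 2 * high:
        raise ValueError(f"fs={fs} Hz too low for a {high} Hz passband edge")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(ppg, dtype=float))


def resample_signal(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Anti-aliased rate conversion via polyphase filtering."""
    if fs_in <= 0 or fs_out <= 0:
        raise ValueError("sampling rates must be positive")
    x = np.asarray(x, dtype=float)
    if fs_in == fs_out:
        return x.copy()
    from fractions import Fraction

    frac = Fraction(fs_out / fs_in).limit_denominator(1000)
    return signal.resample_poly(x, frac.numerator, frac.denominator)


def reject_artifacts(
    ppg: np.ndarray, fs: float, window_s: float = 60.0, k: float = 1.5
) -> np.ndarray:
    """Flag unusually large samples per non-overlapping 60-s window.

    A sample is invalid when |x - window mean| > k * window SD. Windows with
    zero variance flag nothing (the threshold degenerates). Returns a boolean
    validity mask per sample.
    """
    x = np.asarray(ppg, dtype=float)
    win = int(round(window_s * fs))
    if win < 2:
        raise ValueError("artifact window must span at least 2 samples")
    valid = np.ones(x.size, dtype=bool)
    for start in range(0, x.size, win):
        seg = x[start : start + win]
        sd = seg.std()
        if sd == 0:
            continue
        valid[start : start + win] = np.abs(seg - seg.mean()) <= k * sd
    return valid


def detect_pulses(
    ppg: np.ndarray,
    fs: float,
    min_rate_bpm: float = 30.0,
    max_rate_bpm: float = 180.0,
    sample_valid: np.ndarray | None = None,
    prominence_frac: float = 0.3,
) -> BeatSeries:
    """Locate systolic peaks and paired troughs in a band-passed PPG.

    Candidate peaks are local maxima separated by at least ``60/max_rate``
    seconds; each is kept if its prominence exceeds ``prominence_frac`` times
    the rolling (60 s) median prominence, an adaptive threshold that tracks
    slow amplitude drift. The trough paired with a peak is the signal minimum
    over the preceding half pulse-interval. Beats whose peak or trough falls
    on an artifact-flagged sample are marked invalid.
    """
    x = np.asarray(ppg, dtype=float)
    min_dist = int(round(60.0 / max_rate_bpm * fs))
    peaks, props = signal.find_peaks(x, distance=max(min_dist, 1), prominence=1e-12)
    if peaks.size < 2:
        warnings.warn("fewer than 2 pulses detected; returning empty beat series")
        return BeatSeries(np.empty(0), np.empty(0), np.empty(0), np.empty(0, dtype=bool))
    prom = props["prominences"]
    # adaptive threshold: a rolling upper-quantile of candidate prominences
    # tracks the local pulse amplitude even through slow drift; noise peaks
    # sit far below it
    ref = (
        pd.Series(prom)
        .rolling(151, center=True, min_periods=20)
        .quantile(0.8)
        .to_numpy()
    )
    ref = np.where(np.isnan(ref), np.quantile(prom, 0.8), ref)
    keep = prom > prominence_frac * ref
    peaks = peaks[keep]
    if peaks.size < 2:
        warnings.warn("fewer than 2 pulses detected; returning empty beat series")
        return BeatSeries(np.empty(0), np.empty(0), np.empty(0), np.empty(0, dtype=bool))

    max_ppi = 60.0 / min_rate_bpm
    trough_idx = np.empty(peaks.size, dtype=int)
    for i, p in enumerate(peaks):
        lo = peaks[i - 1] if i > 0 else max(0, p - int(max_ppi * fs / 2))
        lo = max(lo, p - int(max_ppi * fs / 2), 0)
        if lo >= p:
            lo = max(0, p - 1)
        trough_idx[i] = lo + int(np.argmin(x[lo:p])) if p > lo else max(0, p - 1)
    pwa = x[peaks] - x[trough_idx]

    # refine beat times to the midpoint of the half-amplitude crossings:
    # the pulse flanks are steep there, so the timing is far less sensitive
    # to noise (or to a rounded/flat systolic top) than the argmax sample
    peak_t = peaks / fs
    half_win = int(0.6 * fs)
    for i, (p, tr) in enumerate(zip(peaks, trough_idx)):
        level = x[tr] + 0.5 * pwa[i]
        lo = max(tr, p - half_win)
        left = None
        for j in range(p, lo, -1):
            if x[j - 1] <= level <= x[j] and x[j] > x[j - 1]:
                frac = (level - x[j - 1]) / (x[j] - x[j - 1])
                left = (j - 1 + frac) / fs
                break
        hi = min(x.size - 1, p + half_win)
        right = None
        for j in range(p, hi):
            if x[j] >= level >= x[j + 1] and x[j] > x[j + 1]:
                frac = (x[j] - level) / (x[j] - x[j + 1])
                right = (j + frac) / fs
                break
        if left is not None and right is not None and right > left:
            peak_t[i] = 0.5 * (left + right)

    valid = pwa > 0
    if sample_valid is not None:
        valid &= sample_valid[peaks] & sample_valid[trough_idx]
    # drop degenerate beats: trough must strictly precede the (refined) peak
    # and refined peak times must stay increasing
    ok = trough_idx / fs < peak_t
    keep = np.flatnonzero(ok)
    mono = np.ones(keep.size, dtype=bool)
    last = -np.inf
    for i, idx in enumerate(keep):
        if peak_t[idx] <= last:
            mono[i] = False
        else:
            last = peak_t[idx]
    keep = keep[mono]
    return BeatSeries(peak_t[keep], trough_idx[keep] / fs, pwa[keep], valid[keep])


def clean_beats(
    beats: BeatSeries,
    min_ppi_s: float = 0.33,
    max_ppi_s: float = 2.0,
    max_jump_frac: float = 0.30,
) -> BeatSeries:
    """Mask beats outside physiological PPI bounds or jumping > 30% from
    the running median of the 5 preceding valid PPIs (artifact-free NN rule).

    No interpolation happens here; invalid beats are only excluded from NN
    statistics. A beat is invalidated when the interval *following* it is
    implausible, mirroring how ectopy corrupts the interval it starts.
    """
    if beats.n_beats == 0:
        raise ValueError("cannot clean an empty beat series")
    valid = beats.valid_mask.copy()
    ppi = beats.ppi
    history: list[float] = []
    for i, interval in enumerate(ppi):
        if not (valid[i] and valid[i + 1]):
            continue
        ok = min_ppi_s <= interval <= max_ppi_s
        if ok and history:
            med = float(np.median(history[-5:]))
            ok = abs(interval - med) <= max_jump_frac * med
        if ok:
            history.append(float(interval))
        else:
            valid[i + 1] = False
    return BeatSeries(beats.peak_times, beats.trough_times, beats.pwa, valid)


def resample_beat_series(
    beats: BeatSeries, which: str, fs_out: float = 4.0,
    t_start: float | None = None, t_stop: float | None = None,
) -> UniformSeries:
    """Cubic interpolation of a beat-indexed sequence onto a uniform grid.

    ``which`` selects ``"ppi"`` (interval assigned to the later peak of the
    pair) or ``"pwa"``. Only valid beats anchor the spline; gaps from
    invalid beats are bridged by the interpolant.
    """
    if which not in ("ppi", "pwa"):
        raise ValueError("which must be 'ppi' or 'pwa'")
    valid = beats.valid_mask
    if which == "pwa":
        t = beats.peak_times[valid]
        v = beats.pwa[valid]
    else:
        ok = valid[:-1] & valid[1:]
        t = beats.peak_times[1:][ok]
        v = beats.ppi[ok]
    if t.size < 4:
        raise ValueError("need at least 4 valid beats to resample")
    spline = CubicSpline(t, v)
    t0 = t[0] if t_start is None else t_start
    t1 = t[-1] if t_stop is None else t_stop
    # half-open grid [t0, t1): a 60-s window at 4 Hz gives exactly 240 samples
    n = int(np.round((t1 - t0) * fs_out))
    grid = t0 + np.arange(n) / fs_out
    vals = spline(np.clip(grid, t[0], t[-1]))  # hold ends, no extrapolation blow-up
    return UniformSeries(vals, fs_out, t0)


def preprocess_recording(
    rec: RawRecording, params: PreprocessingParams | None = None
) -> dict:
    """Full conditioning of one recording.

    Returns a dict with the cleaned ``BeatSeries`` (``beats``), 4 Hz
    ``UniformSeries`` for PPI and PWA spanning the recording, the SpO2
    ``UniformSeries`` at native rate, and the sample validity mask.
    """
    p = params or PreprocessingParams()
    ppg, fs = rec.ppg, rec.ppg_fs
    if fs != p.target_ppg_fs:
        ppg = resample_signal(ppg, fs, p.target_ppg_fs)
        fs = p.target_ppg_fs
    ppg = bandpass_ppg(ppg, fs, p.band_low_hz, p.band_high_hz, p.filter_order)
    sample_valid = reject_artifacts(ppg, fs, p.artifact_window_s, p.artifact_k)
    beats = detect_pulses(ppg, fs, sample_valid=sample_valid)
    beats = clean_beats(beats, p.min_ppi_s, p.max_ppi_s, p.max_ppi_jump_frac)
    duration_s = rec.recording_time_h * 3600.0
    ppi_4hz = resample_beat_series(beats, "ppi", p.beat_fs_out, 0.0, duration_s)
    pwa_4hz = resample_beat_series(beats, "pwa", p.beat_fs_out, 0.0, duration_s)
    spo2 = UniformSeries(rec.spo2, rec.spo2_fs, 0.0)
    return {
        "beats": beats,
        "ppi_4hz": ppi_4hz,
        "pwa_4hz": pwa_4hz,
        "spo2": spo2,
        "sample_valid": sample_valid,
        "ppg_fs": fs,
    }


def read_fixture(edf_path: str | Path) -> RawRecording:
    """Load a fixture written by :func:`oxipulse.synth.write_fixture`."""
    edf_path = Path(edf_path)
    stem = edf_path.stem
    ppg, ppg_fs = read_edf_channel(edf_path, "PPG")
    spo2, spo2_fs = read_edf_channel(edf_path, "SpO2")
    events_path = edf_path.with_name(f"{stem}_events.csv")
    meta_path = edf_path.with_name(f"{stem}_meta.json")
    events = []
    if events_path.exists():
        df = pd.read_csv(events_path)
        events = [
            EventAnnotation(r.kind, float(r.onset_s), float(r.duration_s))
            for r in df.itertuples()
        ]
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return RawRecording(
        subject_id=meta.get("subject_id", stem),
        ppg=ppg,
        ppg_fs=ppg_fs,
        spo2=spo2,
        spo2_fs=spo2_fs,
        events=events,
        recording_time_h=meta.get("recording_time_h", len(ppg) / ppg_fs / 3600.0),
        reference_ahi=meta.get("reference_ahi", float("nan")),
        comorbidity=meta.get("comorbidity", False),
    )
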