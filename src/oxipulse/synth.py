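"""Synthetic overnight pulse-oximetry recordings with known ground truth.

The generator produces the three signals the screening pipeline consumes -
an AC-coupled PPG waveform, an SpO2 trace and event annotations - with the
physiological couplings the analysis assumes built in:

* pulsatile PPG rendered as a train of asymmetric (fast-rise, slow-decay)
  pulse kernels whose per-beat amplitude (PWA) and interval (PPI) carry
  respiratory and low-frequency modulation;
* a transient sympathetic "arousal response" time-locked to the end of
  arousal-associated respiratory events: PWA multiplied by
  ``1 - pwa_drop_frac`` and PPI by ``1 - ppi_shortening_frac``, both
  recovering exponentially with a 15 s time constant;
* SpO2 desaturations lagging apneas and the desaturating subset of
  hypopneas, while arousal-only hypopneas leave SpO2 untouched.

Every recording carries a :class:`GroundTruth` block (planted beat times,
amplitudes, intervals, arousal-response level per beat) so downstream
detectors can be scored against what was actually synthesized.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import SynthConfig
from .edf import write_edf

AROUSAL_TAU_S = 15.0  # recovery time constant of the arousal response
AROUSAL_DURATION_S = 10.0
AROUSAL_LEAD_S = 3.0  # arousal starts this long before event end
SPO2_BASELINE_PCT = 97.0
SPO2_WANDER_SD_PCT = 0.3
HYPOPNEA_DESAT_SCALE = 0.6  # desaturating hypopneas dip at 60% of apnea depth

SEVERITY_BIN_EDGES = ((0.5, 5.0), (5.0, 15.0), (15.0, 30.0), (30.0, 45.0))
SEVERITY_BIN_NAMES = ("none", "mild", "moderate", "severe")


@dataclass(frozen=True)
class EventAnnotation:
    """One scored event: obstructive apnea, hypopnea or arousal."""

    kind: str  # {"obstructive_apnea", "hypopnea", "arousal"}
    onset: float  # seconds from recording start
    duration: float  # seconds

    def __post_init__(self) -> None:
        if self.kind not in ("obstructive_apnea", "hypopnea", "arousal"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        min_dur = 3.0 if self.kind == "arousal" else 10.0
        if self.duration < min_dur:
            raise ValueError(
                f"{self.kind} duration {self.duration} below minimum {min_dur} s"
            )
        if self.onset < 0:
            raise ValueError("onset must be >= 0")

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass
class GroundTruth:
    """Planted per-beat bookkeeping for oracle checks of downstream stages."""

    beat_times: np.ndarray  # s, systolic peak times
    beat_pwa: np.ndarray  # planted amplitude per beat, a.u.
    beat_ppi: np.ndarray  # planted interval preceding each beat (beat_times diff), s
    arousal_level: np.ndarray  # arousal-response level in [0, 1] per beat


@dataclass
class RawRecording:
    """One subject's overnight PPG + SpO2 recording with annotations."""

    subject_id: str
    ppg: np.ndarray
    ppg_fs: float
    spo2: np.ndarray
    spo2_fs: float
    events: list[EventAnnotation]
    recording_time_h: float
    reference_ahi: float
    comorbidity: bool = False
    truth: GroundTruth | None = None

    @property
    def respiratory_events(self) -> list[EventAnnotation]:
        return [e for e in self.events if e.kind != "arousal"]

    @property
    def arousals(self) -> list[EventAnnotation]:
        return [e for e in self.events if e.kind == "arousal"]


def _pulse_kernel(
    t: np.ndarray, span: float, warp: float = 0.7, shape: float = 3.5
) -> np.ndarray:
    """Single-lobe asymmetric pulse over [0, span], peak value 1.

    A time-warped squared sine, sin(pi * (t/span)^warp)^2, passed through a
    symmetric tanh shaper that flattens both extremes. warp < 1 gives the
    fast systolic rise and slow diastolic decay of a finger-PPG pulse; the
    shaper keeps the duty cycle near both extremes high enough that clean
    pulse peaks and troughs stay inside the 1.5-SD artifact envelope the
    preprocessing applies downstream.
    """
    out = np.zeros_like(t)
    inside = (t > 0) & (t < span)
    u = (t[inside] / span) ** warp
    g = np.sin(np.pi * u) ** 2
    out[inside] = 0.5 * (1.0 + np.tanh(shape * (g - 0.5)) / np.tanh(shape * 0.5))
    return out


def _schedule_events(cfg: SynthConfig, rng: np.random.Generator) -> list[EventAnnotation]:
    """Evenly spaced events with jittered gaps; count is exact by design."""
    n = cfg.n_scheduled_events
    duration_s = cfg.duration_h * 3600.0
    if n == 0:
        return []
    # leave head room for warm-up and tail room for the trailing desaturation
    usable_start, usable_end = 60.0, duration_s - 90.0
    slot = (usable_end - usable_start) / n
    max_event_dur = 30.0
    if slot < max_event_dur + 15.0:
        raise ValueError(
            f"event_rate_per_h={cfg.event_rate_per_h} over {cfg.duration_h} h implies "
            f"inter-event slots of {slot:.1f} s, too short for non-overlapping events"
        )
    n_apnea = int(round(cfg.frac_apnea * n))
    kinds = np.array(["obstructive_apnea"] * n_apnea + ["hypopnea"] * (n - n_apnea))
    rng.shuffle(kinds)

    hyp_idx = np.flatnonzero(kinds == "hypopnea")
    n_arousal_only = int(round(cfg.frac_hypopnea_arousal_only * len(hyp_idx)))
    arousal_only = set(rng.choice(hyp_idx, size=n_arousal_only, replace=False).tolist())

    events: list[EventAnnotation] = []
    for i, kind in enumerate(kinds):
        dur = rng.uniform(10.0, 30.0) if kind == "obstructive_apnea" else rng.uniform(10.0, 25.0)
        center = usable_start + (i + 0.5) * slot + rng.uniform(-0.2, 0.2) * slot
        onset = max(usable_start, min(center - dur / 2.0, usable_end - dur))
        ev = EventAnnotation(kind=str(kind), onset=onset, duration=dur)
        events.append(ev)
        # arousal terminating the event: all apneas and arousal-only hypopneas,
        # half of the desaturating hypopneas
        has_arousal = (
            kind == "obstructive_apnea"
            or i in arousal_only
            or rng.random() < 0.5
        )
        if has_arousal:
            events.append(
                EventAnnotation(
                    kind="arousal",
                    onset=ev.end - AROUSAL_LEAD_S,
                    duration=AROUSAL_DURATION_S,
                )
            )
        if kind == "hypopnea" and i in arousal_only:
            object.__setattr__(ev, "_desaturating", False)
        else:
            object.__setattr__(ev, "_desaturating", True)
    events.sort(key=lambda e: e.onset)
    for ev in events:
        if ev.end > duration_s:
            raise ValueError("scheduled event extends beyond recording length")
    return events


def _arousal_response(t: np.ndarray, arousals: np.ndarray) -> np.ndarray:
    """Superposed arousal-response level in [0, 1] at times ``t``.

    ``arousals`` is an (n, 2) array of (onset, end). Each arousal holds the
    response at 1 for its whole annotated window, then it recovers
    exponentially with time constant ``AROUSAL_TAU_S``; overlapping
    responses saturate at 1.
    """
    level = np.zeros_like(t, dtype=float)
    for onset, end in arousals:
        decay = np.exp(-np.maximum(t - end, 0.0) / AROUSAL_TAU_S)
        level += np.where(t < onset, 0.0, decay)
    return np.clip(level, 0.0, 1.0)


def generate_recording(config: SynthConfig, subject_id: str = "synth-000",
                       comorbidity: bool = False) -> RawRecording:
    """Synthesize one overnight recording from a :class:`SynthConfig`.

    Returns a :class:`RawRecording` whose ``reference_ahi`` equals the
    scheduled apnea+hypopnea count divided by the recording time exactly,
    and whose ``truth`` block records every planted beat.
    """
    rng = np.random.default_rng(config.seed)
    duration_s = config.duration_h * 3600.0
    events = _schedule_events(config, rng)
    resp_events = [e for e in events if e.kind != "arousal"]
    arousal_windows = np.array(
        [(e.onset, e.end) for e in events if e.kind == "arousal"]
    ).reshape(-1, 2)

    # --- beat train -------------------------------------------------------
    base_ppi = 60.0 / config.base_pulse_rate
    n_max = int(duration_s / (base_ppi * (1.0 - config.ppi_shortening_frac))) + 16
    phase_lf = rng.uniform(0, 2 * np.pi)
    phase_resp = rng.uniform(0, 2 * np.pi)
    beat_times = np.empty(n_max)
    beat_ppi = np.empty(n_max)
    # arousal-response level precomputed on a 4 Hz grid; the beat loop then
    # does O(1) lookups instead of scanning every arousal per beat
    grid_fs = 4.0
    grid = np.arange(int(duration_s * grid_fs) + 1) / grid_fs
    grid_level = _arousal_response(grid, arousal_windows)
    t = rng.uniform(0, base_ppi)
    i = 0
    while t < duration_s and i < n_max:
        level = float(grid_level[int(t * grid_fs)])
        mod = (
            1.0
            + 0.03 * np.sin(2 * np.pi * 0.25 * t + phase_resp)  # respiratory sinus arrhythmia
            + 0.02 * np.sin(2 * np.pi * 0.09 * t + phase_lf)  # LF (baroreflex-like)
            # beat-to-beat jitter, inflated during the sympathetic surge so
            # short-term variability (RMSSD-type) rises around arousals; the
            # inflation scales with the configured PPI response so disabling
            # the arousal phenomenology silences it too
            + rng.normal(0.0, 0.01 * (1.0 + 10.0 * config.ppi_shortening_frac * level))
        )
        ppi = base_ppi * mod * (1.0 - config.ppi_shortening_frac * level)
        beat_times[i] = t
        beat_ppi[i] = ppi
        t += ppi
        i += 1
    beat_times = beat_times[:i]
    beat_ppi = beat_ppi[:i]

    beat_level = _arousal_response(beat_times, arousal_windows)
    pwa_mod = (
        1.0
        + 0.05 * np.sin(2 * np.pi * 0.1 * beat_times + phase_lf)
        + 0.04 * np.sin(2 * np.pi * 0.25 * beat_times + phase_resp)
        + rng.normal(0.0, 0.03, size=beat_times.size)
    )
    beat_pwa = config.base_pwa * np.clip(pwa_mod, 0.3, None) * (
        1.0 - config.pwa_drop_frac * beat_level
    )

    # --- render PPG -------------------------------------------------------
    n_ppg = int(round(duration_s * config.ppg_fs))
    tt = np.arange(n_ppg) / config.ppg_fs
    ppg = np.zeros(n_ppg)
    kernel_span = 0.92  # fraction of the beat interval covered by the pulse
    for bt, amp, ppi in zip(beat_times, beat_pwa, beat_ppi):
        span = kernel_span * ppi
        i0 = int(np.ceil(bt * config.ppg_fs))
        i1 = min(int(np.floor((bt + span) * config.ppg_fs)) + 1, n_ppg)
        if i0 >= i1:
            continue
        ppg[i0:i1] += amp * _pulse_kernel(tt[i0:i1] - bt, span)
    ppg += rng.normal(0.0, config.noise_sd, size=n_ppg)
    # AC coupling: remove the slow baseline left by the one-sided kernels
    win = int(2.0 * config.ppg_fs)
    kernel = np.ones(win) / win
    baseline = np.convolve(ppg, kernel, mode="same")
    ppg = ppg - baseline

    # --- SpO2 -------------------------------------------------------------
    n_sp = int(round(duration_s * config.spo2_fs))
    ts = np.arange(n_sp) / config.spo2_fs
    # red-noise wander: AR(1) scaled to target SD
    alpha = np.exp(-1.0 / (30.0 * config.spo2_fs))  # 30 s correlation time
    innov = rng.normal(0.0, 1.0, size=n_sp)
    wander = np.empty(n_sp)
    wander[0] = innov[0]
    for k in range(1, n_sp):
        wander[k] = alpha * wander[k - 1] + np.sqrt(1 - alpha**2) * innov[k]
    wander *= SPO2_WANDER_SD_PCT
    spo2 = SPO2_BASELINE_PCT + wander
    for ev in resp_events:
        if not getattr(ev, "_desaturating", True):
            continue
        # deeper dips for longer events; hypopneas desaturate less than apneas
        depth = config.desat_depth_pct * (0.7 + 0.3 * min(ev.duration, 30.0) / 30.0)
        if ev.kind == "hypopnea":
            depth *= HYPOPNEA_DESAT_SCALE
        # saturation starts falling while the airway is still obstructed
        # (shifted by circulation delay), reaches its nadir desat_lag_s after
        # the event ends, then recovers exponentially on reoxygenation
        fall_start = ev.onset + 0.5 * config.desat_lag_s
        nadir = ev.end + config.desat_lag_s
        rec_tau = 20.0
        dip = np.zeros_like(ts)
        falling = (ts >= fall_start) & (ts <= nadir)
        if nadir > fall_start:
            u = (ts[falling] - fall_start) / (nadir - fall_start)
            dip[falling] = 0.5 * (1.0 - np.cos(np.pi * u))
        after = ts > nadir
        dip[after] = np.exp(-(ts[after] - nadir) / rec_tau)
        spo2 -= depth * dip
    spo2 = np.clip(spo2, 50.0, 100.0)

    reference_ahi = len(resp_events) / config.duration_h
    return RawRecording(
        subject_id=subject_id,
        ppg=ppg,
        ppg_fs=config.ppg_fs,
        spo2=spo2,
        spo2_fs=config.spo2_fs,
        events=events,
        recording_time_h=config.duration_h,
        reference_ahi=reference_ahi,
        comorbidity=comorbidity,
        truth=GroundTruth(
            # systolic fiducial: the half-amplitude midpoint of each rendered
            # pulse sits at ~0.40 of the kernel span past the beat onset
            beat_times=beat_times + 0.40 * kernel_span * beat_ppi,
            beat_pwa=beat_pwa,
            beat_ppi=beat_ppi,
            arousal_level=beat_level,
        ),
    )


def largest_remainder_counts(fractions: Sequence[float], n: int) -> list[int]:
    """Apportion ``n`` items to bins by largest-remainder rounding."""
    fr = np.asarray(fractions, dtype=float)
    if fr.min() < 0:
        raise ValueError("fractions must be non-negative")
    if abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    exact = fr * n
    counts = np.floor(exact).astype(int)
    remainder = exact - counts
    short = n - counts.sum()
    for idx in np.argsort(-remainder, kind="stable")[:short]:
        counts[idx] += 1
    return counts.tolist()


def generate_cohort(
    n_subjects: int,
    severity_mix: Sequence[float] = (0.122, 0.244, 0.356, 0.278),
    seed: int = 0,
    base_config: SynthConfig | None = None,
) -> list[RawRecording]:
    """Generate a cohort spanning the four AHI severity bins.

    ``severity_mix`` gives the fraction of subjects in the AHI bins
    <5 / 5-15 / 15-30 / >30; per-subject ground-truth AHI is drawn uniformly
    within the assigned bin. Deterministic for a fixed seed. Each subject's
    comorbidity flag is an independent fair coin, mirroring a cohort where
    half the subjects carry hypertension/dyslipidemia/diabetes.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects to cross-validate")
    if len(severity_mix) != 4:
        raise ValueError("severity_mix must have 4 entries (AHI <5, 5-15, 15-30, >30)")
    base = base_config or SynthConfig()
    rng = np.random.default_rng(seed)
    counts = largest_remainder_counts(severity_mix, n_subjects)
    bins = [b for b, c in zip(SEVERITY_BIN_EDGES, counts) for _ in range(c)]
    order = rng.permutation(n_subjects)  # shuffle bin assignment across ids
    cohort: list[RawRecording] = []
    for j in range(n_subjects):
        lo, hi = bins[order[j]]
        ahi = rng.uniform(lo, hi)
        comorbidity = bool(rng.random() < 0.5)
        cfg_kwargs = {
            **{f: getattr(base, f) for f in base.__dataclass_fields__},
            "event_rate_per_h": float(ahi),
            "seed": int(rng.integers(0, 2**31 - 1)),
        }
        cohort.append(
            generate_recording(
                SynthConfig(**cfg_kwargs),
                subject_id=f"synth-{j:03d}",
                comorbidity=comorbidity,
            )
        )
    return cohort


def write_fixture(recording: RawRecording, path: str | Path, overwrite: bool = False) -> dict:
    """Write a recording as EDF signals + CSV annotations + JSON metadata.

    Creates ``<subject_id>.edf``, ``<subject_id>_events.csv`` and
    ``<subject_id>_meta.json`` under ``path``. Signals round-trip through
    the EDF reader up to 16-bit quantization.
    """
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    edf_path = out / f"{recording.subject_id}.edf"
    csv_path = out / f"{recording.subject_id}_events.csv"
    meta_path = out / f"{recording.subject_id}_meta.json"
    for p in (edf_path, csv_path, meta_path):
        if p.exists() and not overwrite:
            raise FileExistsError(f"{p} exists; pass overwrite=True to replace")
    write_edf(
        edf_path,
        channels=[
            ("PPG", recording.ppg, recording.ppg_fs, "au"),
            ("SpO2", recording.spo2, recording.spo2_fs, "%"),
        ],
        phys_ranges=[None, (0.0, 100.0)],
    )
    pd.DataFrame(
        [(e.kind, e.onset, e.duration) for e in recording.events],
        columns=["kind", "onset_s", "duration_s"],
    ).to_csv(csv_path, index=False)
    meta_path.write_text(
        json.dumps(
            {
                "subject_id": recording.subject_id,
                "recording_time_h": recording.recording_time_h,
                "reference_ahi": recording.reference_ahi,
                "comorbidity": recording.comorbidity,
            },
            indent=2,
        )
    )
    return {"edf": edf_path, "events": csv_path, "meta": meta_path}
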