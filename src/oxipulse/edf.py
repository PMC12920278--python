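"""Minimal EDF (European Data Format) writer.

Writes standard EDF: fixed-width ASCII header, one-second data records,
16-bit little-endian samples scaled between per-channel physical and
digital ranges. Enough of the format for multi-rate physiological fixtures
that standard EDF readers (e.g. ``mne.io.read_raw_edf``) open unmodified.
Channel sampling rates must be integers (samples per 1-s record).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

DIG_MIN, DIG_MAX = -32768, 32767


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def _num(value: float, width: int) -> bytes:
    for fmt in (f"{value:.10g}", f"{value:.4f}", f"{value:.2f}", f"{value:.0f}"):
        if len(fmt) <= width:
            return _field(fmt, width)
    raise ValueError(f"cannot format {value} in {width} chars")


def write_edf(
    path: str | Path,
    channels: Sequence[tuple[str, np.ndarray, float, str]],
    phys_ranges: Sequence[tuple[float, float] | None] | None = None,
) -> None:
    """Write ``channels`` = [(label, samples, fs, unit), ...] to ``path``.

    ``phys_ranges`` optionally fixes the physical min/max per channel (e.g.
    (0, 100) for SpO2); by default a symmetric range covering the data is
    used. Signals are truncated to a whole number of 1-s records.
    """
    if phys_ranges is None:
        phys_ranges = [None] * len(channels)
    n_sig = len(channels)
    rates = []
    n_records = None
    for label, x, fs, unit in channels:
        if abs(fs - round(fs)) > 1e-9 or fs <= 0:
            raise ValueError(f"channel {label}: fs must be a positive integer, got {fs}")
        rates.append(int(round(fs)))
        nrec = len(x) // int(round(fs))
        n_records = nrec if n_records is None else min(n_records, nrec)
    if not n_records:
        raise ValueError("signals shorter than one 1-s record")

    header = b""
    header += _field("0", 8)
    header += _field("X X X X", 80)  # local patient id (anonymous)
    header += _field("Startdate X X X X", 80)
    header += _field("01.01.00", 8)
    header += _field("00.00.00", 8)
    header += _num(256 * (n_sig + 1), 8)
    header += _field("", 44)
    header += _num(n_records, 8)
    header += _num(1, 8)  # record duration, s
    header += _num(n_sig, 4)

    phys = []
    for (label, x, fs, unit), rng in zip(channels, phys_ranges):
        if rng is None:
            amp = (float(np.max(np.abs(x))) or 1.0) * 1.001  # margin vs rounding
            rng = (-amp, amp)
        if rng[1] <= rng[0]:
            raise ValueError(f"channel {label}: degenerate physical range {rng}")
        # canonicalize to the 8-char header representation so the gain used
        # for digitization matches what any reader reconstructs
        rng = (float(_num(rng[0], 8)), float(_num(rng[1], 8)))
        phys.append(rng)

    for get in (
        lambda c, r, fs_: _field(c[0], 16),
        lambda c, r, fs_: _field("", 80),
        lambda c, r, fs_: _field(c[3], 8),
        lambda c, r, fs_: _num(r[0], 8),
        lambda c, r, fs_: _num(r[1], 8),
        lambda c, r, fs_: _num(DIG_MIN, 8),
        lambda c, r, fs_: _num(DIG_MAX, 8),
        lambda c, r, fs_: _field("", 80),
        lambda c, r, fs_: _num(fs_, 8),
        lambda c, r, fs_: _field("", 32),
    ):
        for ch, r, fs_ in zip(channels, phys, rates):
            header += get(ch, r, fs_)

    digital = []
    for (label, x, fs, unit), (pmin, pmax) in zip(channels, phys):
        gain = (DIG_MAX - DIG_MIN) / (pmax - pmin)
        d = np.round((np.asarray(x, dtype=float) - pmin) * gain + DIG_MIN)
        digital.append(np.clip(d, DIG_MIN, DIG_MAX).astype("<i2"))

    with open(path, "wb") as fh:
        fh.write(header)
        for rec in range(n_records):
            for d, fs_ in zip(digital, rates):
                fh.write(d[rec * fs_ : (rec + 1) * fs_].tobytes())


def read_edf_channel(path: str | Path, label: str) -> tuple[np.ndarray, float]:
    """Read one channel back from an EDF file at its native rate.

    A deliberately small reader for the writer above (and any standard EDF):
    parses the header directly so multi-rate files are returned without the
    upsampling general-purpose readers apply.
    """
    with open(path, "rb") as fh:
        head = fh.read(256)
        n_records = int(head[236:244])
        n_sig = int(head[252:256])
        sig_head = fh.read(256 * n_sig)
        labels = [sig_head[16 * i : 16 * (i + 1)].decode().strip() for i in range(n_sig)]
        off = 16 * n_sig + 80 * n_sig + 8 * n_sig
        pmins = [float(sig_head[off + 8 * i : off + 8 * (i + 1)]) for i in range(n_sig)]
        off += 8 * n_sig
        pmaxs = [float(sig_head[off + 8 * i : off + 8 * (i + 1)]) for i in range(n_sig)]
        off += 8 * n_sig
        dmins = [float(sig_head[off + 8 * i : off + 8 * (i + 1)]) for i in range(n_sig)]
        off += 8 * n_sig
        dmaxs = [float(sig_head[off + 8 * i : off + 8 * (i + 1)]) for i in range(n_sig)]
        off += 8 * n_sig + 80 * n_sig
        sprs = [int(sig_head[off + 8 * i : off + 8 * (i + 1)]) for i in range(n_sig)]

        if label not in labels:
            raise KeyError(f"channel {label!r} not in {labels}")
        idx = labels.index(label)
        rec_len = sum(sprs)
        data = np.frombuffer(fh.read(2 * rec_len * n_records), dtype="<i2")

    data = data.reshape(n_records, rec_len)
    start = sum(sprs[:idx])
    raw = data[:, start : start + sprs[idx]].reshape(-1).astype(float)
    gain = (pmaxs[idx] - pmins[idx]) / (dmaxs[idx] - dmins[idx])
    return pmins[idx] + (raw - dmins[idx]) * gain, float(sprs[idx])
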