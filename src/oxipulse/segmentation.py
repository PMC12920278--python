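"""Non-overlapping 60-second segmentation and event-overlap labeling.

A segment is positive when apnea/hypopnea events occupy at least 10 s of
its window (cumulative across events by default, with a switch for the
single-event reading); the arousal tag is set by any nonzero intersection
with an arousal annotation. Windows are half-open [start, start+60): an
event boundary touching the right edge contributes zero overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .config import SegmentationParams
from .synth import EventAnnotation, RawRecording


@dataclass
class SegmentRecord:
    """One 60-s analysis window of one subject."""

    subject_id: str
    start: float  # s from recording start
    length: float
    label: int  # 1 positive, 0 negative
    arousal: bool
    quality: str = "ok"  # {"ok", "low"}

    @property
    def stop(self) -> float:
        return self.start + self.length


def _interval_overlap(a0: float, a1: float, b0: float, b1: float) -> float:
    return max(0.0, min(a1, b1) - max(a0, b0))


def label_segment(
    start: float,
    length: float,
    events: Sequence[EventAnnotation],
    min_overlap: float = 10.0,
    cumulative: bool = True,
) -> int:
    """Positive (1) iff apnea/hypopnea overlap with [start, start+length)
    reaches ``min_overlap`` seconds.

    ``cumulative=True`` sums intersections across events (clustered short
    events count as one burden); ``False`` requires a single event to reach
    the threshold on its own.
    """
    stop = start + length
    overlaps = [
        _interval_overlap(start, stop, e.onset, e.end)
        for e in events
        if e.kind != "arousal"
    ]
    if not overlaps:
        return 0
    total = sum(overlaps) if cumulative else max(overlaps)
    return int(total >= min_overlap)


def tag_arousal(start: float, length: float, events: Sequence[EventAnnotation]) -> bool:
    """True iff any arousal annotation intersects the window by > 0 s."""
    stop = start + length
    return any(
        _interval_overlap(start, stop, e.onset, e.end) > 0
        for e in events
        if e.kind == "arousal"
    )


def segment_recording(
    rec: RawRecording, params: SegmentationParams | None = None
) -> list[SegmentRecord]:
    """Tile the recording into floor(duration/seg_len) non-overlapping
    segments; the trailing partial window is discarded."""
    p = params or SegmentationParams()
    duration_s = rec.recording_time_h * 3600.0
    if duration_s < p.seg_len_s:
        raise ValueError("recording shorter than one segment")
    n = int(np.floor(duration_s / p.seg_len_s + 1e-9))
    events = sorted(rec.events, key=lambda e: e.onset)
    out = []
    for i in range(n):
        start = i * p.seg_len_s
        out.append(
            SegmentRecord(
                subject_id=rec.subject_id,
                start=start,
                length=p.seg_len_s,
                label=label_segment(
                    start, p.seg_len_s, events, p.min_overlap_s, p.cumulative_overlap
                ),
                arousal=tag_arousal(start, p.seg_len_s, events),
            )
        )
    return out


def segments_to_frame(segments: Sequence[SegmentRecord]) -> pd.DataFrame:
    """Segment table: subject_id, start_s, label, arousal, quality."""
    return pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in segments],
            "start_s": [s.start for s in segments],
            "label": [s.label for s in segments],
            "arousal": [s.arousal for s in segments],
            "quality": [s.quality for s in segments],
        }
    )
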