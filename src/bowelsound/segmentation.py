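"""Fixed-length labeled segmentation of annotated recordings.

The classifier consumes fixed 375 ms slices. Prominent intervals shorter
than the segment are centered in one segment (clamped to the recording
boundaries); longer intervals are tiled with overlapping windows at a
175 ms hop, plus one final end-aligned window so the interval's tail is
covered. Non-prominent segments tile the quiet gaps between prominent
intervals — including the stretch before the first and after the last —
with the same hop, discarding any remainder shorter than a full segment.

All arithmetic is in integer milliseconds; the sample slice for a segment
starting at ``t`` ms is ``[floor(t*sr/1000), floor(t*sr/1000) + n)`` with
``n = floor(L*sr/1000)`` so every segment has an identical sample count.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotations import AnnotatedRecording, AnnotationInterval
from .audio import AudioRecording, write_wav

__all__ = [
    "SegmentationConfig",
    "Segment",
    "SegmentDataset",
    "prominent_starts",
    "gap_starts",
    "extract_prominent",
    "extract_non_prominent",
    "segment_recording",
    "build_dataset",
    "write_segments",
]


@dataclass(frozen=True)
class SegmentationConfig:
    """Window length and overlap, in integer milliseconds."""

    segment_length_ms: int = 375
    overlap_ms: int = 200

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_ms < self.segment_length_ms:
            raise ValueError(
                f"overlap ({self.overlap_ms} ms) must be in [0, segment length "
                f"{self.segment_length_ms} ms)"
            )

    @property
    def hop_ms(self) -> int:
        return self.segment_length_ms - self.overlap_ms

    def n_samples(self, sample_rate_hz: int) -> int:
        return int(self.segment_length_ms * sample_rate_hz // 1000)


@dataclass(frozen=True)
class Segment:
    """One fixed-length labeled slice: the classifier's unit of input."""

    samples: np.ndarray
    label: int  # 1 = prominent, 0 = non-prominent
    recording_id: str
    start_ms: int
    sample_rate_hz: int
    padded: bool = False


@dataclass(frozen=True)
class SegmentDataset:
    segments: tuple[Segment, ...]
    config: SegmentationConfig

    @property
    def counts(self) -> dict[int, int]:
        return dict(Counter(s.label for s in self.segments))

    @property
    def n_prominent(self) -> int:
        return self.counts.get(1, 0)

    @property
    def n_non_prominent(self) -> int:
        return self.counts.get(0, 0)

    def __len__(self) -> int:
        return len(self.segments)

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Stack samples into (n, segment_samples) and labels into (n,)."""
        x = np.stack([s.samples for s in self.segments])
        y = np.array([s.label for s in self.segments], dtype=np.int64)
        return x, y


def prominent_starts(
    interval: AnnotationInterval, duration_ms: int, cfg: SegmentationConfig
) -> list[int]:
    """Segment start times (ms) covering one prominent interval.

    Short interval (length <= L): one start at floor((s+e-L)/2) — the
    interval center coincides with the segment center to within half a
    millisecond — clamped into [0, duration-L]. Long interval: hopped
    starts s, s+hop, ... while start+L <= e, then one end-aligned start
    e-L if the last hopped segment ends before e.
    """
    L = cfg.segment_length_ms
    s, e = interval.start_ms, interval.end_ms
    if e - s <= L:
        start = (s + e - L) // 2  # floor for negative values too
        start = max(0, min(start, duration_ms - L))
        if duration_ms < L:
            start = 0  # whole recording shorter than a segment: pad later
        return [start]
    starts = list(range(s, e - L + 1, cfg.hop_ms))
    if starts[-1] + L < e:
        starts.append(e - L)
    return starts


def gap_starts(gap_start_ms: int, gap_end_ms: int, cfg: SegmentationConfig) -> list[int]:
    """Hopped segment starts tiling a quiet gap; sub-length remainders dropped."""
    L = cfg.segment_length_ms
    if gap_end_ms - gap_start_ms < L:
        return []
    return list(range(gap_start_ms, gap_end_ms - L + 1, cfg.hop_ms))


def _cut(rec: AudioRecording, start_ms: int, cfg: SegmentationConfig,
         label: int, recording_id: str) -> Segment:
    n = cfg.n_samples(rec.sample_rate_hz)
    i0 = rec.ms_to_sample(start_ms)
    chunk = rec.samples[i0 : i0 + n]
    padded = False
    if chunk.shape[0] < n:
        # Recording shorter than one segment: pad symmetrically with zeros.
        deficit = n - chunk.shape[0]
        left = deficit // 2
        chunk = np.pad(chunk, (left, deficit - left))
        padded = True
    return Segment(samples=chunk, label=label, recording_id=recording_id,
                   start_ms=start_ms, sample_rate_hz=rec.sample_rate_hz,
                   padded=padded)


def extract_prominent(
    rec: AnnotatedRecording, cfg: SegmentationConfig = SegmentationConfig()
) -> list[Segment]:
    duration = rec.recording.duration_ms
    segments: list[Segment] = []
    for interval in rec.intervals:
        for start in prominent_starts(interval, duration, cfg):
            segments.append(_cut(rec.recording, start, cfg, 1, rec.recording_id))
    return segments


def extract_non_prominent(
    rec: AnnotatedRecording, cfg: SegmentationConfig = SegmentationConfig()
) -> list[Segment]:
    duration = rec.recording.duration_ms
    edges = [0] + [t for iv in rec.intervals for t in (iv.start_ms, iv.end_ms)] + [duration]
    segments: list[Segment] = []
    for gap_start, gap_end in zip(edges[::2], edges[1::2]):
        for start in gap_starts(gap_start, gap_end, cfg):
            segments.append(_cut(rec.recording, start, cfg, 0, rec.recording_id))
    return segments


def segment_recording(
    rec: AnnotatedRecording, cfg: SegmentationConfig = SegmentationConfig()
) -> list[Segment]:
    """All segments for one recording: prominent first, then non-prominent."""
    return extract_prominent(rec, cfg) + extract_non_prominent(rec, cfg)


def build_dataset(
    recs: Sequence[AnnotatedRecording],
    cfg: SegmentationConfig = SegmentationConfig(),
) -> SegmentDataset:
    """Concatenate segments over recordings in deterministic order."""
    rates = {r.recording.sample_rate_hz for r in recs}
    if len(rates) > 1:
        raise ValueError(f"mixed sample rates across recordings: {sorted(rates)}")
    segments: list[Segment] = []
    for rec in recs:
        segments.extend(segment_recording(rec, cfg))
    return SegmentDataset(segments=tuple(segments), config=cfg)


def write_segments(ds: SegmentDataset, out_dir: str | Path) -> pd.DataFrame:
    """Write one 16-bit WAV per segment under prominent/ and non_prominent/.

    Returns the manifest (segment_id, source, start_ms, label, padded, path).
    """
    out_dir = Path(out_dir)
    rows = []
    for i, seg in enumerate(ds.segments):
        sub = "prominent" if seg.label == 1 else "non_prominent"
        name = f"{seg.recording_id}_{seg.start_ms:08d}.wav"
        path = out_dir / sub / name
        write_wav(path, AudioRecording(seg.samples, seg.sample_rate_hz))
        rows.append(
            {"segment_id": i, "source": seg.recording_id, "start_ms": seg.start_ms,
             "label": sub, "padded": seg.padded, "path": str(path)}
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "segments.csv", index=False)
    return manifest
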