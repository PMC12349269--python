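"""Streaming prominent-sound detection over continuous audio.

Continuous recordings are scored with sliding windows that reuse the
training geometry (375 ms windows at the 175 ms training hop), so the
detector sees inputs statistically like the classifier's training
segments. Consecutive super-threshold windows whose spans overlap (or
whose gap is below ``min_gap_ms``) merge into one detection event — the
acoustic convention being that two prominent sounds are distinct only
when baseline sound intervenes. ``match_events`` scores detections
against ground-truth intervals with greedy one-to-one overlap matching.

Each window's score depends only on samples inside the window, so the
pipeline is causal with one-window latency.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotations import AnnotationInterval
from .audio import AudioRecording, FilterSpec, highpass
from .mfcc import MfccConfig, mfcc_batch
from .model import BowelSoundClassifier
from .segmentation import SegmentationConfig, gap_starts

__all__ = [
    "DetectionEvent",
    "sliding_scores",
    "merge_events",
    "match_events",
    "detect_events",
    "write_events_tsv",
]


@dataclass(frozen=True)
class DetectionEvent:
    """A merged run of positive windows."""

    start_ms: int
    end_ms: int
    peak_score: float
    n_windows: int

    def __post_init__(self) -> None:
        if self.end_ms <= self.start_ms:
            raise ValueError("event must have end > start")


def sliding_scores(
    rec: AudioRecording,
    model: BowelSoundClassifier,
    seg_cfg: SegmentationConfig = SegmentationConfig(),
    mfcc_cfg: MfccConfig = MfccConfig(),
    filter_spec: FilterSpec | None = FilterSpec(),
    batch_size: int = 512,
    normalize: bool = True,
) -> list[tuple[int, float]]:
    """Score every sliding window of the recording, in causal order.

    Window starts follow the same enumeration as gap segmentation over an
    annotation-free recording: starts 0, hop, 2*hop, ... while
    start + L <= duration. Returns (start_ms, probability) pairs.

    ``normalize`` applies the same per-recording peak gain used when
    building training segments; it is a one-off gain calibration, separate
    from the scoring chain, which reads nothing beyond each window.
    """
    if filter_spec is not None:
        rec = highpass(rec, filter_spec)
    peak = float(np.max(np.abs(rec.samples))) if normalize and rec.n_samples else 0.0
    samples = rec.samples / peak if peak > 0 else rec.samples
    starts = gap_starts(0, rec.duration_ms, seg_cfg)
    if not starts:
        raise ValueError(
            f"recording of {rec.duration_ms} ms is shorter than one "
            f"{seg_cfg.segment_length_ms} ms window"
        )
    n = seg_cfg.n_samples(rec.sample_rate_hz)
    idx0 = np.array([int(t * rec.sample_rate_hz // 1000) for t in starts])
    windows = samples[idx0[:, None] + np.arange(n)[None, :]]
    scores = []
    for i in range(0, windows.shape[0], batch_size):
        feats = mfcc_batch(windows[i : i + batch_size], rec.sample_rate_hz, mfcc_cfg)
        scores.append(model.predict_proba(feats))
    probs = np.concatenate(scores)
    return list(zip(starts, probs.tolist()))


def merge_events(
    scores: Sequence[tuple[int, float]],
    threshold: float = 0.5,
    min_gap_ms: int = 0,
    segment_length_ms: int = 375,
) -> list[DetectionEvent]:
    """Merge consecutive super-threshold windows into detection events.

    Window spans [start, start + L); spans that overlap, or are separated
    by less than ``min_gap_ms``, join one event covering their union with
    ``peak_score`` the maximum member score.
    """
    events: list[DetectionEvent] = []
    current: dict | None = None
    for start, score in scores:
        if score < threshold:
            continue
        end = start + segment_length_ms
        overlaps = current is not None and start < current["end"]
        within_gap = current is not None and start - current["end"] < min_gap_ms
        if overlaps or within_gap:
            current["end"] = max(current["end"], end)
            current["peak"] = max(current["peak"], score)
            current["n"] += 1
        else:
            if current is not None:
                events.append(DetectionEvent(current["start"], current["end"],
                                             current["peak"], current["n"]))
            current = {"start": start, "end": end, "peak": score, "n": 1}
    if current is not None:
        events.append(DetectionEvent(current["start"], current["end"],
                                     current["peak"], current["n"]))
    return events


def match_events(
    detected: Sequence[DetectionEvent],
    truth: Sequence[AnnotationInterval],
    tolerance_ms: int = 0,
) -> dict[str, float]:
    """Greedy one-to-one matching of detections against truth intervals.

    A detection matches a truth interval when their spans overlap after
    dilating the truth interval by ``tolerance_ms`` on each side; each
    truth interval and each detection participates in at most one match.
    Returns event-level precision, recall and F1; an undefined precision
    (no detections) is reported as 0 with the ``undefined_precision`` flag.
    """
    used = [False] * len(truth)
    tp = 0
    for event in sorted(detected, key=lambda e: e.start_ms):
        for i, iv in enumerate(truth):
            if used[i]:
                continue
            if (event.start_ms < iv.end_ms + tolerance_ms
                    and event.end_ms > iv.start_ms - tolerance_ms):
                used[i] = True
                tp += 1
                break
    n_det, n_truth = len(detected), len(truth)
    precision = tp / n_det if n_det else 0.0
    recall = tp / n_truth if n_truth else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return {
        "precision": precision, "recall": recall, "f1": f1,
        "tp": tp, "n_detected": n_det, "n_truth": n_truth,
        "undefined_precision": n_det == 0,
    }


def detect_events(
    rec: AudioRecording,
    model: BowelSoundClassifier,
    threshold: float = 0.5,
    min_gap_ms: int = 0,
    seg_cfg: SegmentationConfig = SegmentationConfig(),
    mfcc_cfg: MfccConfig = MfccConfig(),
) -> list[DetectionEvent]:
    """Convenience wrapper: sliding_scores then merge_events."""
    scores = sliding_scores(rec, model, seg_cfg, mfcc_cfg)
    return merge_events(scores, threshold, min_gap_ms, seg_cfg.segment_length_ms)


def write_events_tsv(path: str | Path, events: Sequence[DetectionEvent]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("start_ms\tend_ms\tpeak_score\tn_windows\n")
        for ev in events:
            fh.write(f"{ev.start_ms}\t{ev.end_ms}\t{ev.peak_score:.6f}\t{ev.n_windows}\n")
    return path
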