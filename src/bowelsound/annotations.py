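"""Reading and normalizing bowel-sound interval annotations.

Annotators delimit the onset and end of each *prominent* bowel sound (one
clearly audible without amplification). Sounds audible only under heavy
amplification — "obscure"/baseline sounds — are the background class: two
prominent sounds are distinct only if separated by a stretch of baseline,
so overlapping or abutting prominent intervals collapse into one.

Two dialects are supported: the Label Studio JSON export produced by the
annotation tool (region offsets in seconds) and a plain TSV
(``file  start_ms  end_ms  label``) convenient for fixtures and scripts.
The canonical internal unit is the integer millisecond, which keeps the
375/200 ms segmentation arithmetic exact.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .audio import AudioRecording

__all__ = [
    "AnnotationInterval",
    "AnnotatedRecording",
    "read_intervals",
    "write_intervals_tsv",
    "write_intervals_labelstudio",
    "normalize_intervals",
]

Label = Literal["prominent", "obscure"]

_LABEL_ALIASES = {
    "prominent": "prominent",
    "distinct": "prominent",
    "audible": "prominent",
    "obscure": "obscure",
    "baseline": "obscure",
    "inaudible": "obscure",
}


@dataclass(frozen=True, order=True)
class AnnotationInterval:
    """A labeled time span, in integer milliseconds, within one recording."""

    start_ms: int
    end_ms: int
    label: Label = "prominent"

    def __post_init__(self) -> None:
        if self.start_ms < 0:
            raise ValueError(f"start_ms must be >= 0, got {self.start_ms}")
        if self.end_ms <= self.start_ms:
            raise ValueError(
                f"interval must have end > start, got [{self.start_ms}, {self.end_ms}]"
            )
        if self.label not in ("prominent", "obscure"):
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def duration_ms(self) -> int:
        return self.end_ms - self.start_ms


@dataclass(frozen=True)
class AnnotatedRecording:
    """A recording bound to its normalized prominent intervals."""

    recording: AudioRecording
    intervals: tuple[AnnotationInterval, ...]
    recording_id: str = "recording"

    def __post_init__(self) -> None:
        normalized = normalize_intervals(self.intervals)
        for iv in normalized:
            if iv.end_ms > self.recording.duration_ms:
                raise ValueError(
                    f"interval [{iv.start_ms}, {iv.end_ms}] exceeds recording "
                    f"duration {self.recording.duration_ms} ms"
                )
        object.__setattr__(self, "intervals", normalized)


def _seconds_to_ms(t_s: float) -> int:
    # Round half up; a 1e-9 guard absorbs binary representation error on
    # values like 1.0005 s that sit exactly on the half-millisecond.
    return int(math.floor(t_s * 1000.0 + 0.5 + 1e-9))


def _canonical_label(raw: str) -> Label:
    key = raw.strip().lower()
    if key not in _LABEL_ALIASES:
        raise ValueError(f"unknown annotation label: {raw!r}")
    return _LABEL_ALIASES[key]  # type: ignore[return-value]


def read_intervals(
    path: str | Path,
    dialect: Literal["labelstudio_json", "tsv"],
    recording_file: str | None = None,
) -> list[AnnotationInterval]:
    """Read annotation intervals from ``path`` under the given dialect.

    For TSV, rows whose ``file`` column differs from ``recording_file`` are
    skipped when a filter is given. Label Studio offsets (seconds) are
    converted to integer ms, rounding to nearest.
    """
    path = Path(path)
    if dialect == "tsv":
        return _read_tsv(path, recording_file)
    if dialect == "labelstudio_json":
        return _read_labelstudio(path, recording_file)
    raise ValueError(f"unknown dialect: {dialect}")


def _read_tsv(path: Path, recording_file: str | None) -> list[AnnotationInterval]:
    intervals: list[AnnotationInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[:1] == ["file"]:
                continue  # header
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 tab-separated fields")
            file_col, start_s, end_s, label_s = parts
            if recording_file is not None and file_col != recording_file:
                continue
            intervals.append(
                AnnotationInterval(int(start_s), int(end_s), _canonical_label(label_s))
            )
    return intervals


def _read_labelstudio(path: Path, recording_file: str | None) -> list[AnnotationInterval]:
    """Parse a Label Studio JSON export (list of tasks with labeled regions)."""
    with open(path) as fh:
        tasks = json.load(fh)
    if isinstance(tasks, dict):
        tasks = [tasks]
    intervals: list[AnnotationInterval] = []
    for task in tasks:
        audio = str(task.get("data", {}).get("audio", ""))
        if recording_file is not None and Path(audio).name != Path(recording_file).name:
            continue
        for annotation in task.get("annotations", []):
            for region in annotation.get("result", []):
                value = region.get("value", {})
                if "start" not in value or "end" not in value:
                    continue
                labels = value.get("labels", ["prominent"])
                intervals.append(
                    AnnotationInterval(
                        _seconds_to_ms(float(value["start"])),
                        _seconds_to_ms(float(value["end"])),
                        _canonical_label(labels[0]),
                    )
                )
    return intervals


def write_intervals_tsv(
    path: str | Path, intervals: Iterable[AnnotationInterval], file_name: str
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("file\tstart_ms\tend_ms\tlabel\n")
        for iv in intervals:
            fh.write(f"{file_name}\t{iv.start_ms}\t{iv.end_ms}\t{iv.label}\n")
    return path


def write_intervals_labelstudio(
    path: str | Path, intervals: Iterable[AnnotationInterval], file_name: str
) -> Path:
    """Write intervals as a minimal Label Studio-style JSON export."""
    results = [
        {
            "value": {
                "start": iv.start_ms / 1000.0,
                "end": iv.end_ms / 1000.0,
                "labels": [iv.label],
            },
            "type": "labels",
        }
        for iv in intervals
    ]
    task = {"data": {"audio": file_name}, "annotations": [{"result": results}]}
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump([task], fh, indent=1)
    return path


def normalize_intervals(
    intervals: Sequence[AnnotationInterval],
) -> tuple[AnnotationInterval, ...]:
    """Sort and merge prominent intervals; drop explicit obscure spans.

    Overlapping or abutting (zero-gap) prominent intervals merge into one,
    because prominent sounds are distinct only when baseline sound
    intervenes. Obscure annotations are dropped: everything outside the
    prominent union is background by construction. Idempotent.
    """
    prominent = sorted(iv for iv in intervals if iv.label == "prominent")
    merged: list[AnnotationInterval] = []
    for iv in prominent:
        if merged and iv.start_ms <= merged[-1].end_ms:
            last = merged[-1]
            if iv.end_ms > last.end_ms:
                merged[-1] = AnnotationInterval(last.start_ms, iv.end_ms, "prominent")
        else:
            merged.append(iv)
    return tuple(merged)
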