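"""End-to-end pipeline: simulate -> segment -> featurize -> train ->
evaluate -> detect, with every stage's artifacts written to a run
directory and a machine-readable summary for auditability.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from .annotations import AnnotatedRecording, read_intervals
from .audio import AudioRecording, FilterSpec, highpass, read_wav
from .detect import detect_events, match_events
from .mfcc import MfccConfig, mfcc_batch
from .model import BowelSoundClassifier, ModelConfig
from .segmentation import SegmentationConfig, build_dataset
from .synthdata import SynthConfig, generate_corpus, generate_recording, realized_snr
from .train_eval import TrainConfig, evaluate, split_indices, train

logger = logging.getLogger("bowelsound")

__all__ = ["RunConfig", "run_pipeline", "load_annotated_corpus",
           "preprocess_recording"]


@dataclass(frozen=True)
class RunConfig:
    out_dir: str = "run"
    n_recordings: int = 8
    n_test_recordings: int = 2  # extra held-out recordings for the detector
    synth: SynthConfig = field(default_factory=SynthConfig)
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    mfcc: MfccConfig = field(default_factory=MfccConfig)
    model: ModelConfig | None = None  # None: reduced width sized to the features
    training: TrainConfig = field(default_factory=TrainConfig)
    detection_threshold: float = 0.5
    match_tolerance_ms: int = 100
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(_serializable(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _serializable(obj) -> dict:
    out = asdict(obj) if hasattr(obj, "__dataclass_fields__") else obj
    return json.loads(json.dumps(out, default=str))


def preprocess_recording(rec: AudioRecording, spec: FilterSpec) -> AudioRecording:
    """High-pass filter then peak-normalize to float [-1, 1]."""
    filtered = highpass(rec, spec)
    peak = float(np.max(np.abs(filtered.samples)))
    samples = filtered.samples / peak if peak > 0 else filtered.samples
    return AudioRecording(samples=samples, sample_rate_hz=rec.sample_rate_hz)


def load_annotated_corpus(
    corpus_dir: str | Path, filter_spec: FilterSpec | None = FilterSpec()
) -> list[AnnotatedRecording]:
    """Read every WAV with its sibling TSV annotations from a directory."""
    corpus_dir = Path(corpus_dir)
    recs = []
    for wav in sorted(corpus_dir.glob("*.wav")):
        rec = read_wav(wav)
        if filter_spec is not None:
            rec = preprocess_recording(rec, filter_spec)
        intervals = read_intervals(wav.with_suffix(".tsv"), "tsv",
                                   recording_file=wav.name)
        recs.append(AnnotatedRecording(recording=rec, intervals=tuple(intervals),
                                       recording_id=wav.stem))
    return recs


def run_pipeline(cfg: RunConfig = RunConfig()) -> dict:
    """Execute all stages, returning (and writing) the run summary."""
    t0 = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": _serializable(cfg), "config_hash": cfg.config_hash(),
                     "stages": {}}

    def stage(name):
        logger.info("stage %s", name)
        summary["stages"][name] = {"t_start_s": round(time.time() - t0, 2)}
        return summary["stages"][name]

    # --- simulate ---------------------------------------------------------
    info = stage("simulate")
    synth_cfg = replace(cfg.synth, seed=cfg.seed)
    corpus_dir = out / "corpus"
    manifest = generate_corpus(cfg.n_recordings, synth_cfg, corpus_dir)
    info["n_recordings"] = int(len(manifest))
    info["n_events_total"] = int(manifest["n_events"].sum())

    # --- segment ----------------------------------------------------------
    info = stage("segment")
    recs = load_annotated_corpus(corpus_dir, cfg.filter_spec)
    ds = build_dataset(recs, cfg.segmentation)
    info["n_segments"] = len(ds)
    info["n_prominent"] = ds.n_prominent
    info["n_non_prominent"] = ds.n_non_prominent
    info["prominent_fraction"] = ds.n_prominent / max(1, len(ds))

    # --- featurize --------------------------------------------------------
    info = stage("featurize")
    x_raw, y = ds.to_arrays()
    sr = recs[0].recording.sample_rate_hz
    feats = mfcc_batch(x_raw, sr, cfg.mfcc)
    np.savez(out / "features.npz", features=feats, labels=y)
    info["feature_shape"] = list(feats.shape)

    # --- train ------------------------------------------------------------
    info = stage("train")
    train_cfg = replace(cfg.training, seed=cfg.seed)
    tr, va, te = split_indices(y, train_cfg,
                               groups=[s.recording_id for s in ds.segments])
    input_shape = (feats.shape[1], feats.shape[2])
    model_cfg = cfg.model or ModelConfig.reduced(seed=cfg.seed,
                                                 input_shape=input_shape)
    model = BowelSoundClassifier(model_cfg)
    history = train(model, feats[tr], y[tr], feats[va], y[va], train_cfg,
                    history_path=out / "history.npz")
    model.save_checkpoint(out / "model.npz")
    info["n_train"] = int(tr.size)
    info["stopped_epoch"] = history.stopped_epoch
    info["best_epoch"] = history.best_epoch
    info["n_parameters"] = model.n_parameters()

    # --- evaluate ---------------------------------------------------------
    info = stage("evaluate")
    report = evaluate(model, feats[te], y[te])
    info.update(report.to_dict())
    with open(out / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=1)

    # --- detect (held-out recordings never seen in training) --------------
    info = stage("detect")
    event_stats = []
    snrs = []
    for i in range(cfg.n_test_recordings):
        test_cfg = replace(synth_cfg, seed=cfg.seed + 10_000 + i)
        synth = generate_recording(test_cfg)
        if synth.intervals:
            snrs.append(realized_snr(synth))
        events = detect_events(synth.recording, model, cfg.detection_threshold,
                               seg_cfg=cfg.segmentation, mfcc_cfg=cfg.mfcc)
        event_stats.append(match_events(events, synth.intervals,
                                        cfg.match_tolerance_ms))
    tp = sum(s["tp"] for s in event_stats)
    n_det = sum(s["n_detected"] for s in event_stats)
    n_truth = sum(s["n_truth"] for s in event_stats)
    precision = tp / n_det if n_det else 0.0
    recall = tp / n_truth if n_truth else 0.0
    info["event_precision"] = precision
    info["event_recall"] = recall
    info["event_f1"] = (2 * precision * recall / (precision + recall)
                        if precision + recall else 0.0)
    info["realized_snr_db"] = float(np.mean(snrs)) if snrs else None

    summary["elapsed_s"] = round(time.time() - t0, 2)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    return summary
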