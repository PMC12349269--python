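"""Split protocol, early stopping, checkpointing, and metric identities."""

import numpy as np
import pytest

from bowelsound.model import BowelSoundClassifier, ModelConfig
from bowelsound.train_eval import (
    EarlyStopping,
    MetricsHistory,
    ReduceLROnPlateau,
    TrainConfig,
    evaluate,
    fit_loop,
    report_from_scores,
    split_indices,
    train,
)


# ---------------------------------------------------------------------------
# AUC oracle: concordant-pair fraction with ties counted one half

def pairwise_auc(labels, scores):
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestSplit:
    def test_exact_stratified_proportions(self):
        y = np.array([1] * 150 + [0] * 850)
        tr, va, te = split_indices(y, TrainConfig(seed=1))
        assert (tr.size, va.size, te.size) == (600, 200, 200)
        assert (y[tr].sum(), y[va].sum(), y[te].sum()) == (90, 30, 30)
        # disjoint and exhaustive
        assert np.array_equal(np.sort(np.concatenate([tr, va, te])), np.arange(1000))

    def test_same_seed_reproduces_partition(self):
        y = np.array([0, 1] * 50)
        a = split_indices(y, TrainConfig(seed=9))
        b = split_indices(y, TrainConfig(seed=9))
        for pa, pb in zip(a, b):
            assert np.array_equal(pa, pb)

    def test_recording_level_split_keeps_groups_intact(self):
        y = np.tile([0, 0, 0, 1], 25)  # 100 segments
        groups = np.repeat([f"rec{i}" for i in range(10)], 10)
        cfg = TrainConfig(seed=2, split_unit="recording")
        tr, va, te = split_indices(y, cfg, groups=groups)
        parts = {g: set() for g in set(groups)}
        for name, idx in (("tr", tr), ("va", va), ("te", te)):
            for g in groups[idx]:
                parts[g].add(name)
        assert all(len(p) == 1 for p in parts.values())

    def test_class_missing_from_partition_rejected(self):
        y = np.array([0] * 98 + [1] * 2)  # 20% of 2 rounds to 0 per partition
        with pytest.raises(ValueError, match="class missing"):
            split_indices(y, TrainConfig(seed=0))


class TestEarlyStoppingProtocol:
    def test_patience_10_stops_at_epoch_12_with_epoch_2_weights(self):
        """Validation loss [1.0, 0.9, 0.9, ...]: last improvement at epoch 2,
        ten stale epochs later training halts at epoch 12."""
        losses = {1: 1.0, 2: 0.9}

        def run_epoch(epoch):
            vl = losses.get(epoch, 0.9)
            return {"loss": vl, "val_loss": vl}, {"epoch": np.array(epoch)}

        best, history = fit_loop(run_epoch, max_epochs=150, patience=10)
        assert history.stopped_epoch == 12
        assert history.best_epoch == 2
        assert best["epoch"] == 2

    def test_runs_to_max_epochs_when_improving(self):
        def run_epoch(epoch):
            return {"val_loss": 1.0 / epoch}, {"epoch": np.array(epoch)}

        best, history = fit_loop(run_epoch, max_epochs=7, patience=10)
        assert history.stopped_epoch == 7
        assert best["epoch"] == 7

    def test_early_stopping_counter_resets_on_improvement(self):
        stopper = EarlyStopping(patience=3)
        seq = [1.0, 0.9, 0.95, 0.95, 0.8, 0.9, 0.9, 0.9]
        stops = [stopper.update(v, i + 1) for i, v in enumerate(seq)]
        assert stops == [False] * 7 + [True]
        assert stopper.best_epoch == 5

    def test_reduce_lr_on_plateau_halves_after_patience(self):
        sched = ReduceLROnPlateau(lr=0.001, factor=0.5, patience=2, min_lr=1e-5)
        lrs = [sched.update(v) for v in [1.0, 0.9, 0.95, 0.95, 0.95, 0.95]]
        assert lrs == [0.001, 0.001, 0.001, 0.0005, 0.0005, 0.00025]

    def test_reduce_lr_respects_floor(self):
        sched = ReduceLROnPlateau(lr=4e-5, factor=0.5, patience=1, min_lr=1e-5)
        for _ in range(10):
            lr = sched.update(1.0)
        assert lr == 1e-5


class TestMetrics:
    def test_auc_hand_case(self):
        report = report_from_scores([0, 0, 1, 1], [0.1, 0.4, 0.35, 0.8])
        assert report.auc == pytest.approx(0.75)

    def test_confusion_hand_case(self):
        report = report_from_scores([1, 1, 0, 0], [0.9, 0.2, 0.4, 0.6], 0.5)
        assert (report.tp, report.fn, report.tn, report.fp) == (1, 1, 1, 1)
        assert report.accuracy == report.precision == report.recall == 0.5

    def test_perfect_separation(self):
        report = report_from_scores([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert report.auc == 1.0 and report.f1 == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            report_from_scores([1, 1, 1], [0.2, 0.5, 0.9])

    def test_auc_equals_pairwise_concordance_with_ties(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 200))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            report = report_from_scores(y, scores)
            assert report.auc == pytest.approx(pairwise_auc(y, scores), abs=1e-12)

    def test_confusion_identities_on_random_evaluations(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 300))
            y = np.concatenate([[0, 1], rng.integers(0, 2, n)])
            s = rng.random(n + 2)
            r = report_from_scores(y, s)
            total = r.tp + r.fp + r.fn + r.tn
            assert total == n + 2
            assert r.accuracy == pytest.approx((r.tp + r.tn) / total)
            if r.tp + r.fp:
                assert r.precision == pytest.approx(r.tp / (r.tp + r.fp))
            if r.tp + r.fn:
                assert r.recall == pytest.approx(r.tp / (r.tp + r.fn))
            if r.precision + r.recall:
                assert r.f1 == pytest.approx(
                    2 * r.precision * r.recall / (r.precision + r.recall))

    def test_random_scores_on_balanced_labels_near_half(self, rng):
        aucs = []
        for _ in range(1000):
            y = np.array([0, 1] * 10)
            s = rng.random(20)
            aucs.append(report_from_scores(y, s).auc)
        assert 0.45 <= np.mean(aucs) <= 0.55


def _toy_problem(n=160, seed=0):
    """Linearly separable toy features: label carried by the channel mean."""
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2), dtype=float)
    x = rng.standard_normal((n, 7, 4)) * 0.3 + y[:, None, None] * 1.5
    return x, y


class TestTraining:
    def test_loss_decreases_on_separable_toy(self, tiny_model_config):
        x, y = _toy_problem()
        model = BowelSoundClassifier(tiny_model_config)
        cfg = TrainConfig(max_epochs=5, batch_size=32, seed=0)
        history = train(model, x, y, x, y, cfg)
        assert all(a > b for a, b in zip(history.loss, history.loss[1:]))

    def test_seeded_runs_bit_identical(self, tiny_model_config):
        x, y = _toy_problem()
        cfg = TrainConfig(max_epochs=3, batch_size=32, seed=5)
        histories = []
        for _ in range(2):
            model = BowelSoundClassifier(tiny_model_config)
            histories.append(train(model, x, y, x, y, cfg))
        assert histories[0].loss == histories[1].loss
        assert histories[0].val_loss == histories[1].val_loss

    def test_returned_weights_are_checkpointed_best(self, tiny_model_config):
        x, y = _toy_problem(n=64)
        model = BowelSoundClassifier(tiny_model_config)
        cfg = TrainConfig(max_epochs=4, batch_size=16, seed=1)
        history = train(model, x, y, x, y, cfg)
        best_idx = int(np.argmin(history.val_loss)) + 1
        assert history.best_epoch == best_idx

    def test_history_save_load_roundtrip(self, tmp_path, tiny_model_config):
        x, y = _toy_problem(n=64)
        model = BowelSoundClassifier(tiny_model_config)
        history = train(model, x, y, x, y,
                        TrainConfig(max_epochs=2, batch_size=32, seed=0),
                        history_path=tmp_path / "h.npz")
        back = MetricsHistory.load(tmp_path / "h.npz")
        assert back.loss == pytest.approx(history.loss)
        assert back.stopped_epoch == history.stopped_epoch

    def test_evaluate_on_trained_toy_model(self, tiny_model_config):
        x, y = _toy_problem()
        model = BowelSoundClassifier(tiny_model_config)
        train(model, x, y, x, y, TrainConfig(max_epochs=8, batch_size=32, seed=0))
        report = evaluate(model, x, y)
        assert report.auc > 0.95


class TestSweep:
    def test_grid_rows_and_f1_consistency(self, tmp_path):
        from bowelsound.annotations import AnnotatedRecording
        from bowelsound.mfcc import MfccConfig
        from bowelsound.synthdata import SynthConfig, generate_recording
        from bowelsound.train_eval import sweep

        recs = []
        for seed in (1, 2):
            synth = generate_recording(SynthConfig(
                duration_ms=12_000, sample_rate_hz=8000,
                event_rate_per_min=40.0, burst_duration_range_ms=(60, 400),
                seed=seed))
            recs.append(AnnotatedRecording(synth.recording, synth.intervals,
                                           recording_id=f"r{seed}"))

        def factory(shape):
            return ModelConfig(conv_filters=4, n_blocks=1, n_heads=2,
                               d_model=8, ffn_dim=8, dense_hidden=4,
                               input_shape=shape, seed=0)

        table = sweep(recs, [0.375, 0.25], [32, 64],
                      model_factory=factory,
                      train_cfg=TrainConfig(max_epochs=1, batch_size=32, seed=0),
                      mfcc_cfg=MfccConfig(fmax_hz=3500),
                      out_csv=tmp_path / "sweep.csv")
        assert len(table) == 4
        assert set(table.columns) >= {"segment_size_s", "batch_size", "accuracy",
                                      "auc", "precision", "recall", "f1"}
        for _, row in table.iterrows():
            p, r = row["precision"], row["recall"]
            want = 2 * p * r / (p + r) if p + r else 0.0
            assert row["f1"] == pytest.approx(want)
        assert (tmp_path / "sweep.csv").exists()


class TestConfigValidation:
    def test_bad_split_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(split=(0.5, 0.2, 0.2))

    def test_bad_patience_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(early_stop_patience=0)
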