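"""Fold-wise training and cross-validation orchestration.

Training uses Adam (conventional moments, no weight decay), binary
cross-entropy on logits, and a piecewise learning-rate schedule: constant at
the initial rate until ``decay_start_epoch``, linearly decaying to
``final_lr_factor`` x initial between ``decay_start_epoch`` and
``decay_end_epoch``, constant afterwards.

Each fold trains only on its /fold{i}/train split; the 2-of-7 waveform
augmentation (when enabled) touches training waveforms only, and the fold's
test split is scored once, untouched, at the final epoch. ``run_cv`` repeats
this over all folds and summarizes per-metric means, 95% CIs and maxima.

When augmentation is off, mel spectrograms are precomputed once per pair;
with augmentation on, waveforms are re-augmented and re-transformed every
epoch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .augment import AugmentConfig, compose_random_two
from .audio import decode_clip
from .dataset import PairedSample, read_store, store_attrs, store_folds
from .evaluation import MetricsReport, MetricSummary, classify, compute_report, summarize_folds
from .features import MelConfig, melspectrogram
from .model import ModelConfig, PairedDetector, build_detector
from .nn import Adam, bce_with_logits, sigmoid

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings.

    The clinical-scale grid is lr0 in {5e-5, 3e-5} x batch size in {16, 32}
    at 150 epochs; the desk-scale default (small randomly initialized width,
    synthetic cohorts) uses a larger rate and far fewer epochs.
    """

    lr0: float = 1e-3
    batch_size: int = 16
    epochs: int = 15
    decay_start_epoch: int = 100
    decay_end_epoch: int = 105
    final_lr_factor: float = 0.01
    decision_threshold: float = 0.5
    seed: int = 0
    augment: Optional[AugmentConfig] = None

    def __post_init__(self) -> None:
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")
        if not (0 < self.final_lr_factor <= 1.0):
            raise ValueError("final_lr_factor must be in (0, 1]")
        if not (0.0 < self.decision_threshold < 1.0):
            raise ValueError("decision_threshold must be in (0, 1)")
        if self.decay_start_epoch >= self.decay_end_epoch:
            raise ValueError("decay_start_epoch must be < decay_end_epoch")


def lr_at_epoch(e: int, cfg: TrainConfig) -> float:
    """Closed-form schedule: constant -> linear decay -> constant floor."""
    if e < 0 or e > cfg.epochs:
        raise ValueError(f"epoch {e} outside [0, {cfg.epochs}]")
    if e <= cfg.decay_start_epoch:
        return cfg.lr0
    if e >= cfg.decay_end_epoch:
        return cfg.lr0 * cfg.final_lr_factor
    span = cfg.decay_end_epoch - cfg.decay_start_epoch
    frac = (e - cfg.decay_start_epoch) / span
    return cfg.lr0 * (1.0 - (1.0 - cfg.final_lr_factor) * frac)


def _pair_waveforms(
    pairs: Sequence[PairedSample], target_rate: int
) -> tuple[list[np.ndarray], list[np.ndarray], np.ndarray]:
    pre = [decode_clip(p.pre, target_rate=target_rate) for p in pairs]
    post = [decode_clip(p.post, target_rate=target_rate) for p in pairs]
    labels = np.array([p.label for p in pairs], dtype=np.float64)
    return pre, post, labels


def _mel_batch(waves: Sequence[np.ndarray], mel_cfg: MelConfig) -> np.ndarray:
    mels = [melspectrogram(w, mel_cfg).values for w in waves]
    return np.stack(mels)[:, None, :, :]


def train_fold(
    store: str | Path,
    fold: int,
    model_cfg: Optional[ModelConfig] = None,
    train_cfg: Optional[TrainConfig] = None,
    mel_cfg: Optional[MelConfig] = None,
) -> tuple[PairedDetector, list[dict], MetricsReport]:
    """Train one fold from the HDF5 store; return detector, per-epoch
    history, and the final-epoch test-split report."""
    model_cfg = model_cfg or ModelConfig()
    train_cfg = train_cfg or TrainConfig()
    attrs = store_attrs(store)
    rate = int(attrs["target_rate"])
    mel_cfg = mel_cfg or MelConfig(sample_rate=rate)

    train_pairs = read_store(store, fold, "train")
    test_pairs = read_store(store, fold, "test")
    if not train_pairs or not test_pairs:
        raise ValueError(f"fold {fold} has an empty split")
    train_subjects = {p.subject_id for p in train_pairs}
    test_subjects = {p.subject_id for p in test_pairs}
    if train_subjects & test_subjects:
        raise ValueError("subject leakage between train and test splits")

    pre_w, post_w, y_train = _pair_waveforms(train_pairs, rate)
    pre_t, post_t, y_test = _pair_waveforms(test_pairs, rate)
    x_test_pre = _mel_batch(pre_t, mel_cfg)
    x_test_post = _mel_batch(post_t, mel_cfg)
    if train_cfg.augment is None:
        x_train_pre = _mel_batch(pre_w, mel_cfg)
        x_train_post = _mel_batch(post_w, mel_cfg)

    detector = build_detector(model_cfg, seed=train_cfg.seed + 7919 * fold)
    adam = Adam(list(detector.param_items()), lr=train_cfg.lr0)
    rng = np.random.default_rng([train_cfg.seed, fold])

    n = len(train_pairs)
    bs = train_cfg.batch_size
    history: list[dict] = []
    for epoch in range(train_cfg.epochs):
        adam.lr = lr_at_epoch(epoch, train_cfg)
        order = rng.permutation(n)
        detector.training = True
        losses, correct = [], 0
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            if train_cfg.augment is not None:
                xb_pre = _mel_batch(
                    [compose_random_two(pre_w[i], train_cfg.augment, rng) for i in idx],
                    mel_cfg,
                )
                xb_post = _mel_batch(
                    [compose_random_two(post_w[i], train_cfg.augment, rng) for i in idx],
                    mel_cfg,
                )
            else:
                xb_pre, xb_post = x_train_pre[idx], x_train_post[idx]
            yb = y_train[idx]
            logits = detector.forward(xb_pre, xb_post)
            loss, dlogits = bce_with_logits(logits, yb)
            detector.backward(dlogits)
            adam.step()
            losses.append(loss)
            preds = [classify(p, train_cfg.decision_threshold) for p in sigmoid(logits)]
            correct += int(np.sum(np.asarray(preds) == yb))
        detector.training = False
        test_logits = detector.forward(x_test_pre, x_test_post)
        test_loss, _ = bce_with_logits(test_logits, y_test)
        history.append(
            {
                "epoch": epoch,
                "lr": adam.lr,
                "train_loss": float(np.mean(losses)),
                "train_accuracy": 100.0 * correct / n,
                "test_loss": test_loss,
            }
        )

    detector.training = False
    probs = detector.predict_proba(detector.forward(x_test_pre, x_test_post))
    report = compute_report(
        y_test.astype(int),
        probs,
        threshold=train_cfg.decision_threshold,
        train_accuracy=history[-1]["train_accuracy"],
        train_loss=history[-1]["train_loss"],
    )
    return detector, history, report


def run_cv(
    store: str | Path,
    model_cfg: Optional[ModelConfig] = None,
    train_cfg: Optional[TrainConfig] = None,
    mel_cfg: Optional[MelConfig] = None,
) -> tuple[list[MetricsReport], dict[str, MetricSummary]]:
    """Train and score every fold; return per-fold reports and the summary."""
    k = store_folds(store)
    reports = []
    for fold in range(k):
        _, _, report = train_fold(store, fold, model_cfg, train_cfg, mel_cfg)
        logger.info("fold %d: AUC %.4f acc %.2f", fold, report.auc, report.accuracy)
        reports.append(report)
    return reports, summarize_folds(reports)
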