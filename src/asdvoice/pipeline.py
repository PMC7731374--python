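"""Evaluation protocol: splits, cross-validation, decision rule, metrics.

Utterances are the unit of evaluation.  A held-out test set (10% of
utterances, stratified over vocalization types) is carved out first; the
remainder is divided into five stratified folds for cross-validation.
Splitting is always at utterance level, so windows of one utterance never
straddle partitions.  Window-level softmax outputs are converted to class
indices and an utterance is called ASD when the mean class index over its
windows strictly exceeds 0.5 (a tie at exactly 0.5 is TD).  Performance is
summarized by a 2x2 confusion matrix (ASD positive) and accuracy,
precision, recall, F1, UAR (unweighted average recall: mean of per-class
recalls, robust to class imbalance) and WAR (weighted average recall,
identical to accuracy).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import autoencoder as ae_mod
from . import classifiers as clf_mod
from . import features as feat_mod
from .features import UtteranceFeatures
from .nn.train import TrainConfig

MODEL_CHOICES = ("svm", "blstm88", "blstm54", "joint")


@dataclass
class SplitPlan:
    """Utterance-level test/fold assignment, stratified by vocal_label."""

    test_utterances: list[str]
    folds: list[list[str]]
    seed: int

    def to_dict(self) -> dict:
        return {"test_utterances": self.test_utterances,
                "folds": self.folds, "seed": self.seed}


@dataclass
class ConfusionMatrix2x2:
    """Utterance-level counts; ASD is the positive class."""

    tp: int  # actual ASD, predicted ASD
    fn: int  # actual ASD, predicted TD
    fp: int  # actual TD, predicted ASD
    tn: int  # actual TD, predicted TD

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    uar: float
    war: float
    undefined: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def make_split_plan(utterances: list[UtteranceFeatures],
                    test_fraction: float = 0.1, n_folds: int = 5,
                    seed: int = 0) -> SplitPlan:
    """Stratified utterance-level test split plus cross-validation folds.

    Within each vocal_label stratum the shuffled utterances are allocated
    proportionally to the test set (largest-remainder rounding so the test
    total matches round(test_fraction * n)) and the rest are dealt
    round-robin into folds, with the starting fold rotated per stratum so
    fold sizes stay balanced overall.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    rng = np.random.default_rng(seed)
    strata: dict[int, list[str]] = {}
    for u in utterances:
        strata.setdefault(u.vocal_label, []).append(u.utterance_id)
    n_total = len(utterances)
    target_test = int(round(test_fraction * n_total))

    shuffled = {lab: [ids[i] for i in rng.permutation(len(ids))]
                for lab, ids in sorted(strata.items())}
    base = {lab: int(np.floor(test_fraction * len(ids)))
            for lab, ids in shuffled.items()}
    remainder = {lab: test_fraction * len(ids) - base[lab]
                 for lab, ids in shuffled.items()}
    short = target_test - sum(base.values())
    for lab in sorted(remainder, key=lambda l: (-remainder[l], l))[:max(short, 0)]:
        base[lab] += 1

    test: list[str] = []
    folds: list[list[str]] = [[] for _ in range(n_folds)]
    for offset, (lab, ids) in enumerate(shuffled.items()):
        n_test = min(base[lab], len(ids))
        test.extend(ids[:n_test])
        for i, uid in enumerate(ids[n_test:]):
            folds[(i + offset) % n_folds].append(uid)
    return SplitPlan(test_utterances=test, folds=folds, seed=seed)


def utterance_decision(frame_class_indices) -> str:
    """ASD iff the mean window class index strictly exceeds 0.5."""
    idx = np.asarray(frame_class_indices, dtype=np.float64)
    if idx.size == 0:
        raise ValueError("no window predictions for utterance")
    return "ASD" if idx.mean() > 0.5 else "TD"


def confusion(pred: list[str], truth: list[str]) -> ConfusionMatrix2x2:
    """Count utterance decisions against ground truth (ASD positive)."""
    if len(pred) != len(truth):
        raise ValueError("prediction/truth length mismatch")
    counts = {"tp": 0, "fn": 0, "fp": 0, "tn": 0}
    for p, t in zip(pred, truth):
        if p not in feat_mod.GROUPS or t not in feat_mod.GROUPS:
            raise ValueError(f"unknown label in pair ({p!r}, {t!r})")
        if t == "ASD":
            counts["tp" if p == "ASD" else "fn"] += 1
        else:
            counts["fp" if p == "ASD" else "tn"] += 1
    return ConfusionMatrix2x2(**counts)


def compute_metrics(cm: ConfusionMatrix2x2) -> MetricsReport:
    """Standard binary metrics plus UAR/WAR from a 2x2 confusion matrix.

    Ratios with a zero denominator are reported as 0 and flagged in
    ``undefined`` so degenerate single-class predictors never crash
    evaluation.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    undefined: list[str] = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    accuracy = (cm.tp + cm.tn) / cm.total
    precision = ratio(cm.tp, cm.tp + cm.fp, "precision")
    recall = ratio(cm.tp, cm.tp + cm.fn, "recall")
    f1 = ratio(2 * precision * recall, precision + recall, "f1")
    tnr = ratio(cm.tn, cm.tn + cm.fp, "tnr")
    uar = (recall + tnr) / 2.0
    return MetricsReport(accuracy=accuracy, precision=precision, recall=recall,
                         f1=f1, uar=uar, war=accuracy, undefined=undefined)


# experiment driver ----------------------------------------------------------

@dataclass
class ExperimentConfig:
    """Everything `run_experiment` needs beyond the utterances themselves."""

    model: str = "joint"
    seed: int = 0
    test_fraction: float = 0.1
    n_folds: int = 5
    group_size: int = 5
    n_selected: int = 54
    alpha: float = 0.3
    n_cells: int = 8
    dropout_rate: float = 0.2
    pooling: str = "final"
    freeze_encoder: bool = False
    svm_c: float = 1.0
    ae_epochs: int = 30
    clf_epochs: int = 60
    patience: int = 100
    lr: float = 1e-3
    batch_size: int = 128
    l2_coeff: float = 1e-4
    evaluate_test: bool = True

    def __post_init__(self):
        if self.model not in MODEL_CHOICES:
            raise ValueError(f"model must be one of {MODEL_CHOICES}")


def _one_hot(labels: list[str]) -> np.ndarray:
    # ASD positive -> (0, 1); TD negative -> (1, 0)
    out = np.zeros((len(labels), 2))
    for i, lab in enumerate(labels):
        out[i, 1 if lab == "ASD" else 0] = 1.0
    return out


def _windows_of(utts: list[UtteranceFeatures], stats, group_size: int,
                columns: np.ndarray | None = None):
    """Normalize, optionally select columns, group; returns stacked windows,
    one-hot labels, and per-utterance window slices."""
    mats, labels, slices = [], [], {}
    start = 0
    for u in utts:
        frames = feat_mod.apply_normalizer(u.frames, stats)
        if columns is not None:
            frames = frames[:, columns]
        grouped = feat_mod.group_frames(
            UtteranceFeatures(u.utterance_id, u.subject_id, u.group,
                              u.vocal_label, frames, u.duration_s), group_size)
        if grouped.n_windows == 0:
            continue
        mats.append(grouped.windows)
        labels.extend([u.group] * grouped.n_windows)
        slices[u.utterance_id] = (start, start + grouped.n_windows, u.group)
        start += grouped.n_windows
    if not mats:
        raise ValueError("no utterance long enough for one window")
    return np.concatenate(mats, axis=0), _one_hot(labels), slices


def _fit_fold(train_utts, val_utts, cfg: ExperimentConfig, fold_seed: int):
    """Train one fold's model; return (per-utterance val decisions, val loss,
    fitted predictor closure)."""
    train_frames = np.concatenate([u.frames for u in train_utts], axis=0)
    stats = feat_mod.fit_normalizer(train_frames)
    columns = None
    ae_model = None

    if cfg.model == "blstm54":
        asd = np.concatenate([feat_mod.apply_normalizer(u.frames, stats)
                              for u in train_utts if u.group == "ASD"], axis=0)
        td = np.concatenate([feat_mod.apply_normalizer(u.frames, stats)
                             for u in train_utts if u.group == "TD"], axis=0)
        sel = feat_mod.select_features(asd, td, k=cfg.n_selected)
        columns = np.asarray(sel.selected_indices)

    Xtr, ytr, _ = _windows_of(train_utts, stats, cfg.group_size, columns)
    Xva, yva, val_slices = _windows_of(val_utts, stats, cfg.group_size, columns)

    if cfg.model == "svm":
        clf = clf_mod.train_svm(Xtr.reshape(len(Xtr), -1), ytr.argmax(axis=1),
                                C=cfg.svm_c)
        val_pred = clf.predict(Xva.reshape(len(Xva), -1))
        val_loss = 0.0

        def predict(X):
            return clf.predict(X.reshape(len(X), -1))
    else:
        tc = TrainConfig(max_epochs=cfg.clf_epochs, patience=cfg.patience,
                         lr=cfg.lr, batch_size=cfg.batch_size,
                         l2_coeff=cfg.l2_coeff, seed=fold_seed)
        if cfg.model == "joint":
            ae_tc = TrainConfig(max_epochs=cfg.ae_epochs, patience=cfg.patience,
                                lr=cfg.lr, batch_size=max(cfg.batch_size, 256),
                                l2_coeff=cfg.l2_coeff, seed=fold_seed)
            frame_tr = np.concatenate(
                [feat_mod.apply_normalizer(u.frames, stats) for u in train_utts])
            ylab_tr = _one_hot([u.group for u in train_utts
                                for _ in range(u.n_frames)])
            frame_va = np.concatenate(
                [feat_mod.apply_normalizer(u.frames, stats) for u in val_utts])
            ylab_va = _one_hot([u.group for u in val_utts
                                for _ in range(u.n_frames)])
            ae_model, _ = ae_mod.train_autoencoder(
                frame_tr, ylab_tr, frame_va, ylab_va,
                ae_mod.AEConfig(alpha=cfg.alpha, l2_coeff=cfg.l2_coeff,
                                seed=fold_seed), ae_tc)
            bcfg = clf_mod.BLSTMConfig(
                input_dim=ae_model.config.latent_dim, n_cells=cfg.n_cells,
                sequence_len=cfg.group_size, dropout_rate=cfg.dropout_rate,
                pooling=cfg.pooling, seed=fold_seed)
            model = clf_mod.build_joint_model(ae_model, bcfg,
                                              freeze_encoder=cfg.freeze_encoder)
        else:
            bcfg = clf_mod.BLSTMConfig(
                input_dim=Xtr.shape[2], n_cells=cfg.n_cells,
                sequence_len=cfg.group_size, dropout_rate=cfg.dropout_rate,
                pooling=cfg.pooling, seed=fold_seed)
            model = clf_mod.build_blstm(bcfg)
        model, history = clf_mod.train_classifier(model, (Xtr, ytr), (Xva, yva), tc)
        val_loss = min(history.val_loss)
        preds = clf_mod.predict_windows(model, Xva)
        val_pred = np.array([p.class_index for p in preds])

        def predict(X):
            return np.array([p.class_index
                             for p in clf_mod.predict_windows(model, X)])

    decisions = {}
    for uid, (lo, hi, truth) in val_slices.items():
        decisions[uid] = (utterance_decision(val_pred[lo:hi]), truth)
    return decisions, float(val_loss), predict, stats, columns


def run_experiment(utterances: list[UtteranceFeatures],
                   config: ExperimentConfig,
                   out_path: str | Path | None = None) -> dict:
    """Full protocol: split, five-fold cross-validated training, pooled
    utterance-level metrics, optional held-out-test evaluation with the
    best-validation fold model.  Deterministic given config (seeds for each
    fold are spawned from config.seed).  Returns (and optionally writes) a
    JSON-serializable report."""
    plan = make_split_plan(utterances, config.test_fraction, config.n_folds,
                           config.seed)
    by_id = {u.utterance_id: u for u in utterances}
    fold_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                  for s in np.random.SeedSequence(config.seed).spawn(config.n_folds)]

    pooled: dict[str, tuple[str, str]] = {}
    per_fold = []
    best = None  # (val_loss, predict, stats, columns)
    for i in range(config.n_folds):
        val_utts = [by_id[uid] for uid in plan.folds[i]]
        train_utts = [by_id[uid] for j in range(config.n_folds) if j != i
                      for uid in plan.folds[j]]
        decisions, val_loss, predict, stats, columns = _fit_fold(
            train_utts, val_utts, config, fold_seeds[i])
        pooled.update(decisions)
        cm = confusion([d[0] for d in decisions.values()],
                       [d[1] for d in decisions.values()])
        per_fold.append({"fold": i, "val_loss": val_loss,
                         "confusion": asdict(cm),
                         "metrics": compute_metrics(cm).to_dict()})
        if best is None or val_loss < best[0]:
            best = (val_loss, predict, stats, columns)

    cm_pooled = confusion([d[0] for d in pooled.values()],
                          [d[1] for d in pooled.values()])
    report = {
        "config": asdict(config),
        "plan": plan.to_dict(),
        "pooled": {"confusion": asdict(cm_pooled),
                   "metrics": compute_metrics(cm_pooled).to_dict()},
        "per_fold": per_fold,
    }

    if config.evaluate_test and plan.test_utterances:
        _, predict, stats, columns = best
        test_utts = [by_id[uid] for uid in plan.test_utterances]
        Xte, _, slices = _windows_of(test_utts, stats, config.group_size, columns)
        pred_idx = predict(Xte)
        tdec = {uid: (utterance_decision(pred_idx[lo:hi]), truth)
                for uid, (lo, hi, truth) in slices.items()}
        cm_test = confusion([d[0] for d in tdec.values()],
                            [d[1] for d in tdec.values()])
        report["test"] = {"confusion": asdict(cm_test),
                          "metrics": compute_metrics(cm_test).to_dict()}

    if out_path is not None:
        Path(out_path).write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
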