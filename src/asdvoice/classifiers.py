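"""Window-level ASD/TD classifiers: linear SVM, vanilla BLSTM, joint AE+BLSTM.

All three families consume 5-frame windows of normalized acoustic features
and emit a binary decision per window.  ASD is the positive class, one-hot
(0, 1); TD is negative, (1, 0).  The SVM sees the window flattened to a
single 440-dimensional vector; the BLSTMs process the window as a length-5
sequence with a single bidirectional recurrent layer of 8 cells per
direction.  The joint model runs a trainable copy of a pretrained
auto-encoder's encoder over each frame and feeds the 54-dimensional
bottleneck sequence to the BLSTM, fine-tuning both together under the
classification loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import LinearSVC

from .autoencoder import SemiSupervisedAE
from .nn import Tensor, autodiff as ad
from .nn.layers import BatchNorm, Dense, Dropout, Module
from .nn.layers import BiLSTM as _BiLSTM
from .nn.train import History, TrainConfig, fit


@dataclass
class BLSTMConfig:
    input_dim: int = 88
    n_cells: int = 8          # hidden units per direction
    sequence_len: int = 5     # must equal the frame-grouping size
    dropout_rate: float = 0.2
    pooling: str = "final"    # "final" states or "mean" over time
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.sequence_len < 1:
            raise ValueError("sequence_len must be >= 1")


@dataclass
class FramePrediction:
    """One window's softmax output and hard decision (1 = ASD)."""

    window_id: str
    probs: np.ndarray
    class_index: int


def flatten_for_svm(window: np.ndarray) -> np.ndarray:
    """Row-major concatenation of a (5, 88) window into a 440-vector:
    element (frame f, feature j) lands at index 88*f + j."""
    window = np.asarray(window, dtype=np.float64)
    if window.shape != (5, 88):
        raise ValueError(f"expected a (5, 88) window, got shape {window.shape}")
    return window.reshape(-1)


def train_svm(X: np.ndarray, y: np.ndarray, C: float = 1.0) -> LinearSVC:
    """Linear-kernel max-margin classifier on flattened windows.

    y holds class indices (1 = ASD).  Class weights are left unadjusted.
    """
    X, y = np.asarray(X, np.float64), np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    clf = LinearSVC(C=C, max_iter=5000)
    clf.fit(X, y)
    return clf


class BLSTMClassifier(Module):
    """Single bidirectional LSTM layer -> batch norm -> dropout -> softmax(2)."""

    def __init__(self, config: BLSTMConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.bilstm = _BiLSTM(config.input_dim, config.n_cells, rng,
                              pooling=config.pooling)
        self.bn = BatchNorm(self.bilstm.out_dim)
        self.dropout = Dropout(config.dropout_rate)
        self.out = Dense(self.bilstm.out_dim, 2, rng)

    def logits_graph(self, x: np.ndarray, training: bool,
                     rng: np.random.Generator) -> Tensor:
        if x.ndim != 3 or x.shape[1] != self.config.sequence_len \
                or x.shape[2] != self.config.input_dim:
            raise ValueError(
                f"expected (batch, {self.config.sequence_len}, "
                f"{self.config.input_dim}) input, got {x.shape}")
        steps = [Tensor(x[:, t, :]) for t in range(x.shape[1])]
        h = self.bilstm.forward(steps)
        h = self.bn.forward(h, training)
        h = self.dropout.forward(h, training, rng)
        return self.out.forward(h)

    def no_decay_params(self) -> list[Tensor]:
        return [p for p in self.parameters() if p.data.ndim == 1]


class JointModel(Module):
    """Trainable AE-encoder front end feeding a BLSTM sequence classifier.

    The encoder is initialized from a pretrained auto-encoder and receives
    gradient during classifier training (joint optimization); pass
    ``freeze_encoder=True`` to keep it fixed as an ablation.
    """

    def __init__(self, pretrained: SemiSupervisedAE, config: BLSTMConfig,
                 freeze_encoder: bool = False):
        latent = pretrained.config.latent_dim
        if config.input_dim != latent:
            raise ValueError(
                f"BLSTM input_dim {config.input_dim} != encoder latent {latent}")
        self.encoder = SemiSupervisedAE(pretrained.config)
        self.encoder.load_state(pretrained.state())
        self.blstm = BLSTMClassifier(config)
        self.freeze_encoder = freeze_encoder
        self.frame_dim = pretrained.config.input_dim

    def parameters(self) -> list[Tensor]:
        params = self.blstm.parameters()
        if not self.freeze_encoder:
            enc = [l.W for l in self.encoder.encoder_layers] + \
                  [l.b for l in self.encoder.encoder_layers]
            for bn in self.encoder.encoder_bn:
                enc.extend([bn.gamma, bn.beta])
            params = enc + params
        return params

    def logits_graph(self, x: np.ndarray, training: bool,
                     rng: np.random.Generator) -> Tensor:
        if x.ndim != 3 or x.shape[2] != self.frame_dim:
            raise ValueError(
                f"expected (batch, seq, {self.frame_dim}) input, got {x.shape}")
        enc_training = training and not self.freeze_encoder
        latent_steps = [
            self.encoder.encode_graph(Tensor(x[:, t, :]), enc_training)
            for t in range(x.shape[1])
        ]
        h = self.blstm.bilstm.forward(latent_steps)
        h = self.blstm.bn.forward(h, training)
        h = self.blstm.dropout.forward(h, training, rng)
        return self.blstm.out.forward(h)

    def no_decay_params(self) -> list[Tensor]:
        return [p for p in self.parameters() if p.data.ndim == 1]


def build_blstm(config: BLSTMConfig) -> BLSTMClassifier:
    return BLSTMClassifier(config)


def build_joint_model(pretrained: SemiSupervisedAE, config: BLSTMConfig,
                      freeze_encoder: bool = False) -> JointModel:
    return JointModel(pretrained, config, freeze_encoder=freeze_encoder)


def _ce_batch_loss(model, xb: np.ndarray, yb: np.ndarray, training: bool,
                   rng) -> Tensor:
    logits = model.logits_graph(xb, training, rng)
    logp = ad.log_softmax(logits, axis=1)
    return ad.neg(ad.tmean(ad.tsum(Tensor(yb) * logp, axis=1)))


def train_classifier(model, train: tuple[np.ndarray, np.ndarray],
                     val: tuple[np.ndarray, np.ndarray],
                     opt: TrainConfig | None = None) -> tuple[Module, History]:
    """Cross-entropy training with Adam and validation early stopping.

    train/val are (windows, one-hot labels); the returned model carries the
    parameters of the best-validation-loss epoch.
    """
    opt = opt or TrainConfig()
    history = fit(model, _ce_batch_loss, train, val, opt,
                  no_decay=model.no_decay_params())
    return model, history


def predict_windows(model, X: np.ndarray,
                    window_ids: list[str] | None = None) -> list[FramePrediction]:
    """Inference-mode window predictions (probabilities sum to 1)."""
    rng = np.random.default_rng(0)  # dropout inactive in inference mode
    probs = ad.softmax(model.logits_graph(np.asarray(X, np.float64), False, rng),
                       axis=1).data
    ids = window_ids or [str(i) for i in range(len(probs))]
    return [FramePrediction(window_id=i, probs=p, class_index=int(p.argmax()))
            for i, p in zip(ids, probs)]
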