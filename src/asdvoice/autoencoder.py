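"""Semi-supervised stacked auto-encoder for acoustic bottleneck features.

A symmetric dense stack (88-70-54-70-88 by default) is trained to
reconstruct z-normalized eGeMAPS-style frames under mean absolute error,
while an auxiliary softmax head attached to the 54-dimensional latent
(bottleneck) layer predicts the ASD/TD group label under binary
cross-entropy.  The two objectives are mixed as

    L_total = L_recon + alpha * L_aux,     alpha = 0.3 by default,

so the bottleneck is shaped both by reconstruction fidelity and by class
separability — the "semi-supervised" training of the feature extractor.
Hidden layers use batch normalization followed by ReLU; the decoder output
layer is affine with no activation, appropriate for real-valued
z-normalized targets.  Weights carry L2 decay; biases and batch-norm
parameters do not.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .nn import Tensor, autodiff as ad
from .nn.layers import BatchNorm, Dense, Module
from .nn.train import History, TrainConfig, fit

PROB_CLIP = 1e-7


@dataclass
class AEConfig:
    layer_dims: tuple[int, ...] = (88, 70, 54, 70, 88)
    alpha: float = 0.3
    activation: str = "relu"
    l2_coeff: float = 1e-4
    use_batch_norm: bool = True
    seed: int = 0

    def __post_init__(self):
        dims = tuple(self.layer_dims)
        if len(dims) < 3 or len(dims) % 2 == 0:
            raise ValueError("layer_dims must have odd length >= 3")
        if dims != dims[::-1]:
            raise ValueError(f"layer_dims must be symmetric, got {dims}")
        if dims[len(dims) // 2] >= dims[0]:
            raise ValueError("latent dimension must be smaller than the input "
                             "dimension (bottleneck condition)")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.activation != "relu":
            raise ValueError(f"unsupported activation {self.activation!r}")
        self.layer_dims = dims

    @property
    def input_dim(self) -> int:
        return self.layer_dims[0]

    @property
    def latent_dim(self) -> int:
        return self.layer_dims[len(self.layer_dims) // 2]


@dataclass
class AEParameters:
    """Read-only numpy view of a trained model's parameters."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    aux_weight: np.ndarray
    aux_bias: np.ndarray


class SemiSupervisedAE(Module):
    def __init__(self, config: AEConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        dims = config.layer_dims
        mid = len(dims) // 2
        self.encoder_layers = [Dense(dims[i], dims[i + 1], rng) for i in range(mid)]
        self.decoder_layers = [Dense(dims[i], dims[i + 1], rng)
                               for i in range(mid, len(dims) - 1)]
        if config.use_batch_norm:
            self.encoder_bn = [BatchNorm(d.out_dim) for d in self.encoder_layers]
            # no BN on the linear output layer
            self.decoder_bn = [BatchNorm(d.out_dim) for d in self.decoder_layers[:-1]]
        else:
            self.encoder_bn, self.decoder_bn = [], []
        self.aux_head = Dense(config.latent_dim, 2, rng)

    # graph-building passes -------------------------------------------------
    def encode_graph(self, x: Tensor, training: bool) -> Tensor:
        h = x
        for i, layer in enumerate(self.encoder_layers):
            h = layer.forward(h)
            if self.config.use_batch_norm:
                h = self.encoder_bn[i].forward(h, training)
            h = ad.relu(h)
        return h

    def decode_graph(self, z: Tensor, training: bool) -> Tensor:
        h = z
        for i, layer in enumerate(self.decoder_layers[:-1]):
            h = layer.forward(h)
            if self.config.use_batch_norm:
                h = self.decoder_bn[i].forward(h, training)
            h = ad.relu(h)
        return self.decoder_layers[-1].forward(h)  # linear output

    def aux_logits_graph(self, z: Tensor) -> Tensor:
        return self.aux_head.forward(z)

    def parameters_view(self) -> AEParameters:
        dense = self.encoder_layers + self.decoder_layers
        return AEParameters(
            weights=[d.W.data.copy() for d in dense],
            biases=[d.b.data.copy() for d in dense],
            aux_weight=self.aux_head.W.data.copy(),
            aux_bias=self.aux_head.b.data.copy(),
        )

    def no_decay_params(self) -> list[Tensor]:
        return [p for p in self.parameters() if p.data.ndim == 1]


def init_autoencoder(config: AEConfig | None = None) -> SemiSupervisedAE:
    """Build a seed-deterministic semi-supervised AE from its config."""
    return SemiSupervisedAE(config or AEConfig())


def _check_input(x: np.ndarray, dim: int, what: str) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    if x.ndim != 2 or x.shape[1] != dim:
        raise ValueError(f"{what} must have {dim} features, got shape {x.shape}")
    return x, single


def encode(model: SemiSupervisedAE, x: np.ndarray) -> np.ndarray:
    """Deterministic inference-mode bottleneck features (running BN stats)."""
    x, single = _check_input(x, model.config.input_dim, "input frame")
    z = model.encode_graph(Tensor(x), training=False).data
    return z[0] if single else z


def decode(model: SemiSupervisedAE, z: np.ndarray) -> np.ndarray:
    z, single = _check_input(z, model.config.latent_dim, "latent vector")
    y = model.decode_graph(Tensor(z), training=False).data
    return y[0] if single else y


def aux_classify(model: SemiSupervisedAE, z: np.ndarray) -> np.ndarray:
    """Softmax ASD/TD probabilities from bottleneck features."""
    z, single = _check_input(z, model.config.latent_dim, "latent vector")
    p = ad.softmax(model.aux_logits_graph(Tensor(z)), axis=1).data
    return p[0] if single else p


# losses ---------------------------------------------------------------------

def recon_loss(y_rec: np.ndarray, y_gt: np.ndarray) -> float:
    """Mean absolute error over all samples and feature dimensions."""
    y_rec, y_gt = np.asarray(y_rec, np.float64), np.asarray(y_gt, np.float64)
    if y_rec.shape != y_gt.shape:
        raise ValueError(f"shape mismatch {y_rec.shape} vs {y_gt.shape}")
    return float(np.abs(y_rec - y_gt).mean())


def aux_loss(y_aux: np.ndarray, label: np.ndarray) -> float:
    """Binary cross-entropy of softmax outputs against one-hot labels.

    ASD is one-hot (0, 1) and TD is (1, 0); probabilities are clipped to
    [1e-7, 1 - 1e-7] before the log.  Accepts a single pair or a batch;
    batches are averaged over samples.
    """
    y_aux, label = np.atleast_2d(np.asarray(y_aux, np.float64)), \
        np.atleast_2d(np.asarray(label, np.float64))
    if y_aux.shape != label.shape:
        raise ValueError("probability/label shape mismatch")
    if np.any(np.abs(y_aux.sum(axis=1) - 1.0) > 1e-6) or np.any(y_aux < 0):
        raise ValueError("y_aux rows must be normalized probabilities")
    p = np.clip(y_aux, PROB_CLIP, 1.0 - PROB_CLIP)
    return float(-(label * np.log(p)).sum(axis=1).mean())


def total_loss(recon: float, aux: float, alpha: float = 0.3) -> float:
    """Weighted sum of reconstruction and auxiliary losses."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    return recon + alpha * aux


# training -------------------------------------------------------------------

def _ae_batch_loss(model: SemiSupervisedAE, xb: np.ndarray, yb: np.ndarray,
                   training: bool, rng) -> Tensor:
    x = Tensor(xb)
    z = model.encode_graph(x, training)
    rec = model.decode_graph(z, training)
    l_rec = ad.tmean(ad.absolute(rec - x))
    logp = ad.log_softmax(model.aux_logits_graph(z), axis=1)
    l_aux = ad.neg(ad.tmean(ad.tsum(Tensor(yb) * logp, axis=1)))
    return l_rec + Tensor(model.config.alpha) * l_aux


def train_autoencoder(
    train_x: np.ndarray, train_y: np.ndarray,
    val_x: np.ndarray, val_y: np.ndarray,
    config: AEConfig | None = None,
    opt: TrainConfig | None = None,
) -> tuple[SemiSupervisedAE, History]:
    """Jointly minimize reconstruction MAE and auxiliary BCE with Adam.

    Inputs must already be normalized with training-partition statistics;
    labels are one-hot (n, 2) rows, ASD = (0, 1).  Returns the model at its
    best-validation-loss epoch and the per-epoch loss history.
    """
    config = config or AEConfig()
    opt = opt or TrainConfig(seed=config.seed, l2_coeff=config.l2_coeff)
    train_x = np.asarray(train_x, np.float64)
    if train_x.ndim != 2 or train_x.shape[0] == 0:
        raise ValueError("empty training set")
    model = init_autoencoder(config)
    history = fit(model, _ae_batch_loss, (train_x, np.asarray(train_y, np.float64)),
                  (np.asarray(val_x, np.float64), np.asarray(val_y, np.float64)),
                  opt, no_decay=model.no_decay_params())
    return model, history


# checkpointing ---------------------------------------------------------------

def save_checkpoint(model: SemiSupervisedAE, path: str | Path) -> None:
    cfg = model.config
    Path(path).write_text(json.dumps({
        "config": {"layer_dims": list(cfg.layer_dims), "alpha": cfg.alpha,
                   "activation": cfg.activation, "l2_coeff": cfg.l2_coeff,
                   "use_batch_norm": cfg.use_batch_norm, "seed": cfg.seed},
        "state": [s.tolist() for s in model.state()],
    }))


def load_checkpoint(path: str | Path) -> SemiSupervisedAE:
    d = json.loads(Path(path).read_text())
    cfg = d["config"]
    cfg["layer_dims"] = tuple(cfg["layer_dims"])
    model = init_autoencoder(AEConfig(**cfg))
    model.load_state([np.asarray(s, np.float64) for s in d["state"]])
    return model
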