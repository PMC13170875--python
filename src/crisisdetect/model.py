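"""Joint autoencoder-classifier with optional attention-gated fusion.

The model maps a call embedding eps through an encoder g to a latent z,
reconstructs eps_hat with a decoder d, and predicts four binary labels
(depressed mood, suicidal ideation, suicide plan, high risk) from z with
sigmoid heads. Training minimizes

    L = lambda1 * L_rec + lambda2 * sum_j gamma_j * L_bce(j)

where L_rec is the batch-mean of the per-sample summed squared
reconstruction error and L_bce(j) is per-label binary cross-entropy. The
reconstruction term regularizes the latent toward the data manifold so the
classifier does not overfit high-dimensional noise.

In fused mode a text encoder and an audio encoder each produce a latent;
a learnable gate (MLP with sigmoid output) computes a scalar attention
weight alpha in [0, 1] from the concatenated latents and the classifier
consumes

    z_fused = alpha * z_text + (1 - alpha) * z_audio ,

with each modality reconstructed by its own decoder. When one modality is
uninformative the gate can shut it out entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .nn import Parameter, Tensor

__all__ = [
    "ModelConfig",
    "TrainedJointModel",
    "aggregate_segments",
    "reconstruction_loss",
    "label_bce",
    "classification_loss",
    "total_loss",
    "gated_fusion",
    "fit",
    "predict_proba",
    "predict_labels",
]

BCE_CLIP = 1e-7
N_LABELS = 4


@dataclass
class ModelConfig:
    """Architecture and optimization settings.

    Loss weights, optimizer, batch size, epoch budget and early-stopping
    patience default to the values used in the original hotline experiments
    (Adam, lr 1e-4, batch 32, 150 epochs, patience 40, lambda1=1,
    lambda2=0.8, per-task weights gamma all 1). Layer widths are this
    package's own defaults; the published architecture diagram is not
    reproduced here.
    """

    input_dim: int = 3072
    latent_dim: int = 64
    encoder_hidden: int = 256
    classifier_hidden: int = 64
    gate_hidden: int = 32
    n_labels: int = N_LABELS
    lambda1: float = 1.0
    lambda2: float = 0.8
    gamma: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    learning_rate: float = 1e-4
    batch_size: int = 32
    max_epochs: int = 150
    patience: int = 40
    decision_threshold: float = 0.5
    seed: int = 0
    # fused mode only: the audio branch's input dimension
    audio_input_dim: int | None = None

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("loss weights must be nonnegative")
        if len(self.gamma) != N_LABELS or any(g < 0 for g in self.gamma):
            raise ValueError("gamma must be 4 nonnegative weights")
        if not 0.0 < self.decision_threshold < 1.0:
            raise ValueError("decision_threshold must be in (0, 1)")


# --------------------------------------------------------------------------
# loss primitives (plain numpy; the training loop rebuilds them on the tape)


def reconstruction_loss(eps_hat: np.ndarray, eps: np.ndarray) -> float:
    """Batch-mean of the per-sample summed squared reconstruction error."""
    eps_hat = np.atleast_2d(np.asarray(eps_hat, dtype=float))
    eps = np.atleast_2d(np.asarray(eps, dtype=float))
    if eps_hat.shape != eps.shape:
        raise ValueError(f"shape mismatch: {eps_hat.shape} vs {eps.shape}")
    return float(np.mean(np.sum((eps_hat - eps) ** 2, axis=1)))


def label_bce(y_true: np.ndarray, y_hat: np.ndarray) -> float:
    """Binary cross-entropy for one label over a batch, clipped for stability."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y_true.shape != y_hat.shape:
        raise ValueError("shape mismatch")
    if np.any(y_hat < 0) or np.any(y_hat > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    p = np.clip(y_hat, BCE_CLIP, 1 - BCE_CLIP)
    return float(-np.mean(y_true * np.log(p) + (1 - y_true) * np.log(1 - p)))


def classification_loss(per_label_losses, gamma=(1.0, 1.0, 1.0, 1.0)) -> float:
    """Weighted sum of the four per-task BCE losses."""
    per_label_losses = np.asarray(per_label_losses, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    if per_label_losses.shape != (N_LABELS,) or gamma.shape != (N_LABELS,):
        raise ValueError("expected exactly 4 per-label losses and 4 weights")
    return float(np.dot(gamma, per_label_losses))


def total_loss(l_rec: float, l_clf: float, lambda1: float = 1.0, lambda2: float = 0.8) -> float:
    """lambda1 * reconstruction + lambda2 * classification."""
    if lambda1 < 0 or lambda2 < 0:
        raise ValueError("loss weights must be nonnegative")
    if l_rec < 0 or l_clf < 0:
        raise ValueError("losses must be nonnegative")
    return float(lambda1 * l_rec + lambda2 * l_clf)


# --------------------------------------------------------------------------
# segment aggregation


def aggregate_segments(segment_vectors, method: str = "mean", hidden_dim: int = 64, seed: int = 0) -> np.ndarray:
    """Collapse a variable-length sequence of segment vectors to one vector.

    ``mean`` is the order-invariant arithmetic mean. ``birnn`` runs a fixed,
    seeded bidirectional recurrent (Elman-tanh) pass over the sequence and
    concatenates the final hidden states of the forward and backward
    directions — an order-sensitive random-feature summary of temporal
    dynamics standing in for a trained BiLSTM pooling layer.
    """
    segs = np.asarray(segment_vectors, dtype=float)
    if segs.ndim != 2 or segs.shape[0] == 0:
        raise ValueError("expected a nonempty (n_segments, dim) array")
    if method == "mean":
        return segs.mean(axis=0)
    if method == "birnn":
        d = segs.shape[1]
        rng = np.random.default_rng(seed)
        w_in = rng.standard_normal((d, hidden_dim)) / np.sqrt(d)
        w_rec = rng.standard_normal((hidden_dim, hidden_dim)) / np.sqrt(hidden_dim)

        def run(seq):
            h = np.zeros(hidden_dim)
            for x in seq:
                h = np.tanh(x @ w_in + h @ w_rec)
            return h

        return np.concatenate([run(segs), run(segs[::-1])])
    raise ValueError(f"unknown aggregation method: {method!r}")


# --------------------------------------------------------------------------
# network


def _init_linear(rng, fan_in, fan_out):
    w = Parameter(rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / fan_in))
    b = Parameter(np.zeros((1, fan_out)))
    return w, b


class _Branch:
    """Encoder + mirrored decoder for one modality."""

    def __init__(self, rng, input_dim, hidden, latent):
        self.e1 = _init_linear(rng, input_dim, hidden)
        self.e2 = _init_linear(rng, hidden, latent)
        self.d1 = _init_linear(rng, latent, hidden)
        self.d2 = _init_linear(rng, hidden, input_dim)

    def encode(self, x: Tensor) -> Tensor:
        h = nn.linear(x, *self.e1).relu()
        return nn.linear(h, *self.e2)

    def decode(self, z: Tensor) -> Tensor:
        h = nn.linear(z, *self.d1).relu()
        return nn.linear(h, *self.d2)

    def params(self):
        return [p for pair in (self.e1, self.e2, self.d1, self.d2) for p in pair]


class _Network:
    def __init__(self, config: ModelConfig, mode: str):
        self.config = config
        self.mode = mode
        rng = np.random.default_rng(config.seed)
        self.text_branch = _Branch(rng, config.input_dim, config.encoder_hidden, config.latent_dim)
        self.audio_branch = None
        self.gate = None
        if mode == "fused":
            adim = config.audio_input_dim or config.input_dim
            self.audio_branch = _Branch(rng, adim, config.encoder_hidden, config.latent_dim)
            self.gate = (
                _init_linear(rng, 2 * config.latent_dim, config.gate_hidden),
                _init_linear(rng, config.gate_hidden, 1),
            )
        self.c1 = _init_linear(rng, config.latent_dim, config.classifier_hidden)
        self.c2 = _init_linear(rng, config.classifier_hidden, config.n_labels)

    def params(self) -> list[Parameter]:
        ps = self.text_branch.params()
        if self.audio_branch is not None:
            ps += self.audio_branch.params()
            ps += [p for pair in self.gate for p in pair]
        ps += [*self.c1, *self.c2]
        return ps

    def forward(self, x_text: Tensor, x_audio: Tensor | None):
        """Returns (probs, recon terms [(eps_hat, eps), ...], alpha or None)."""
        z_t = self.text_branch.encode(x_text)
        alpha = None
        if self.mode == "fused":
            z_a = self.audio_branch.encode(x_audio)
            # RMS-normalize each modality latent before fusion: otherwise the
            # encoders can silence a modality by shrinking its latent scale
            # and the gate weight alpha is unidentifiable
            zt_n = _rms_normalize(z_t)
            za_n = _rms_normalize(z_a)
            g1, g2 = self.gate
            h = nn.linear(nn.concat([zt_n, za_n]), *g1).relu()
            alpha = nn.linear(h, *g2).sigmoid()  # (B, 1)
            z = gated_fusion_tensors(zt_n, za_n, alpha)
            recons = [
                (self.text_branch.decode(z_t), x_text),
                (self.audio_branch.decode(z_a), x_audio),
            ]
        else:
            z = z_t
            recons = [(self.text_branch.decode(z_t), x_text)]
        h = nn.linear(z, *self.c1).relu()
        probs = nn.linear(h, *self.c2).sigmoid()
        return probs, recons, alpha

    def get_state(self):
        return [p.data.copy() for p in self.params()]

    def set_state(self, state):
        for p, s in zip(self.params(), state):
            p.data = s.copy()


def _rms_normalize(z: Tensor, eps: float = 1e-8) -> Tensor:
    """Scale each row to unit root-mean-square."""
    ms = (z * z).mean(axis=1, keepdims=True)
    return z * ((ms + eps) ** -0.5)


def gated_fusion_tensors(z_text: Tensor, z_audio: Tensor, alpha: Tensor) -> Tensor:
    return alpha * z_text + (1.0 - alpha) * z_audio


def gated_fusion(z_text: np.ndarray, z_audio: np.ndarray, alpha: float | np.ndarray) -> tuple[np.ndarray, float]:
    """Convex combination of two modality latents with attention weight alpha.

    This is the inference-side primitive; during training alpha comes from
    the learnable gate. Returns ``(z_fused, alpha)``.
    """
    z_text = np.asarray(z_text, dtype=float)
    z_audio = np.asarray(z_audio, dtype=float)
    if z_text.shape != z_audio.shape:
        raise ValueError("latent length mismatch")
    a = float(np.asarray(alpha).reshape(()))
    if not 0.0 <= a <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    return a * z_text + (1.0 - a) * z_audio, a


def compute_gate_alpha(model: "TrainedJointModel", x_text: np.ndarray, x_audio: np.ndarray) -> np.ndarray:
    """Per-sample gate weights alpha of a trained fused model."""
    if model.mode != "fused":
        raise ValueError("gate weights exist only in fused mode")
    net = model._network
    _, _, alpha = net.forward(Tensor(np.atleast_2d(x_text)), Tensor(np.atleast_2d(x_audio)))
    return alpha.data.ravel()


# --------------------------------------------------------------------------
# training


@dataclass
class TrainedJointModel:
    config: ModelConfig
    mode: str
    history: dict = field(default_factory=dict)  # per-epoch train/val losses
    stopped_epoch: int = 0
    _network: _Network | None = None

    def to_dict(self) -> dict:
        return {"config": asdict(self.config), "mode": self.mode,
                "stopped_epoch": self.stopped_epoch, "history": self.history}


def _batch_loss(net: _Network, xb_t, xb_a, yb, config: ModelConfig):
    probs, recons, _ = net.forward(xb_t, xb_a)
    l_rec = None
    for eps_hat, eps in recons:
        term = ((eps_hat - eps) ** 2).sum(axis=1).mean()
        l_rec = term if l_rec is None else l_rec + term
    if len(recons) > 1:
        l_rec = l_rec * (1.0 / len(recons))
    p = probs.clip(BCE_CLIP, 1 - BCE_CLIP)
    y = Tensor(yb)
    bce_matrix = -(y * p.log() + (1.0 - y) * (1.0 - p).log())  # (B, 4)
    per_label = bce_matrix.mean(axis=0)  # (4,)
    l_clf = (per_label * Tensor(np.asarray(config.gamma, dtype=float))).sum()
    return config.lambda1 * l_rec + config.lambda2 * l_clf


def _eval_loss(net, x_t, x_a, y, config) -> float:
    return float(_batch_loss(net, Tensor(x_t), None if x_a is None else Tensor(x_a), y, config).data)


def fit(train, val, config: ModelConfig, mode: str = "text_only") -> TrainedJointModel:
    """Train the joint model with mini-batch Adam and early stopping.

    ``train`` and ``val`` are ``(X, y)`` pairs for the unimodal modes or
    ``((X_text, X_audio), y)`` for fused mode, with y of shape (n, 4).
    Training stops when the validation loss has not improved for
    ``config.patience`` consecutive epochs or at ``config.max_epochs``;
    the best-validation weights are restored. Deterministic given
    ``config.seed``.
    """
    if mode not in ("text_only", "audio_only", "fused"):
        raise ValueError(f"unknown mode: {mode!r}")

    def unpack(split):
        X, y = split
        if mode == "fused":
            x_t, x_a = X
            x_t = np.asarray(x_t, float)
            x_a = np.asarray(x_a, float)
        else:
            x_t = np.asarray(X, float)
            x_a = None
        y = np.asarray(y, float)
        if len(y) == 0 or len(x_t) == 0:
            raise ValueError("empty split")
        if y.ndim != 2 or y.shape[1] != config.n_labels:
            raise ValueError("labels must be (n, 4)")
        return x_t, x_a, y

    xt_tr, xa_tr, y_tr = unpack(train)
    xt_va, xa_va, y_va = unpack(val)
    if xt_tr.shape[1] != config.input_dim:
        raise ValueError(f"input_dim mismatch: data {xt_tr.shape[1]} vs config {config.input_dim}")

    net = _Network(config, mode)
    opt = nn.Adam(net.params(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)

    n = len(y_tr)
    best_val = np.inf
    best_state = net.get_state()
    since_improve = 0
    hist_train, hist_val = [], []
    stopped = config.max_epochs

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb_t = Tensor(xt_tr[idx])
            xb_a = Tensor(xa_tr[idx]) if xa_tr is not None else None
            loss = _batch_loss(net, xb_t, xb_a, y_tr[idx], config)
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        val_loss = _eval_loss(net, xt_va, xa_va, y_va, config)
        hist_train.append(float(np.mean(epoch_losses)))
        hist_val.append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_state = net.get_state()
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= config.patience:
                stopped = epoch
                break
    net.set_state(best_state)
    return TrainedJointModel(
        config=config,
        mode=mode,
        history={"train_loss": hist_train, "val_loss": hist_val},
        stopped_epoch=min(stopped, len(hist_train)),
        _network=net,
    )


def predict_proba(model: TrainedJointModel, X) -> np.ndarray:
    """Per-call probabilities for the four labels, shape (n, 4)."""
    net = model._network
    if model.mode == "fused":
        x_t, x_a = X
        x_t = np.atleast_2d(np.asarray(x_t, float))
        x_a = np.atleast_2d(np.asarray(x_a, float))
        if x_t.shape[1] != model.config.input_dim:
            raise ValueError("input_dim mismatch")
        probs, _, _ = net.forward(Tensor(x_t), Tensor(x_a))
    else:
        x_t = np.atleast_2d(np.asarray(X, float))
        if x_t.shape[1] != model.config.input_dim:
            raise ValueError("input_dim mismatch")
        probs, _, _ = net.forward(Tensor(x_t), None)
    return probs.data


def predict_labels(probs: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binarize probabilities; ties at the threshold count as positive."""
    probs = np.asarray(probs, dtype=float)
    if np.any(probs < 0) or np.any(probs > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    return (probs >= threshold).astype(int)
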