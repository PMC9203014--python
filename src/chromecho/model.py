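"""The neural architecture and training loop.

The predictor has three parts.  A convolutional sequence encoder f maps a
one-hot flanked bin sequence to a hidden vector phi of length K; it is
pre-trained on the same multi-label task with a temporary classification
head, the head is dropped, and the encoder is frozen.  Two graph layers —
g_c over the stacked spatial-neighbor representations (k_c x K) and g_s over
the stacked sequential window ((1+2*k_s) x K) — convolve along the feature
axis with neighbors as channels and end in global average pooling.  A single
fully connected prediction layer maps the concatenation h_s || h_c to L
sigmoid outputs.  Training minimizes mean binary cross entropy with
mini-batch SGD (momentum 0.9); only graph-layer and head parameters are
updated, and the checkpoint with minimum validation loss is kept.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .genome_io import reverse_complement

__all__ = [
    "TrainConfig",
    "ModelConfig",
    "SMALL_PRESET",
    "SequenceEncoder",
    "EchoModel",
    "bce_loss",
    "pretrain_encoder",
    "encode_all",
    "train_echo",
    "predict",
    "predict_with_revcomp",
    "save_checkpoint",
    "load_checkpoint",
    "save_encoder",
    "load_encoder",
]


@dataclass
class TrainConfig:
    """Optimization hyperparameters (defaults follow the published setup)."""

    batch_size: int = 64
    lr: float = 0.5
    momentum: float = 0.9
    epochs: int = 10
    seed: int = 0

    def to_dict(self):
        return asdict(self)


@dataclass
class ModelConfig:
    """Architecture sizes.

    `K` is the hidden representation length; `enc_channels` / `enc_kernels`
    / `enc_pools` define the convolutional encoder stack; `graph_channels`
    and `graph_kernel` define the two-conv graph layers.
    """

    seq_len: int = 1000
    K: int = 2600
    k_c: int = 50
    k_s: int = 10
    n_features: int = 1
    enc_channels: tuple = (320, 480, 960)
    enc_kernels: tuple = (8, 8, 8)
    enc_pools: tuple = (4, 4, 4)
    enc_readout: str = "flatten"  # "flatten" or "max" (global max over positions)
    enc_center_frac: float = 1.0  # fraction of the width kept before a max readout
    graph_channels: int = 64
    graph_kernel: int = 5
    graph_first_kernel: int = 0  # 0 = span the full feature axis (width K)

    def to_dict(self):
        return asdict(self)


#: Desk-scale preset for synthetic fixtures.
SMALL_PRESET = dict(
    K=64,
    enc_channels=(32,),
    enc_kernels=(10,),
    enc_pools=(1,),
    enc_readout="max",
    graph_channels=16,
    graph_kernel=5,
)


class SequenceEncoder:
    """Convolutional encoder f: one-hot (B, 4, W) -> hidden (B, K)."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        layers: list[nn.Layer] = []
        w, c = cfg.seq_len, 4
        for ch, k, p in zip(cfg.enc_channels, cfg.enc_kernels, cfg.enc_pools):
            layers += [nn.Conv1d(c, ch, k, rng=rng), nn.ReLU()]
            w = w - k + 1
            if p > 1:
                layers.append(nn.MaxPool1d(p))
                w //= p
            c = ch
        if cfg.enc_readout == "max":
            # position-independent motif-presence readout over the central
            # (labeled) part of the window
            if cfg.enc_center_frac < 1.0:
                layers.append(nn.CenterCrop1d(cfg.enc_center_frac))
            layers += [nn.GlobalMaxPool1d(), nn.Dense(c, cfg.K, rng=rng), nn.ReLU()]
        else:
            layers += [nn.Flatten(), nn.Dense(c * w, cfg.K, rng=rng), nn.ReLU()]
        self.net = nn.Sequential(*layers)
        self.frozen = False
        self.cfg = cfg

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.net.forward(np.asarray(x, dtype=np.float32))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        """Gradient w.r.t. the input of the last forward call.

        Frozen means the parameters are never updated; gradients still flow
        through so sequences can be attributed.
        """
        g = self.net.backward(gy)
        if self.frozen:
            nn.zero_grads(self.parameters())
        return g

    def parameters(self):
        return self.net.parameters()

    def freeze(self):
        self.frozen = True

    def checksum(self) -> float:
        return nn.checksum(self.parameters())


def _graph_stack(n_channels: int, cfg: ModelConfig, rng) -> nn.Sequential:
    """Two 1-D convolutions over the feature axis, then global average pooling.

    By default the first convolution spans the whole feature axis
    (kernel = K, valid), so filters can weight individual hidden-feature
    coordinates of each neighbor channel; the width collapses to 1 and the
    second convolution is pointwise.  With `graph_first_kernel` > 0 both
    convolutions are narrow and same-padded instead.
    """
    gc, gk = cfg.graph_channels, cfg.graph_kernel
    k1 = cfg.graph_first_kernel if cfg.graph_first_kernel > 0 else cfg.K
    if k1 >= cfg.K:
        first = nn.Conv1d(n_channels, gc, cfg.K, padding=0, rng=rng)
        second = nn.Conv1d(gc, gc, 1, padding=0, rng=rng)
    else:
        first = nn.Conv1d(n_channels, gc, k1, padding=k1 // 2, rng=rng)
        second = nn.Conv1d(gc, gc, gk, padding=gk // 2, rng=rng)
    return nn.Sequential(first, nn.ReLU(), second, nn.ReLU(), nn.GlobalAvgPool1d())


class EchoModel:
    """Graph layers g_c / g_s plus the fully connected prediction head p.

    `forward` consumes pre-stacked feature matrices Xi_c (B, k_c, K) and
    Xi_s (B, 1+2*k_s, K) and returns per-feature probabilities (B, L).
    The two graph stacks share their architecture except for the first
    layer's channel count.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.g_c = _graph_stack(cfg.k_c, cfg, rng)
        self.g_s = _graph_stack(1 + 2 * cfg.k_s, cfg, rng)
        self.head = nn.Dense(2 * cfg.graph_channels, cfg.n_features, rng=rng)
        self._probs = None

    def forward(self, xi_c: np.ndarray, xi_s: np.ndarray) -> np.ndarray:
        xi_c = np.asarray(xi_c, dtype=np.float32)
        xi_s = np.asarray(xi_s, dtype=np.float32)
        if xi_c.shape[1:] != (self.cfg.k_c, self.cfg.K):
            raise ValueError(f"Xi_c has shape {xi_c.shape}, expected (*, {self.cfg.k_c}, {self.cfg.K})")
        if xi_s.shape[1:] != (1 + 2 * self.cfg.k_s, self.cfg.K):
            raise ValueError(f"Xi_s has shape {xi_s.shape}")
        h_c = self.g_c.forward(xi_c)
        h_s = self.g_s.forward(xi_s)
        logits = self.head.forward(np.concatenate([h_s, h_c], axis=1))
        self._probs = nn.sigmoid(logits)
        return self._probs

    def backward(self, g_logits: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Backpropagate a gradient at the logits; returns (gXi_c, gXi_s)."""
        gh = self.head.backward(g_logits)
        c = self.cfg.graph_channels
        g_xi_s = self.g_s.backward(gh[:, :c])
        g_xi_c = self.g_c.backward(gh[:, c:])
        return g_xi_c, g_xi_s

    def backward_from_probs(self, g_probs: np.ndarray):
        """Backward seeded at the probabilities (chains the sigmoid)."""
        gz = g_probs * self._probs * (1.0 - self._probs)
        return self.backward(gz)

    def parameters(self):
        return self.g_c.parameters() + self.g_s.parameters() + self.head.parameters()


def bce_loss(y_hat: np.ndarray, y: np.ndarray, eps: float = 1e-7) -> float:
    """Mean binary cross entropy with probabilities clamped to [eps, 1-eps]."""
    if y_hat.shape != y.shape:
        raise ValueError(f"shape mismatch {y_hat.shape} vs {y.shape}")
    p = np.clip(y_hat, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


class _PretrainNet:
    """Encoder plus the temporary classification head used in pretraining."""

    def __init__(self, encoder: SequenceEncoder, n_features: int, rng):
        self.encoder = encoder
        self.head = nn.Dense(encoder.cfg.K, n_features, rng=rng)

    def forward(self, x):
        return nn.sigmoid(self.head.forward(self.encoder.forward(x)))

    def parameters(self):
        return self.encoder.parameters() + self.head.parameters()


def _epoch_minibatches(n: int, batch: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for s in range(0, n, batch):
        yield order[s : s + batch]


def pretrain_encoder(
    X: np.ndarray,
    Y: np.ndarray,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    cfg: ModelConfig,
    tc: TrainConfig,
):
    """Pre-train the sequence encoder on the multi-label task.

    Trains encoder + temporary head with mini-batch SGD, keeps the
    parameters at minimum validation loss, freezes the encoder and returns
    (encoder, head, history).  The head is retained so the sequence-only
    baseline model remains available for comparisons.
    """
    if len(val_idx) == 0:
        raise ValueError("validation set is empty")
    rng = np.random.default_rng(tc.seed)
    encoder = SequenceEncoder(cfg, rng)
    net = _PretrainNet(encoder, Y.shape[1], rng)
    params = net.parameters()
    opt = nn.SGD(params, tc.lr, tc.momentum)
    history = {"train_loss": [], "val_loss": []}
    best = (np.inf, nn.get_state(params))
    Yf = Y.astype(np.float32)
    for _epoch in range(tc.epochs):
        tl = 0.0
        nb = 0
        for mb in _epoch_minibatches(len(train_idx), tc.batch_size, rng):
            idx = train_idx[mb]
            probs = net.forward(X[idx])
            yb = Yf[idx]
            loss = bce_loss(probs, yb)
            if not np.isfinite(loss):
                raise FloatingPointError("NaN/inf loss during pretraining")
            opt.zero_grad()
            gz = (probs - yb) / probs.size  # combined sigmoid+BCE gradient at logits
            encoder.net.backward(net.head.backward(gz))
            opt.step()
            tl += loss
            nb += 1
        vl = _eval_pretrain_loss(net, X, Yf, val_idx, tc.batch_size)
        history["train_loss"].append(tl / max(nb, 1))
        history["val_loss"].append(vl)
        if vl < best[0]:
            best = (vl, nn.get_state(params))
    nn.set_state(params, best[1])
    encoder.freeze()
    return encoder, net.head, history


def _eval_pretrain_loss(net, X, Yf, idx, batch):
    tot, n = 0.0, 0
    for s in range(0, len(idx), batch):
        sel = idx[s : s + batch]
        probs = net.forward(X[sel])
        tot += bce_loss(probs, Yf[sel]) * len(sel)
        n += len(sel)
    return tot / max(n, 1)


def sequence_only_predict(encoder, head, X, batch: int = 256) -> np.ndarray:
    """Probabilities from the frozen encoder + pretrain head baseline."""
    out = []
    for s in range(0, len(X), batch):
        out.append(nn.sigmoid(head.forward(encoder.forward(X[s : s + batch]))))
    return np.concatenate(out, axis=0)


def encode_all(encoder: SequenceEncoder, X: np.ndarray, batch: int = 256) -> np.ndarray:
    """Hidden matrix phi (N x K); row i corresponds to bin i."""
    out = []
    for s in range(0, len(X), batch):
        out.append(encoder.forward(X[s : s + batch]))
    return np.concatenate(out, axis=0)


def train_echo(
    phi_aug: np.ndarray,
    idx_c: np.ndarray,
    idx_s: np.ndarray,
    Y: np.ndarray,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    model: EchoModel,
    tc: TrainConfig,
):
    """Train graph layers + head on pre-encoded, pre-sampled neighborhoods.

    `phi_aug` is the encoder output augmented with the zero dummy row;
    `idx_c` / `idx_s` are the per-bin neighbor index arrays.  Only the
    model's own parameters are updated (the encoder is not part of it).
    Returns the per-epoch loss history; the model is left at the
    minimum-validation-loss checkpoint.
    """
    rng = np.random.default_rng(tc.seed)
    params = model.parameters()
    opt = nn.SGD(params, tc.lr, tc.momentum)
    history = {"train_loss": [], "val_loss": []}
    best = (np.inf, nn.get_state(params))
    Yf = Y.astype(np.float32)
    for _epoch in range(tc.epochs):
        tl, nb = 0.0, 0
        for mb in _epoch_minibatches(len(train_idx), tc.batch_size, rng):
            idx = train_idx[mb]
            probs = model.forward(phi_aug[idx_c[idx]], phi_aug[idx_s[idx]])
            yb = Yf[idx]
            loss = bce_loss(probs, yb)
            if not np.isfinite(loss):
                raise FloatingPointError("NaN/inf loss during training")
            opt.zero_grad()
            model.backward((probs - yb) / probs.size)
            opt.step()
            tl += loss
            nb += 1
        vl = _eval_echo_loss(model, phi_aug, idx_c, idx_s, Yf, val_idx, tc.batch_size)
        history["train_loss"].append(tl / max(nb, 1))
        history["val_loss"].append(vl)
        if vl < best[0]:
            best = (vl, nn.get_state(params))
    nn.set_state(params, best[1])
    return history


def _eval_echo_loss(model, phi_aug, idx_c, idx_s, Yf, idx, batch):
    tot, n = 0.0, 0
    for s in range(0, len(idx), batch):
        sel = idx[s : s + batch]
        probs = model.forward(phi_aug[idx_c[sel]], phi_aug[idx_s[sel]])
        tot += bce_loss(probs, Yf[sel]) * len(sel)
        n += len(sel)
    return tot / max(n, 1)


def predict(model: EchoModel, phi_aug, idx_c, idx_s, which=None, batch: int = 256) -> np.ndarray:
    """Probabilities for the given bin indices (default: all rows of idx_c)."""
    which = np.arange(idx_c.shape[0]) if which is None else np.asarray(which)
    out = []
    for s in range(0, len(which), batch):
        sel = which[s : s + batch]
        out.append(model.forward(phi_aug[idx_c[sel]], phi_aug[idx_s[sel]]).copy())
    return np.concatenate(out, axis=0)


def predict_with_revcomp(
    model: EchoModel, encoder: SequenceEncoder, X: np.ndarray,
    idx_c: np.ndarray, idx_s: np.ndarray, which=None, batch: int = 256,
) -> np.ndarray:
    """Average the forward passes on the original and reverse-complement strands.

    The reverse-complement pass re-encodes every sequence (centers and
    neighbors alike) before sampling, so both strands contribute
    symmetrically; off by default elsewhere in the pipeline.
    """
    from .sampling import augment_hidden

    phi = encode_all(encoder, X, batch)
    Xrc = np.stack([reverse_complement(x) for x in X])
    phi_rc = encode_all(encoder, Xrc, batch)
    p1 = predict(model, augment_hidden(phi), idx_c, idx_s, which, batch)
    p2 = predict(model, augment_hidden(phi_rc), idx_c, idx_s, which, batch)
    return 0.5 * (p1 + p2)


def save_encoder(path, encoder: SequenceEncoder, head: nn.Dense,
                 train_config: TrainConfig) -> None:
    """Archive the frozen encoder plus the pretraining head and configs."""
    arrays = {f"enc_{k}": p.value for k, p in enumerate(encoder.parameters())}
    arrays |= {f"head_{k}": p.value for k, p in enumerate(head.parameters())}
    meta = {"model_config": encoder.cfg.to_dict(), "train_config": train_config.to_dict()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_encoder(path):
    data = np.load(path)
    meta = json.loads(bytes(data["__meta__"]).decode())
    cfg = ModelConfig(**{k: tuple(v) if isinstance(v, list) else v
                         for k, v in meta["model_config"].items()})
    rng = np.random.default_rng(0)
    encoder = SequenceEncoder(cfg, rng)
    for k, p in enumerate(encoder.parameters()):
        p.value[...] = data[f"enc_{k}"]
    encoder.freeze()
    head = nn.Dense(cfg.K, cfg.n_features, rng=rng)
    for k, p in enumerate(head.parameters()):
        p.value[...] = data[f"head_{k}"]
    return encoder, head, meta


def save_checkpoint(path, model: EchoModel, encoder: SequenceEncoder | None,
                    train_config: TrainConfig, extra: dict | None = None) -> None:
    """Single-file archive: all parameters plus the full configuration."""
    arrays = {}
    for k, p in enumerate(model.parameters()):
        arrays[f"model_{k}"] = p.value
    if encoder is not None:
        for k, p in enumerate(encoder.parameters()):
            arrays[f"encoder_{k}"] = p.value
    meta = {
        "model_config": model.cfg.to_dict(),
        "train_config": train_config.to_dict(),
        "extra": extra or {},
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path):
    """Restore (model, encoder_or_None, meta) from `save_checkpoint` output."""
    data = np.load(path)
    meta = json.loads(bytes(data["__meta__"]).decode())
    cfg = ModelConfig(**{k: tuple(v) if isinstance(v, list) else v
                         for k, v in meta["model_config"].items()})
    rng = np.random.default_rng(0)
    model = EchoModel(cfg, rng)
    for k, p in enumerate(model.parameters()):
        p.value[...] = data[f"model_{k}"]
    encoder = None
    if "encoder_0" in data:
        encoder = SequenceEncoder(cfg, rng)
        for k, p in enumerate(encoder.parameters()):
            p.value[...] = data[f"encoder_{k}"]
        encoder.freeze()
    return model, encoder, meta
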