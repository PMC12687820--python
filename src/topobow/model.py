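"""Attention-guided MLP classifier over fused feature vectors.

The 950-dim standardized input is cut into 5 equal segments of 190
features, treated as a 5-token sequence.  A single 10-head self-attention
layer (scaled dot-product, head width 19, learned query/key/value and
output projections, 0.1 attention dropout) lets each segment attend to
the others; the re-assembled sequence is flattened back to 950 and passed
through a GELU MLP head (1024 -> 512 -> 256 -> 1024 with dropouts
0.4/0.4/0.3/0.2) into a 2-unit linear output trained with softmax
cross-entropy.  During training, Gaussian noise (sd 0.05) is added to the
input as feature-level augmentation; noise and dropout are disabled at
inference, so eval-mode forward passes are deterministic.

Optimization is AdamW (decoupled weight decay) with cosine-annealed
learning rate and best-validation-accuracy snapshotting.  The network is
implemented directly in NumPy: forward passes cache intermediates and
gradients are computed analytically, which keeps the whole package free
of a deep-learning runtime while training in seconds at these problem
sizes.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

DTYPE = np.float32


@dataclass(frozen=True)
class TopoBowNetConfig:
    """Architecture and training hyperparameters."""

    input_dim: int = 950
    n_segments: int = 5
    n_heads: int = 10
    attn_dropout: float = 0.1
    noise_sd: float = 0.05
    head_layers: tuple = ((1024, 0.4), (512, 0.4), (256, 0.3), (1024, 0.2))
    output_units: int = 2
    epochs: int = 500
    learning_rate: float = 1e-4
    weight_decay: float = 0.01
    batch_size: int = 32
    early_stop_patience: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_dim % self.n_segments:
            raise ValueError(
                f"input_dim {self.input_dim} not divisible by "
                f"{self.n_segments} segments"
            )
        if self.segment_len % self.n_heads:
            raise ValueError(
                f"segment length {self.segment_len} not divisible by "
                f"{self.n_heads} heads"
            )

    @property
    def segment_len(self) -> int:
        return self.input_dim // self.n_segments

    @property
    def head_dim(self) -> int:
        return self.segment_len // self.n_heads


def _gelu(z: np.ndarray) -> np.ndarray:
    return 0.5 * z * (1.0 + erf(z / np.sqrt(2.0, dtype=DTYPE)))


def _gelu_grad(z: np.ndarray) -> np.ndarray:
    phi = np.exp(-0.5 * z * z) / np.sqrt(2.0 * np.pi)
    return 0.5 * (1.0 + erf(z / np.sqrt(2.0, dtype=DTYPE))) + z * phi.astype(DTYPE)


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class TopoBowNet:
    """The attention + MLP network with analytic gradients."""

    def __init__(self, config: TopoBowNetConfig):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.params: dict[str, np.ndarray] = {}
        L = config.segment_len
        for name in ("Wq", "Wk", "Wv", "Wo"):
            self.params[name] = self._glorot(L, L)
            self.params["b" + name[1]] = np.zeros(L, dtype=DTYPE)
        widths = [config.input_dim] + [w for w, _ in config.head_layers]
        for i, (w_out, _) in enumerate(config.head_layers):
            self.params[f"W{i}"] = self._glorot(widths[i], w_out)
            self.params[f"c{i}"] = np.zeros(w_out, dtype=DTYPE)
        self.params["Wout"] = self._glorot(widths[-1], config.output_units)
        self.params["cout"] = np.zeros(config.output_units, dtype=DTYPE)

    def _glorot(self, n_in: int, n_out: int) -> np.ndarray:
        lim = np.sqrt(6.0 / (n_in + n_out))
        return self.rng.uniform(-lim, lim, size=(n_in, n_out)).astype(DTYPE)

    # ---- forward -----------------------------------------------------

    def forward(self, X: np.ndarray, train: bool = False,
                return_cache: bool = False):
        """Class scores (n, 2) and head-averaged attention (n, S, S).

        In train mode, Gaussian input noise and the configured dropouts
        are applied (drawn from the model's own rng); in eval mode the
        pass is a pure function of the input.
        """
        cfg = self.config
        p = self.params
        X = np.ascontiguousarray(np.asarray(X, dtype=DTYPE))
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != cfg.input_dim:
            raise ValueError(f"expected input width {cfg.input_dim}, "
                             f"got {X.shape[1]}")
        n = X.shape[0]
        S, L, H, Dh = cfg.n_segments, cfg.segment_len, cfg.n_heads, cfg.head_dim
        cache: dict = {}

        if train and cfg.noise_sd > 0:
            X = X + self.rng.normal(0.0, cfg.noise_sd, X.shape).astype(DTYPE)
        T = X.reshape(n, S, L)
        Q = T @ p["Wq"] + p["bq"]
        K = T @ p["Wk"] + p["bk"]
        V = T @ p["Wv"] + p["bv"]

        def heads(M):  # (n, S, L) -> (n, H, S, Dh)
            return M.reshape(n, S, H, Dh).transpose(0, 2, 1, 3)

        Qh, Kh, Vh = heads(Q), heads(K), heads(V)
        scores = Qh @ Kh.transpose(0, 1, 3, 2) / np.sqrt(DTYPE(Dh))
        A = softmax(scores)
        Ad = A
        if train and cfg.attn_dropout > 0:
            mask = (self.rng.random(A.shape) >= cfg.attn_dropout)
            Ad = A * mask.astype(DTYPE) / DTYPE(1.0 - cfg.attn_dropout)
            cache["attn_mask"] = mask
        Ch = Ad @ Vh  # (n, H, S, Dh)
        C = Ch.transpose(0, 2, 1, 3).reshape(n, S, L)
        O = C @ p["Wo"] + p["bo"]
        F = O.reshape(n, cfg.input_dim)

        h = F
        acts = []
        for i, (_, drop) in enumerate(cfg.head_layers):
            z = h @ p[f"W{i}"] + p[f"c{i}"]
            a = _gelu(z)
            if train and drop > 0:
                m = (self.rng.random(a.shape) >= drop)
                out = a * m.astype(DTYPE) / DTYPE(1.0 - drop)
            else:
                m, out = None, a
            acts.append((h, z, a, m))
            h = out
        logits = h @ p["Wout"] + p["cout"]

        if return_cache:
            cache.update(T=T, Qh=Qh, Kh=Kh, Vh=Vh, A=A, Ad=Ad, Ch=Ch, C=C,
                         F=F, acts=acts, h_last=h)
            return logits, A.mean(axis=1), cache
        return logits, A.mean(axis=1)

    # ---- backward ----------------------------------------------------

    def backward(self, dlogits: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        """Gradients of the loss w.r.t. every parameter."""
        cfg = self.config
        p = self.params
        n = dlogits.shape[0]
        S, L, H, Dh = cfg.n_segments, cfg.segment_len, cfg.n_heads, cfg.head_dim
        g: dict[str, np.ndarray] = {}

        g["Wout"] = cache["h_last"].T @ dlogits
        g["cout"] = dlogits.sum(axis=0)
        dh = dlogits @ p["Wout"].T
        for i in reversed(range(len(cfg.head_layers))):
            h_in, z, _a, m = cache["acts"][i]
            drop = cfg.head_layers[i][1]
            if m is not None:
                dh = dh * m.astype(DTYPE) / DTYPE(1.0 - drop)
            dz = dh * _gelu_grad(z)
            g[f"W{i}"] = h_in.T @ dz
            g[f"c{i}"] = dz.sum(axis=0)
            dh = dz @ p[f"W{i}"].T

        dO = dh.reshape(n, S, L)
        C2 = cache["C"].reshape(n * S, L)
        dO2 = dO.reshape(n * S, L)
        g["Wo"] = C2.T @ dO2
        g["bo"] = dO2.sum(axis=0)
        dC = dO @ p["Wo"].T
        dCh = dC.reshape(n, S, H, Dh).transpose(0, 2, 1, 3)

        dAd = dCh @ cache["Vh"].transpose(0, 1, 3, 2)
        dVh = cache["Ad"].transpose(0, 1, 3, 2) @ dCh
        if "attn_mask" in cache:
            dA = dAd * cache["attn_mask"].astype(DTYPE) / DTYPE(1.0 - cfg.attn_dropout)
        else:
            dA = dAd
        A = cache["A"]
        dscores = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
        dscores /= np.sqrt(DTYPE(Dh))
        dQh = dscores @ cache["Kh"]
        dKh = dscores.transpose(0, 1, 3, 2) @ cache["Qh"]

        def unheads(M):  # (n, H, S, Dh) -> (n*S, L)
            return M.transpose(0, 2, 1, 3).reshape(n * S, L)

        T2 = cache["T"].reshape(n * S, L)
        for name, dM in (("Wq", dQh), ("Wk", dKh), ("Wv", dVh)):
            d2 = unheads(dM)
            g[name] = T2.T @ d2
            g["b" + name[1]] = d2.sum(axis=0)
        return g

    # ---- loss --------------------------------------------------------

    @staticmethod
    def loss_and_dlogits(logits: np.ndarray, y: np.ndarray):
        """Mean softmax cross-entropy and its gradient w.r.t. logits."""
        n = logits.shape[0]
        probs = softmax(logits)
        loss = -np.log(np.maximum(probs[np.arange(n), y], 1e-12)).mean()
        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        return float(loss), (dlogits / n).astype(DTYPE)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        logits, _ = self.forward(X, train=False)
        return softmax(logits)

    def attention_map(self, X: np.ndarray) -> np.ndarray:
        """Per-sample attention mass received by each segment (rows sum 1).

        Head-averaged attention is additionally averaged over query
        segments, giving for each sample the share of attention each of
        the S segments receives.
        """
        _, attn = self.forward(X, train=False)
        return attn.mean(axis=1)


@dataclass
class TrainedModel:
    """A fitted network plus its config, history and best-epoch snapshot."""

    model: TopoBowNet
    config: TopoBowNetConfig
    history: dict = field(default_factory=dict)
    best_epoch: int = -1
    best_val_accuracy: float = float("nan")

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def attention_map(self, X: np.ndarray) -> np.ndarray:
        return self.model.attention_map(X)


def cosine_lr(base_lr: float, epoch: int, total_epochs: int) -> float:
    """Cosine annealing from base_lr at epoch 0 toward ~0 at the end."""
    return base_lr * 0.5 * (1.0 + np.cos(np.pi * epoch / max(1, total_epochs)))


class _AdamW:
    def __init__(self, params: dict, weight_decay: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0
        self.wd = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps

    def step(self, params: dict, grads: dict, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, gk in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * gk
            self.v[k] = b2 * self.v[k] + (1 - b2) * gk * gk
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= (lr * mhat / (np.sqrt(vhat) + self.eps)).astype(DTYPE)
            if self.wd > 0 and k.startswith("W"):  # decoupled decay, weights only
                params[k] -= DTYPE(lr * self.wd) * params[k]


def train(train_X: np.ndarray, train_y: np.ndarray,
          val_X: np.ndarray | None = None, val_y: np.ndarray | None = None,
          config: TopoBowNetConfig | None = None) -> TrainedModel:
    """Fit the network by AdamW with cosine annealing and snapshotting.

    Expects standardized features and binary labels.  The snapshot with
    the highest validation accuracy is restored into the returned model;
    without a validation set the final parameters are kept.
    """
    cfg = config or TopoBowNetConfig()
    train_y = np.asarray(train_y, dtype=int)
    if len(np.unique(train_y)) < 2:
        raise ValueError("training set must contain both classes")
    net = TopoBowNet(cfg)
    opt = _AdamW(net.params, cfg.weight_decay)
    n = len(train_y)
    history = {"loss": [], "val_accuracy": [], "lr": []}
    best_acc, best_epoch, best_params = -1.0, -1, None
    since_best = 0

    for epoch in range(cfg.epochs):
        lr = cosine_lr(cfg.learning_rate, epoch, cfg.epochs)
        order = net.rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            logits, _, cache = net.forward(train_X[idx], train=True,
                                           return_cache=True)
            loss, dlogits = net.loss_and_dlogits(logits, train_y[idx])
            grads = net.backward(dlogits, cache)
            opt.step(net.params, grads, lr)
            epoch_loss += loss * len(idx)
        history["loss"].append(epoch_loss / n)
        history["lr"].append(lr)
        if val_X is not None and len(val_X):
            acc = float((net.predict_proba(val_X).argmax(axis=1)
                         == np.asarray(val_y)).mean())
            history["val_accuracy"].append(acc)
            if acc > best_acc:
                best_acc, best_epoch = acc, epoch
                best_params = {k: v.copy() for k, v in net.params.items()}
                since_best = 0
            else:
                since_best += 1
                if (cfg.early_stop_patience is not None
                        and since_best >= cfg.early_stop_patience):
                    break

    if best_params is not None:
        net.params = best_params
    return TrainedModel(model=net, config=cfg, history=history,
                        best_epoch=best_epoch, best_val_accuracy=best_acc)
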