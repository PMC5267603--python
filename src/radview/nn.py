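"""A small, fully deterministic numpy CNN.

This is the numerical core behind the transfer-learning harness: a stack of
3x3 conv + ReLU + 2x2 max-pool blocks (the *extractor*) followed by two
fully connected layers (the *head*), trained with SGD or SGD with Nesterov
momentum, weight decay, and a step-decayed learning rate. Everything is
float64 numpy with explicit per-image forward passes, so same seed + config
gives bit-identical parameters, and batched inference equals one-at-a-time
inference exactly.

Parameter names partition the network: ``conv{i}.*`` belong to the
extractor, ``fc{i}.*`` to the head. Freezing the extractor is implemented by
simply excluding its names from the trainable set — frozen tensors are never
touched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

HEAD_PREFIX = "fc"


def is_head_param(name: str) -> bool:
    return name.startswith(HEAD_PREFIX)


@dataclass(frozen=True)
class ArchConfig:
    """Shape of the toy CNN; input_size must be divisible by 2**len(conv_channels)."""

    input_size: int = 64
    in_channels: int = 1
    conv_channels: tuple[int, ...] = (8, 16, 32)
    kernel: int = 3
    fc_hidden: int = 32
    n_classes: int = 2

    def __post_init__(self) -> None:
        if self.input_size % (2 ** len(self.conv_channels)) != 0:
            raise ValueError("input_size must be divisible by 2^(number of conv blocks)")
        if self.kernel % 2 != 1:
            raise ValueError("kernel must be odd")

    @property
    def tag(self) -> str:
        chans = "-".join(map(str, self.conv_channels))
        return f"cnn{self.input_size}x{self.in_channels}c[{chans}]fc{self.fc_hidden}x{self.n_classes}"

    @property
    def feature_dim(self) -> int:
        side = self.input_size // (2 ** len(self.conv_channels))
        return self.conv_channels[-1] * side * side


def init_params(arch: ArchConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """He-normal initialization, seeded through ``rng``."""
    params: dict[str, np.ndarray] = {}
    cin = arch.in_channels
    k = arch.kernel
    for i, cout in enumerate(arch.conv_channels):
        fan_in = cin * k * k
        params[f"conv{i}.W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, k, k))
        params[f"conv{i}.b"] = np.zeros(cout)
        cin = cout
    d = arch.feature_dim
    params["fc1.W"] = rng.normal(0.0, np.sqrt(2.0 / d), size=(d, arch.fc_hidden))
    params["fc1.b"] = np.zeros(arch.fc_hidden)
    params["fc2.W"] = rng.normal(0.0, np.sqrt(2.0 / arch.fc_hidden), size=(arch.fc_hidden, arch.n_classes))
    params["fc2.b"] = np.zeros(arch.n_classes)
    return params


# ------------------------------------------------------------------ layers

def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k), axis=(1, 2))  # (C, H, W, k, k)
    return win.transpose(1, 2, 0, 3, 4).reshape(h * w, c * k * k)


def _col2im(dcols: np.ndarray, shape: tuple[int, int, int], k: int) -> np.ndarray:
    c, h, w = shape
    p = k // 2
    dxp = np.zeros((c, h + 2 * p, w + 2 * p))
    d = dcols.reshape(h, w, c, k, k)
    for di in range(k):
        for dj in range(k):
            dxp[:, di : di + h, dj : dj + w] += d[:, :, :, di, dj].transpose(2, 0, 1)
    return dxp[:, p : p + h, p : p + w]


def _pool_fwd(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    c, h, w = x.shape
    xr = x.reshape(c, h // 2, 2, w // 2, 2).transpose(0, 1, 3, 2, 4).reshape(c, h // 2, w // 2, 4)
    idx = xr.argmax(-1)
    out = np.take_along_axis(xr, idx[..., None], -1)[..., 0]
    return out, idx


def _pool_bwd(dout: np.ndarray, idx: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    c, h, w = shape
    d4 = np.zeros((c, h // 2, w // 2, 4))
    np.put_along_axis(d4, idx[..., None], dout[..., None], -1)
    return d4.reshape(c, h // 2, w // 2, 2, 2).transpose(0, 1, 3, 2, 4).reshape(c, h, w)


def forward_one(params: dict[str, np.ndarray], arch: ArchConfig, x: np.ndarray):
    """Forward pass on one image (C, H, W) -> (logits, cache)."""
    cache = []
    h = x
    for i in range(len(arch.conv_channels)):
        W = params[f"conv{i}.W"]
        b = params[f"conv{i}.b"]
        in_shape = h.shape
        cols = _im2col(h, arch.kernel)
        pre = (cols @ W.reshape(W.shape[0], -1).T + b).T.reshape(W.shape[0], in_shape[1], in_shape[2])
        act = np.maximum(pre, 0.0)
        pooled, idx = _pool_fwd(act)
        cache.append((in_shape, cols, pre, idx))
        h = pooled
    feat_shape = h.shape
    flat = h.reshape(-1)
    z1 = flat @ params["fc1.W"] + params["fc1.b"]
    a1 = np.maximum(z1, 0.0)
    logits = a1 @ params["fc2.W"] + params["fc2.b"]
    cache.append((flat, z1, a1, feat_shape))
    return logits, cache


def backward_one(params: dict[str, np.ndarray], arch: ArchConfig, cache, dlogits: np.ndarray) -> dict[str, np.ndarray]:
    grads: dict[str, np.ndarray] = {}
    flat, z1, a1, feat_shape = cache[-1]
    grads["fc2.W"] = np.outer(a1, dlogits)
    grads["fc2.b"] = dlogits
    da1 = params["fc2.W"] @ dlogits
    dz1 = da1 * (z1 > 0)
    grads["fc1.W"] = np.outer(flat, dz1)
    grads["fc1.b"] = dz1
    dh = (params["fc1.W"] @ dz1).reshape(feat_shape)
    for i in reversed(range(len(arch.conv_channels))):
        in_shape, cols, pre, idx = cache[i]
        dact = _pool_bwd(dh, idx, pre.shape)
        dpre = dact * (pre > 0)
        f = dpre.shape[0]
        dpre2 = dpre.reshape(f, -1)  # (F, HW)
        wmat = params[f"conv{i}.W"].reshape(f, -1)
        grads[f"conv{i}.W"] = (dpre2 @ cols).reshape(params[f"conv{i}.W"].shape)
        grads[f"conv{i}.b"] = dpre2.sum(axis=1)
        dcols = dpre2.T @ wmat  # (HW, C*k*k)
        dh = _col2im(dcols, in_shape, arch.kernel)
    return grads


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max()
    e = np.exp(z)
    return e / e.sum()


def predict_proba(params: dict[str, np.ndarray], arch: ArchConfig, X: np.ndarray) -> np.ndarray:
    """Class probabilities for X of shape (N, C, H, W); images are processed
    one at a time so results are independent of batching."""
    out = np.empty((len(X), arch.n_classes))
    for i in range(len(X)):
        logits, _ = forward_one(params, arch, X[i])
        out[i] = softmax(logits)
    return out


def lr_at_epoch(base_lr: float, epoch: int, decay: float = 0.1, every: int = 10) -> float:
    """Step schedule: base_lr reduced by ``decay`` every ``every`` epochs (0-based)."""
    return base_lr * decay ** (epoch // every)


def sgd_train(
    params: dict[str, np.ndarray],
    arch: ArchConfig,
    X: np.ndarray,
    y: np.ndarray,
    *,
    epochs: int,
    batch_size: int,
    base_lr: float,
    momentum: float = 0.9,
    weight_decay: float = 0.0005,
    nesterov: bool = True,
    trainable: set[str] | None = None,
    seed: int = 0,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> list[dict]:
    """Train in place; returns a per-epoch history of lr / loss / val accuracy.

    Only parameters named in ``trainable`` are updated (all by default);
    frozen tensors are never written to, so they remain bit-identical.
    """
    if trainable is None:
        trainable = set(params)
    rng = np.random.default_rng(seed)
    velocity = {k: np.zeros_like(params[k]) for k in trainable}
    n = len(X)
    history: list[dict] = []
    for epoch in range(epochs):
        lr = lr_at_epoch(base_lr, epoch)
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            gsum = {k: np.zeros_like(params[k]) for k in trainable}
            for j in idx:
                logits, cache = forward_one(params, arch, X[j])
                p = softmax(logits)
                epoch_loss += -np.log(max(p[y[j]], 1e-300))
                dlogits = p.copy()
                dlogits[y[j]] -= 1.0
                grads = backward_one(params, arch, cache, dlogits)
                for k in trainable:
                    gsum[k] += grads[k]
            m = len(idx)
            for k in trainable:
                g = gsum[k] / m + weight_decay * params[k]
                velocity[k] = momentum * velocity[k] + g
                step = g + momentum * velocity[k] if nesterov else velocity[k]
                params[k] -= lr * step
        entry = {"epoch": epoch, "lr": lr, "train_loss": epoch_loss / n}
        if X_val is not None and y_val is not None:
            probs = predict_proba(params, arch, X_val)
            entry["val_accuracy"] = float((probs.argmax(1) == y_val).mean())
        history.append(entry)
    return history
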