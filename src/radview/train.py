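"""Transfer-learning harness: pretrain on generic images, fine-tune on radiographs.

Two fine-tuning regimes are supported, mirroring standard practice:

* ``fc_only`` — the convolutional extractor is frozen (bit-identical before
  and after) and only the fully connected head is retrained, at a base
  learning rate of 0.005;
* ``all_layers`` — every parameter is trainable, at a base learning rate of
  0.0005. This regime requires an augmented fine-tuning set: with original
  images only there are too few examples relative to the parameter count,
  so the configuration is rejected.

Both regimes use (Nesterov) SGD with mini-batches of 24, momentum 0.9,
weight decay 0.0005, and a learning rate reduced tenfold every ten epochs,
for 30 epochs by default. Inputs are normalized by /255 followed by
subtraction of the training-set mean, which is stored on the model so that
prediction is independent of the evaluation batch composition.
"""

from __future__ import annotations

import copy
import hashlib
from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .evaluate import Prediction
from .records import ImageRecord

RADIOGRAPH_CLASSES = ("lateral", "frontal")  # index 1 = frontal, so PFI = probs[1]

REGIMES = ("fc_only", "all_layers")
PRETRAIN_MODES = ("none", "color_generic", "greyscale_generic")
OPTIMIZERS = ("nesterov", "sgd")


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    regime: str = "fc_only"
    use_augmented: bool = True
    pretrain_mode: str = "greyscale_generic"
    base_lr: float | None = None  # default depends on regime
    epochs: int = 30
    batch_size: int = 24
    momentum: float = 0.9
    weight_decay: float = 0.0005
    optimizer: str = "nesterov"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ConfigurationError(f"unknown regime {self.regime!r}")
        if self.pretrain_mode not in PRETRAIN_MODES:
            raise ConfigurationError(f"unknown pretrain mode {self.pretrain_mode!r}")
        if self.optimizer not in OPTIMIZERS:
            raise ConfigurationError(f"unknown optimizer {self.optimizer!r}")
        if self.base_lr is None:
            object.__setattr__(self, "base_lr", 0.005 if self.regime == "fc_only" else 0.0005)
        if self.base_lr <= 0:
            raise ConfigurationError("base_lr must be positive")
        if self.batch_size < 1 or self.epochs < 1:
            raise ConfigurationError("batch_size and epochs must be at least 1")
        if self.regime == "all_layers" and not self.use_augmented:
            raise ConfigurationError(
                "all-layers fine-tuning on un-augmented data is rejected: too few "
                "images relative to the number of trainable parameters"
            )

    def lr_schedule(self) -> list[float]:
        return [nn.lr_at_epoch(self.base_lr, e) for e in range(self.epochs)]


@dataclass
class ModelState:
    """Named parameter tensors plus the metadata needed to reuse them."""

    params: dict[str, np.ndarray]
    arch: nn.ArchConfig
    classes: tuple[str, ...]
    input_mean: float = 0.0
    history: list = field(default_factory=list)

    @property
    def arch_tag(self) -> str:
        return self.arch.tag

    @property
    def extractor_params(self) -> dict[str, np.ndarray]:
        return {k: v for k, v in self.params.items() if not nn.is_head_param(k)}

    @property
    def head_params(self) -> dict[str, np.ndarray]:
        return {k: v for k, v in self.params.items() if nn.is_head_param(k)}

    def param_hash(self) -> str:
        h = hashlib.sha256()
        for name in sorted(self.params):
            h.update(name.encode())
            h.update(np.ascontiguousarray(self.params[name]).tobytes())
        return h.hexdigest()

    def copy(self) -> "ModelState":
        return ModelState(
            params={k: v.copy() for k, v in self.params.items()},
            arch=self.arch,
            classes=self.classes,
            input_mean=self.input_mean,
            history=list(self.history),
        )


def _as_batches(X: np.ndarray, in_channels: int) -> np.ndarray:
    """uint8 (N,H,W) or (N,H,W,3) -> float (N,C,H,W) scaled to [0,1]."""
    X = np.asarray(X)
    if X.ndim == 3:
        out = X[:, None, :, :].astype(float)
    elif X.ndim == 4 and X.shape[-1] == 3:
        out = X.transpose(0, 3, 1, 2).astype(float)
    else:
        raise ValueError(f"cannot interpret image stack of shape {X.shape}")
    if out.shape[1] != in_channels:
        raise ValueError(f"model expects {in_channels}-channel input, got {out.shape[1]}")
    return out / 255.0


def pretrain(
    generic_images: np.ndarray,
    labels: np.ndarray,
    config: TrainConfig,
    arch: nn.ArchConfig | None = None,
    class_names: tuple[str, ...] | None = None,
) -> ModelState:
    """Train a model on a generic labeled image set (or just initialize it).

    ``pretrain_mode='none'`` returns a randomly initialized, untrained model;
    ``greyscale_generic`` expects (N, H, W) input, ``color_generic``
    (N, H, W, 3).
    """
    labels = np.asarray(labels)
    class_ids = np.unique(labels)
    if config.pretrain_mode != "none" and len(class_ids) < 2:
        raise ValueError("pretraining requires at least 2 classes")
    in_channels = 3 if config.pretrain_mode == "color_generic" else 1
    if arch is None:
        size = generic_images.shape[1]
        arch = nn.ArchConfig(input_size=size, in_channels=in_channels, n_classes=max(len(class_ids), 2))
    rng = np.random.default_rng(config.seed)
    params = nn.init_params(arch, rng)
    model = ModelState(
        params=params,
        arch=arch,
        classes=class_names or tuple(f"class{c}" for c in range(arch.n_classes)),
    )
    if config.pretrain_mode == "none":
        return model
    X = _as_batches(generic_images, in_channels)
    model.input_mean = float(X.mean())
    X = X - model.input_mean
    y = np.searchsorted(class_ids, labels)
    model.history = nn.sgd_train(
        model.params,
        arch,
        X,
        y,
        epochs=config.epochs,
        batch_size=config.batch_size,
        base_lr=config.base_lr,
        momentum=config.momentum,
        weight_decay=config.weight_decay,
        nesterov=config.optimizer == "nesterov",
        trainable=None,  # pretraining fine-tunes all layers
        seed=config.seed,
    )
    return model


def adapt_to_greyscale(model: ModelState) -> ModelState:
    """Collapse a 3-channel model to 1-channel input by averaging the
    first conv layer's input-channel kernels."""
    if model.arch.in_channels == 1:
        return model
    new = model.copy()
    new.params["conv0.W"] = model.params["conv0.W"].mean(axis=1, keepdims=True)
    new.arch = replace(model.arch, in_channels=1)
    return new


def _stack_records(records: list[ImageRecord], arch: nn.ArchConfig) -> tuple[np.ndarray, np.ndarray]:
    pixels, labels = [], []
    for rec in records:
        if rec.pixels is None:
            raise ValueError(f"record {rec.image_id} has no pixels")
        if rec.pixels.shape != (arch.input_size, arch.input_size):
            raise ValueError(
                f"record {rec.image_id} has shape {rec.pixels.shape}; "
                f"model expects {(arch.input_size, arch.input_size)}"
            )
        if rec.label not in RADIOGRAPH_CLASSES:
            raise ValueError(f"record {rec.image_id} has non-binary label {rec.label!r}")
        pixels.append(rec.pixels)
        labels.append(RADIOGRAPH_CLASSES.index(rec.label))
    return np.stack(pixels), np.array(labels, dtype=np.int64)


def finetune(
    model: ModelState,
    radiographs: list[ImageRecord],
    config: TrainConfig,
    val_records: list[ImageRecord] | None = None,
) -> ModelState:
    """Fine-tune a (pre)trained model on labeled radiographs.

    The head is re-initialized for the frontal/lateral task (seeded); the
    extractor is carried over and, under ``fc_only``, never modified. A
    3-channel pretrained model is first collapsed to greyscale input.
    """
    if model.arch.in_channels == 3:
        model = adapt_to_greyscale(model)
    new = model.copy()
    new.classes = RADIOGRAPH_CLASSES
    if new.arch.n_classes != len(RADIOGRAPH_CLASSES):
        new.arch = replace(new.arch, n_classes=len(RADIOGRAPH_CLASSES))

    rng = np.random.default_rng(config.seed)
    fresh = nn.init_params(new.arch, rng)
    for name in list(new.params):
        if nn.is_head_param(name):
            new.params[name] = fresh[name]

    X_raw, y = _stack_records(radiographs, new.arch)
    X = _as_batches(X_raw, 1)
    new.input_mean = float(X.mean())
    X = X - new.input_mean

    X_val = y_val = None
    if val_records:
        Xv_raw, y_val = _stack_records(val_records, new.arch)
        X_val = _as_batches(Xv_raw, 1) - new.input_mean

    trainable = set(new.params) if config.regime == "all_layers" else {
        k for k in new.params if nn.is_head_param(k)
    }
    new.history = nn.sgd_train(
        new.params,
        new.arch,
        X,
        y,
        epochs=config.epochs,
        batch_size=config.batch_size,
        base_lr=config.base_lr,
        momentum=config.momentum,
        weight_decay=config.weight_decay,
        nesterov=config.optimizer == "nesterov",
        trainable=trainable,
        seed=config.seed,
        X_val=X_val,
        y_val=y_val,
    )
    return new


def predict(model: ModelState, images: list[ImageRecord]) -> list[Prediction]:
    """Probability of frontal image (PFI) for each record.

    Images are evaluated one at a time internally, so batching never changes
    the scores.
    """
    if "frontal" not in model.classes:
        raise ValueError("model was not fine-tuned for frontal/lateral classification")
    frontal_idx = model.classes.index("frontal")
    preds: list[Prediction] = []
    for rec in images:
        if rec.pixels is None:
            raise ValueError(f"record {rec.image_id} has no pixels")
        if rec.pixels.shape != (model.arch.input_size, model.arch.input_size):
            raise ValueError(
                f"record {rec.image_id} has shape {rec.pixels.shape}; "
                f"model expects {(model.arch.input_size, model.arch.input_size)}"
            )
        x = rec.pixels[None, :, :].astype(float) / 255.0 - model.input_mean
        probs = nn.predict_proba(model.params, model.arch, x[None] if x.ndim == 3 else x)
        preds.append(Prediction(image_id=rec.image_id, pfi=float(probs[0, frontal_idx]), label=rec.label))
    return preds
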