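"""Procedural phantom radiographs and generic pretraining images.

The phantoms are stylized chest radiographs built from ellipses and bars:

* **frontal** — two laterally symmetric dark elliptical lung fields flanking
  a bright central mediastinal/vertebral column, so the image is mirror
  symmetric about its vertical midline (before jitter/noise);
* **lateral** — a single large dark lung region with a bright vertical
  column near one lateral (posterior) edge, hence strongly asymmetric.

The geometry, not anatomy, carries the class signal: a left/right mirror
correlation already separates the two views, which guarantees the training
harness has learnable structure at the configured noise levels.

All generators are seeded and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import rotate as _sk_rotate

from .records import ImageRecord

# Grey levels of the stylized anatomy (8-bit scale).
_BACKGROUND = 150
_LUNG = 60
_COLUMN = 220


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of one phantom radiograph.

    noise_sd is the sd of additive Gaussian pixel noise in grey levels;
    rotation_jitter (degrees) and intensity_jitter (fraction) randomize pose
    and exposure. With all three at 0 the output is the pure geometry.
    """

    width: int = 64
    height: int = 64
    view: str = "frontal"
    noise_sd: float = 8.0
    rotation_jitter: float = 0.0
    intensity_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 32 or self.height < 32:
            raise ValueError("phantom must be at least 32x32 pixels")
        if self.view not in ("frontal", "lateral"):
            raise ValueError(f"unknown view {self.view!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.intensity_jitter < 1:
            raise ValueError("intensity_jitter must be in [0, 1)")
        if self.rotation_jitter < 0:
            raise ValueError("rotation_jitter must be non-negative")


def _frontal_geometry(w: int, h: int) -> np.ndarray:
    y, x = np.mgrid[0:h, 0:w].astype(float)
    cx = (w - 1) / 2.0
    dx = np.abs(x - cx)  # symmetric coordinate => exact mirror symmetry
    img = np.full((h, w), float(_BACKGROUND))
    # mediastinal / vertebral column
    img[dx <= 0.06 * w] = _COLUMN
    # two symmetric lung fields
    lung = (((dx - 0.26 * w) / (0.17 * w)) ** 2 + ((y - 0.50 * h) / (0.32 * h)) ** 2) <= 1.0
    img[lung] = _LUNG
    return img


def _lateral_geometry(w: int, h: int) -> np.ndarray:
    y, x = np.mgrid[0:h, 0:w].astype(float)
    img = np.full((h, w), float(_BACKGROUND))
    # posterior vertebral column near one lateral edge
    img[np.abs(x - 0.82 * w) <= 0.05 * w] = _COLUMN
    # single overlapping lung field, shifted anterior
    lung = (((x - 0.42 * w) / (0.28 * w)) ** 2 + ((y - 0.50 * h) / (0.33 * h)) ** 2) <= 1.0
    img[lung] = _LUNG
    return img


def make_phantom(config: PhantomConfig) -> ImageRecord:
    """Render one 8-bit phantom radiograph; identical config => identical pixels."""
    rng = np.random.default_rng(config.seed)
    w, h = config.width, config.height
    img = _frontal_geometry(w, h) if config.view == "frontal" else _lateral_geometry(w, h)

    if config.rotation_jitter > 0:
        angle = rng.uniform(-config.rotation_jitter, config.rotation_jitter)
        img = _sk_rotate(img, angle, order=1, cval=_BACKGROUND, preserve_range=True)
    if config.intensity_jitter > 0:
        img = img * (1.0 + rng.uniform(-config.intensity_jitter, config.intensity_jitter))
    if config.noise_sd > 0:
        img = img + rng.normal(0.0, config.noise_sd, size=img.shape)

    pixels = np.rint(np.clip(img, 0, 255)).astype(np.uint8)
    return ImageRecord(
        image_id=f"phantom-{config.view}-{config.seed}",
        pixels=pixels,
        label=config.view,
    )


def make_cohort(
    n_patients: int,
    images_per_patient: tuple[int, int] = (1, 2),
    frontal_fraction: float = 2.0 / 3.0,
    seed: int = 0,
    size: int = 64,
    noise_sd: float = 8.0,
    rotation_jitter: float = 2.0,
    intensity_jitter: float = 0.05,
) -> list[ImageRecord]:
    """Generate a patient-structured cohort of labeled phantom radiographs.

    Each patient contributes a uniform number of images in
    ``images_per_patient`` (inclusive), each labeled frontal with probability
    ``frontal_fraction`` (the 2/3 default reflects two-view studies
    contributing one of each view while single-view studies are usually
    frontal). Records carry patient and study identifiers so patient-level
    split stratification is testable.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be at least 1")
    lo, hi = images_per_patient
    if not (1 <= lo <= hi):
        raise ValueError("images_per_patient must be an increasing range from >= 1")
    if not 0.0 <= frontal_fraction <= 1.0:
        raise ValueError("frontal_fraction must be a probability")

    rng = np.random.default_rng(seed)
    records: list[ImageRecord] = []
    for p in range(n_patients):
        patient_id = f"pt{p:05d}"
        n_images = int(rng.integers(lo, hi + 1))
        for j in range(n_images):
            view = "frontal" if rng.random() < frontal_fraction else "lateral"
            cfg = PhantomConfig(
                width=size,
                height=size,
                view=view,
                noise_sd=noise_sd,
                rotation_jitter=rotation_jitter,
                intensity_jitter=intensity_jitter,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            rec = make_phantom(cfg)
            records.append(
                ImageRecord(
                    image_id=f"{patient_id}-s{j}-img",
                    pixels=rec.pixels,
                    label=view,
                    patient_id=patient_id,
                    study_id=f"{patient_id}-s{j}",
                )
            )
    return records


def make_generic_set(
    n_per_class: int,
    size: int = 64,
    channels: int = 1,
    seed: int = 0,
    noise_sd: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Generic two-class shape-discrimination images for pretraining.

    Class 0 is a filled disc, class 1 a filled axis-aligned square frame, at
    randomized position/scale on a dim background — a stand-in for a generic
    (non-radiology) labeled corpus. Returns (X, y): X is uint8 of shape
    (N, H, W) for ``channels=1`` or (N, H, W, 3) for ``channels=3``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be at least 1")
    if channels not in (1, 3):
        raise ValueError("channels must be 1 or 3")
    rng = np.random.default_rng(seed)
    y, x = np.mgrid[0:size, 0:size].astype(float)
    images, labels = [], []
    for cls in (0, 1):
        for _ in range(n_per_class):
            img = np.full((size, size), 40.0)
            cx = rng.uniform(0.35, 0.65) * size
            cy = rng.uniform(0.35, 0.65) * size
            r = rng.uniform(0.15, 0.3) * size
            if cls == 0:
                mask = (x - cx) ** 2 + (y - cy) ** 2 <= r**2
            else:
                outer = (np.abs(x - cx) <= r) & (np.abs(y - cy) <= r)
                inner = (np.abs(x - cx) <= 0.5 * r) & (np.abs(y - cy) <= 0.5 * r)
                mask = outer & ~inner
            img[mask] = 200.0
            img += rng.normal(0.0, noise_sd, size=img.shape)
            grey = np.rint(np.clip(img, 0, 255)).astype(np.uint8)
            if channels == 3:
                tint = rng.uniform(0.6, 1.0, size=3)
                rgb = np.clip(grey[..., None].astype(float) * tint, 0, 255)
                images.append(np.rint(rgb).astype(np.uint8))
            else:
                images.append(grey)
            labels.append(cls)
    return np.stack(images), np.array(labels, dtype=np.int64)
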