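"""Raw pixels to model-input form: min-max windowing, greyscale, squash resize.

Min-max windowing maps the observed intensity range of each image linearly
onto the full 8-bit display range, so a 12-bit radiograph and an 8-bit PNG
end up on the same scale. The resize step squashes to a fixed square size
(default 256x256) without preserving aspect ratio. Everything in this module
is deterministic.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import resize as _sk_resize

from .io import to_greyscale
from .records import ImageRecord

TARGET_SIZE = 256


def minmax_window(pixels: np.ndarray) -> np.ndarray:
    """Linearly map [min, max] of the image onto [0, 255] (uint8).

    A constant image maps to all zeros: with no observed range there is no
    information to rescale, so any constant output is as good as another.
    """
    px = np.asarray(pixels, dtype=float)
    if px.size == 0:
        raise ValueError("minmax_window requires at least one pixel")
    lo, hi = px.min(), px.max()
    if hi == lo:
        return np.zeros_like(px, dtype=np.uint8)
    scaled = (px - lo) / (hi - lo) * 255.0
    return np.rint(scaled).astype(np.uint8)


def resize_squash(pixels: np.ndarray, target: int | tuple[int, int] = TARGET_SIZE, order: int = 1) -> np.ndarray:
    """Anisotropically resize to ``target`` (bilinear by default), uint8 output.

    Aspect ratio is deliberately not preserved; non-square inputs are squashed.
    """
    px = np.asarray(pixels, dtype=float)
    if px.size == 0:
        raise ValueError("resize_squash requires a non-empty image")
    shape = (target, target) if np.isscalar(target) else tuple(target)
    if px.shape == shape:
        out = px
    else:
        out = _sk_resize(px, shape, order=order, preserve_range=True, anti_aliasing=False)
    return np.rint(np.clip(out, 0, 255)).astype(np.uint8)


def preprocess_pixels(pixels: np.ndarray, target: int | tuple[int, int] = TARGET_SIZE) -> np.ndarray:
    """Full chain: greyscale collapse -> min-max window -> squash resize."""
    return resize_squash(minmax_window(to_greyscale(pixels)), target)


def preprocess_record(record: ImageRecord, target: int | tuple[int, int] = TARGET_SIZE) -> ImageRecord:
    if record.pixels is None:
        raise ValueError(f"record {record.image_id} has no pixels to preprocess")
    out = preprocess_pixels(record.pixels, target)
    new = ImageRecord(
        image_id=record.image_id,
        pixels=out,
        label=record.label,
        patient_id=record.patient_id,
        study_id=record.study_id,
        split=record.split,
        parent_id=record.parent_id,
        transform_tag=record.transform_tag,
    )
    return new
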