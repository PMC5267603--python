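"""Image and DICOM readers/writers.

PNG is the internal storage format (lossless, so pipelines stay bit-exact);
a JPEG export path mirrors the common archival choice. DICOM support is
limited to monochrome photometric interpretations: the raw pixel array is
returned and min-max windowing is applied downstream exactly as for any
other source.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

# Rec. 601 luma weights for collapsing RGB to greyscale.
_LUMA = np.array([0.299, 0.587, 0.114])


def to_greyscale(pixels: np.ndarray) -> np.ndarray:
    """Collapse an (H, W, 3) array to (H, W) by Rec. 601 luma; pass 2-D through."""
    px = np.asarray(pixels)
    if px.ndim == 2:
        return px
    if px.ndim == 3 and px.shape[2] in (3, 4):
        return px[..., :3].astype(float) @ _LUMA
    raise ValueError(f"cannot interpret array of shape {px.shape} as an image")


def read_image(path: str | Path) -> np.ndarray:
    """Read PNG/JPEG as a 2-D float array (greyscale collapsed if needed)."""
    with Image.open(path) as im:
        arr = np.asarray(im)
    return to_greyscale(arr)


def write_png(pixels: np.ndarray, path: str | Path) -> None:
    px = np.asarray(pixels)
    if px.dtype != np.uint8:
        raise ValueError("write_png expects uint8 pixels")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(px, mode="L").save(path, format="PNG")


def write_jpeg(pixels: np.ndarray, path: str | Path, quality: int = 90) -> None:
    px = np.asarray(pixels)
    if px.dtype != np.uint8:
        raise ValueError("write_jpeg expects uint8 pixels")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(px, mode="L").save(path, format="JPEG", quality=quality)


def read_dicom(path: str | Path) -> np.ndarray:
    """Return the raw pixel array of a monochrome single-frame DICOM."""
    import pydicom

    ds = pydicom.dcmread(path)
    photometric = str(getattr(ds, "PhotometricInterpretation", ""))
    if not photometric.startswith("MONOCHROME"):
        raise ValueError(f"unsupported photometric interpretation {photometric!r}")
    arr = ds.pixel_array
    if arr.ndim != 2:
        raise ValueError("multi-frame DICOM is not supported")
    return arr
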