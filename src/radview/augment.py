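"""Label-preserving image augmentation with full lineage tracking.

Six operator families expand each preprocessed source image into child
images that inherit its label, patient, study and split:

* ``hflip`` / ``vflip`` — exact reflections;
* ``rotate`` — ±2° (bilinear, zero fill) or ±90° (exact index permutation);
* ``translate`` — 3 px along one of the 8 compass directions, zero fill;
* ``pixel_spread`` — raster-order swap of each pixel with a uniformly chosen
  8-neighbor (seeded);
* ``median_offset`` — replace each pixel with the order statistic one rank
  before/after the median of its square neighborhood (radius 2 or 5; edge
  pixels use the truncated window);
* ``random_noise`` — seeded salt-and-pepper corruption of 1% of pixels;
* ``compose`` — an ordered chain of the above.

The default plan emits exactly 106 distinct non-identity children per
parent: a {15 geometric} x {7 photometric} grid minus the identity-identity
cell (104 composites) plus two documented extras (180° rotation as
hflip∘vflip, with and without pixel spread).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage.transform import rotate as _sk_rotate

from .records import ImageRecord

FAMILIES = ("hflip", "vflip", "rotate", "translate", "pixel_spread", "median_offset", "random_noise", "compose")

# (row, col) unit steps; image row 0 is "north"
_DIRECTIONS = {
    "n": (-1, 0), "ne": (-1, 1), "e": (0, 1), "se": (1, 1),
    "s": (1, 0), "sw": (1, -1), "w": (0, -1), "nw": (-1, -1),
}

ROTATE_ANGLES = (2, -2, 90, -90)
TRANSLATE_DISTANCE = 3
NOISE_RATE = 0.01


@dataclass(frozen=True)
class TransformSpec:
    """One augmentation operator; ``seed`` matters only for stochastic families."""

    family: str
    params: tuple = ()
    seed: int = 0
    parts: tuple = ()  # compose only

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown transform family {self.family!r}")
        if self.family == "rotate":
            (angle,) = self.params
            if angle not in ROTATE_ANGLES:
                raise ValueError(f"rotation angle must be one of {ROTATE_ANGLES}")
        elif self.family == "translate":
            (direction,) = self.params
            if direction not in _DIRECTIONS:
                raise ValueError(f"unknown compass direction {direction!r}")
        elif self.family == "median_offset":
            radius, side = self.params
            if radius not in (2, 5):
                raise ValueError("median_offset neighborhood radius must be 2 or 5")
            if side not in ("before", "after"):
                raise ValueError("median_offset side must be 'before' or 'after'")
        elif self.family == "compose":
            if not self.parts:
                raise ValueError("compose requires at least one part")
            if any(p.family == "compose" for p in self.parts):
                raise ValueError("compose parts must not themselves be compositions")

    @property
    def tag(self) -> str:
        if self.family == "compose":
            return "+".join(p.tag for p in self.parts)
        if self.family == "rotate":
            return f"rot{self.params[0]:+d}"
        if self.family == "translate":
            return f"tr_{self.params[0]}{TRANSLATE_DISTANCE}"
        if self.family == "median_offset":
            return f"med_{self.params[1]}{self.params[0]}"
        if self.family == "pixel_spread":
            return "spread"
        if self.family == "random_noise":
            return "noise"
        return self.family

    def with_seed(self, seed: int) -> "TransformSpec":
        if self.family == "compose":
            parts = tuple(p.with_seed(seed + i) for i, p in enumerate(self.parts))
            return replace(self, seed=seed, parts=parts)
        return replace(self, seed=seed)


@dataclass(frozen=True)
class AugmentationPlan:
    specs: tuple[TransformSpec, ...]
    name: str = "custom"

    def __post_init__(self) -> None:
        tags = [s.tag for s in self.specs]
        if len(set(tags)) != len(tags):
            raise ValueError("plan specs must be distinct")

    def __len__(self) -> int:
        return len(self.specs)


# ---------------------------------------------------------------- operators

def _hflip(px: np.ndarray) -> np.ndarray:
    return np.fliplr(px)


def _vflip(px: np.ndarray) -> np.ndarray:
    return np.flipud(px)


def _rotate(px: np.ndarray, angle: int) -> np.ndarray:
    if angle % 90 == 0:
        return np.ascontiguousarray(np.rot90(px, k=(angle // 90) % 4))
    out = _sk_rotate(px.astype(float), angle, order=1, cval=0.0, preserve_range=True)
    return np.rint(np.clip(out, 0, 255)).astype(np.uint8)


def _translate(px: np.ndarray, direction: str, distance: int = TRANSLATE_DISTANCE) -> np.ndarray:
    dy, dx = _DIRECTIONS[direction]
    dy, dx = dy * distance, dx * distance
    out = np.zeros_like(px)
    h, w = px.shape
    ys = slice(max(dy, 0), h + min(dy, 0))
    xs = slice(max(dx, 0), w + min(dx, 0))
    ys_src = slice(max(-dy, 0), h + min(-dy, 0))
    xs_src = slice(max(-dx, 0), w + min(-dx, 0))
    out[ys, xs] = px[ys_src, xs_src]
    return out


def _pixel_spread(px: np.ndarray, seed: int) -> np.ndarray:
    """Raster-order swap of each pixel with a random in-bounds 8-neighbor."""
    rng = np.random.default_rng(seed)
    out = px.copy()
    h, w = out.shape
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    choices = rng.integers(0, 8, size=h * w)
    k = 0
    for i in range(h):
        for j in range(w):
            dy, dx = offsets[choices[k]]
            k += 1
            ni, nj = i + dy, j + dx
            if 0 <= ni < h and 0 <= nj < w:
                out[i, j], out[ni, nj] = out[ni, nj], out[i, j]
    return out


def _median_offset(px: np.ndarray, radius: int, side: str) -> np.ndarray:
    """Order statistic at rank median±1 of each pixel's square neighborhood."""
    h, w = px.shape
    k = 2 * radius + 1
    padded = np.full((h + 2 * radius, w + 2 * radius), np.nan)
    padded[radius : radius + h, radius : radius + w] = px
    win = sliding_window_view(padded, (k, k)).reshape(h, w, k * k)
    ordered = np.sort(win, axis=-1)  # NaN sorts to the end
    counts = np.count_nonzero(~np.isnan(win), axis=-1)
    med = (counts - 1) // 2
    rank = np.clip(med + (1 if side == "after" else -1), 0, counts - 1)
    out = np.take_along_axis(ordered, rank[..., None], axis=-1)[..., 0]
    return out.astype(np.uint8)


def _random_noise(px: np.ndarray, seed: int, rate: float = NOISE_RATE) -> np.ndarray:
    """Salt-and-pepper corruption of ``rate`` of the pixels."""
    rng = np.random.default_rng(seed)
    out = px.copy()
    n = out.size
    n_corrupt = int(round(rate * n))
    flat_idx = rng.choice(n, size=n_corrupt, replace=False)
    values = rng.integers(0, 2, size=n_corrupt).astype(np.uint8) * 255
    out.reshape(-1)[flat_idx] = values
    return out


def apply_pixels(px: np.ndarray, spec: TransformSpec) -> np.ndarray:
    if spec.family == "hflip":
        return _hflip(px)
    if spec.family == "vflip":
        return _vflip(px)
    if spec.family == "rotate":
        return _rotate(px, spec.params[0])
    if spec.family == "translate":
        return _translate(px, spec.params[0])
    if spec.family == "pixel_spread":
        return _pixel_spread(px, spec.seed)
    if spec.family == "median_offset":
        return _median_offset(px, *spec.params)
    if spec.family == "random_noise":
        return _random_noise(px, spec.seed)
    out = px
    for part in spec.parts:
        out = apply_pixels(out, part)
    return out


def apply_transform(record: ImageRecord, spec: TransformSpec) -> ImageRecord:
    """Apply one spec, producing a child that inherits all parent metadata."""
    if record.pixels is None:
        raise ValueError(f"record {record.image_id} has no pixels")
    child_px = apply_pixels(record.pixels, spec)
    return record.child(f"{record.image_id}__{spec.tag}", child_px, spec.tag)


# ------------------------------------------------------------- default plan

def geometric_variants() -> list[TransformSpec]:
    specs = [TransformSpec("hflip"), TransformSpec("vflip")]
    specs += [TransformSpec("rotate", (a,)) for a in ROTATE_ANGLES]
    specs += [TransformSpec("translate", (d,)) for d in ("n", "ne", "e", "se", "s", "sw", "w", "nw")]
    return specs  # 14


def photometric_variants() -> list[TransformSpec]:
    specs = [TransformSpec("pixel_spread")]
    specs += [TransformSpec("median_offset", (r, s)) for r in (2, 5) for s in ("before", "after")]
    specs += [TransformSpec("random_noise")]
    return specs  # 6


def default_plan() -> AugmentationPlan:
    """The fixed 106-child plan: (identity+14 geo) x (identity+6 photo) minus
    identity x identity, plus hflip∘vflip (= 180° rotation) with and without
    pixel spread."""
    geo = geometric_variants()
    photo = photometric_variants()
    specs: list[TransformSpec] = []
    specs.extend(geo)  # geometric alone (photo = identity)
    specs.extend(photo)  # photometric alone (geo = identity)
    for g in geo:
        for p in photo:
            specs.append(TransformSpec("compose", parts=(g, p)))
    specs.append(TransformSpec("compose", parts=(TransformSpec("hflip"), TransformSpec("vflip"))))
    specs.append(
        TransformSpec(
            "compose",
            parts=(TransformSpec("hflip"), TransformSpec("vflip"), TransformSpec("pixel_spread")),
        )
    )
    return AugmentationPlan(specs=tuple(specs), name="default-106")


def _derive_seed(base_seed: int, image_id: str, index: int) -> int:
    return zlib.crc32(f"{base_seed}:{image_id}:{index}".encode()) & 0x7FFFFFFF


def augment_set(
    records: list[ImageRecord],
    plan: AugmentationPlan,
    base_seed: int = 0,
    materialize: bool = True,
) -> list[ImageRecord]:
    """Expand every record into ``len(plan)`` children.

    Children inherit label, patient, study and split; per-child seeds are
    derived deterministically from (base_seed, parent id, spec index).
    With ``materialize=False`` only metadata records are emitted (pixels are
    ``None``), which supports cheap large-count accounting.
    """
    children: list[ImageRecord] = []
    for rec in records:
        if rec.split == "unassigned":
            raise RuntimeError(f"record {rec.image_id} has no split assignment; split before augmenting")
        for i, spec in enumerate(plan.specs):
            seeded = spec.with_seed(_derive_seed(base_seed, rec.image_id, i))
            if materialize:
                children.append(apply_transform(rec, seeded))
            else:
                children.append(rec.child(f"{rec.image_id}__{seeded.tag}", None, seeded.tag))
    return children
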