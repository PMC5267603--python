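"""Binary-cutoff selection and exact-interval evaluation of PFI scores.

The classifier's raw output is the probability of a frontal image (PFI);
frontal is the positive class throughout. The operating threshold is chosen
by scanning cutoffs from 0 to 1 in 0.001 steps and maximizing the Youden
Index J(c) = sensitivity(c) + specificity(c) - 1, where an image is called
frontal iff PFI >= c. When a range of cutoffs attains the maximum, the
higher end is chosen. Accuracy is the proportion of images correctly
classified, with exact (Clopper-Pearson) binomial confidence intervals;
groups of models are compared by a Pearson chi-square on pooled 2x2 counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .preprocess import resize_squash
from .records import ImageRecord

CUTOFF_STEP = 0.001


@dataclass(frozen=True)
class Prediction:
    image_id: str
    pfi: float
    label: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.pfi <= 1.0:
            raise ValueError("pfi must lie in [0, 1]")
        if self.label not in ("frontal", "lateral"):
            raise ValueError(f"prediction label must be frontal or lateral, got {self.label!r}")


@dataclass(frozen=True)
class CutoffResult:
    grid: np.ndarray
    j_values: np.ndarray
    max_range: tuple[float, float]
    chosen_cutoff: float

    @property
    def max_j(self) -> float:
        return float(self.j_values.max())


@dataclass(frozen=True)
class ConfusionTable:
    """Counts with frontal as the positive class."""

    true_frontal: int  # frontal called frontal
    false_lateral: int  # frontal called lateral
    false_frontal: int  # lateral called frontal
    true_lateral: int  # lateral called lateral

    @property
    def total(self) -> int:
        return self.true_frontal + self.false_lateral + self.false_frontal + self.true_lateral

    @property
    def correct(self) -> int:
        return self.true_frontal + self.true_lateral

    @property
    def accuracy(self) -> float:
        return self.correct / self.total

    def as_array(self) -> np.ndarray:
        return np.array([[self.true_frontal, self.false_lateral], [self.false_frontal, self.true_lateral]])


@dataclass(frozen=True)
class BinomialCI:
    successes: int
    trials: int
    level: float
    lower: float
    upper: float


@dataclass(frozen=True)
class GroupComparison:
    counts: np.ndarray  # pooled 2x2: rows = groups, cols = (correct, incorrect)
    chi2: float
    p: float
    alpha: float = 0.05


def youden_cutoff(predictions: list[Prediction], step: float = CUTOFF_STEP) -> CutoffResult:
    """Scan the cutoff grid and return the J-maximizing range and its high end."""
    pf = np.array([p.pfi for p in predictions if p.label == "frontal"])
    pl = np.array([p.pfi for p in predictions if p.label == "lateral"])
    if len(pf) == 0 or len(pl) == 0:
        raise ValueError("need at least one frontal and one lateral prediction")
    n_points = int(round(1.0 / step))
    grid = np.arange(n_points + 1) / n_points
    sens = (pf[None, :] >= grid[:, None]).mean(axis=1)
    spec = (pl[None, :] < grid[:, None]).mean(axis=1)
    j = sens + spec - 1.0
    jmax = j.max()
    hit = np.flatnonzero(j == jmax)
    return CutoffResult(
        grid=grid,
        j_values=j,
        max_range=(float(grid[hit[0]]), float(grid[hit[-1]])),
        chosen_cutoff=float(grid[hit[-1]]),
    )


def classify(predictions: list[Prediction], cutoff: float) -> ConfusionTable:
    """2x2 confusion table calling frontal iff PFI >= cutoff."""
    if not 0.0 <= cutoff <= 1.0 + 1e-12:
        raise ValueError("cutoff must lie in [0, 1]")
    tf = fl = ff = tl = 0
    for p in predictions:
        called_frontal = p.pfi >= cutoff
        if p.label == "frontal":
            tf += called_frontal
            fl += not called_frontal
        else:
            ff += called_frontal
            tl += not called_frontal
    return ConfusionTable(tf, fl, ff, tl)


def clopper_pearson(k: int, n: int, level: float = 0.95) -> BinomialCI:
    """Exact binomial interval via beta quantiles."""
    if n < 1 or not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n and n >= 1")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    alpha = 1.0 - level
    lower = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2.0, k, n - k + 1))
    upper = 1.0 if k == n else float(stats.beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return BinomialCI(successes=k, trials=n, level=level, lower=lower, upper=upper)


def compare_groups(
    tables: list[tuple[int, int]],
    grouping: list,
    alpha: float = 0.05,
    correction: bool = False,
) -> GroupComparison:
    """Pool per-model (correct, incorrect) counts into two groups and run a
    Pearson chi-square (df=1, no continuity correction by default)."""
    if len(tables) != len(grouping):
        raise ValueError("one group label per table is required")
    groups = sorted(set(grouping), key=str)
    if len(groups) != 2:
        raise ValueError("grouping must partition the tables into exactly two groups")
    pooled = np.zeros((2, 2), dtype=np.int64)
    for (correct, incorrect), g in zip(tables, grouping):
        if correct < 0 or incorrect < 0:
            raise ValueError("counts must be non-negative")
        pooled[groups.index(g)] += (correct, incorrect)
    if (pooled.sum(axis=1) == 0).any():
        raise ValueError("each group must contain at least one observation")
    if (pooled.sum(axis=0) == 0).any():
        # no variation in outcome at all: homogeneous by definition
        return GroupComparison(counts=pooled, chi2=0.0, p=1.0, alpha=alpha)
    chi2, p, _, _ = stats.chi2_contingency(pooled, correction=correction)
    return GroupComparison(counts=pooled, chi2=float(chi2), p=float(p), alpha=alpha)


# ------------------------------------------------------------ perturbations

PERTURB_KINDS = ("text_label", "rotate", "obscure_half", "crop")

# 7x5 bitmap of the letter "L" used for the burned-in annotation stamp.
_GLYPH_L = np.array(
    [
        [1, 0, 0, 0, 0],
        [1, 0, 0, 0, 0],
        [1, 0, 0, 0, 0],
        [1, 0, 0, 0, 0],
        [1, 0, 0, 0, 0],
        [1, 0, 0, 0, 0],
        [1, 1, 1, 1, 1],
    ],
    dtype=np.uint8,
)
TEXT_MARGIN = 4
TEXT_SCALE = 2


def text_stamp_bbox(shape: tuple[int, int], corner: str = "nw", scale: int = TEXT_SCALE) -> tuple[int, int, int, int]:
    """(row0, row1, col0, col1) of the stamped block, end-exclusive."""
    gh, gw = _GLYPH_L.shape[0] * scale, _GLYPH_L.shape[1] * scale
    h, w = shape
    r0 = TEXT_MARGIN if corner[0] == "n" else h - TEXT_MARGIN - gh
    c0 = TEXT_MARGIN if corner[1] == "w" else w - TEXT_MARGIN - gw
    return r0, r0 + gh, c0, c0 + gw


def perturb(record: ImageRecord, kind: str, **kwargs) -> ImageRecord:
    """Robustness-probe transformations; output shape equals input shape.

    * ``text_label`` — burn a high-intensity character block into a corner
      (the whole block is replaced: glyph pixels at 255, block background 0);
    * ``rotate`` — rotate by ``angle`` degrees (default 10, bilinear, zero fill);
    * ``obscure_half`` — zero one half (``side`` in left/right/top/bottom);
    * ``crop`` — extract a centered window of ``fraction`` of each dimension
      and squash-resize back to the original size.
    """
    if kind not in PERTURB_KINDS:
        raise ValueError(f"unknown perturbation {kind!r}")
    if record.pixels is None:
        raise ValueError(f"record {record.image_id} has no pixels")
    px = record.pixels
    if kind == "text_label":
        corner = kwargs.get("corner", "nw")
        scale = kwargs.get("scale", TEXT_SCALE)
        out = px.copy()
        r0, r1, c0, c1 = text_stamp_bbox(px.shape, corner, scale)
        out[r0:r1, c0:c1] = np.kron(_GLYPH_L, np.ones((scale, scale), dtype=np.uint8)) * 255
        tag = f"text_label:{corner}"
    elif kind == "rotate":
        from skimage.transform import rotate as _sk_rotate

        angle = kwargs.get("angle", 10.0)
        out = np.rint(
            np.clip(_sk_rotate(px.astype(float), angle, order=1, cval=0.0, preserve_range=True), 0, 255)
        ).astype(np.uint8)
        tag = f"rotate:{angle:g}"
    elif kind == "obscure_half":
        side = kwargs.get("side", "left")
        out = px.copy()
        h, w = px.shape
        if side == "left":
            out[:, : w // 2] = 0
        elif side == "right":
            out[:, w // 2 :] = 0
        elif side == "top":
            out[: h // 2, :] = 0
        elif side == "bottom":
            out[h // 2 :, :] = 0
        else:
            raise ValueError(f"unknown side {side!r}")
        tag = f"obscure_half:{side}"
    else:  # crop
        fraction = kwargs.get("fraction", 0.8)
        if not 0.0 < fraction <= 1.0:
            raise ValueError("crop fraction must be in (0, 1]")
        h, w = px.shape
        ch, cw = int(round(fraction * h)), int(round(fraction * w))
        r0, c0 = (h - ch) // 2, (w - cw) // 2
        window = px[r0 : r0 + ch, c0 : c0 + cw]
        out = resize_squash(window, (h, w))
        tag = f"crop:{fraction:g}"
    return record.child(f"{record.image_id}__{tag}", out, tag)
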