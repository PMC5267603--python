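"""Core record type and manifest handling.

An :class:`ImageRecord` is one greyscale image together with its view label,
patient/study identifiers, split assignment, and lineage (the parent it was
derived from by augmentation or perturbation, if any).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

LABELS = ("frontal", "lateral", "unknown")
SPLITS = ("train", "val", "test", "unassigned")

MANIFEST_COLUMNS = [
    "image_id",
    "path",
    "label",
    "patient_id",
    "study_id",
    "split",
    "parent_id",
    "transform_tag",
]


@dataclass
class ImageRecord:
    """A single greyscale image plus metadata.

    ``pixels`` is a 2-D uint8 array, or ``None`` for metadata-only records
    (e.g. dry-run augmentation). ``parent_id`` and ``transform_tag`` are both
    set (derived record) or both ``None`` (source record).
    """

    image_id: str
    pixels: np.ndarray | None = None
    label: str = "unknown"
    patient_id: str = ""
    study_id: str = ""
    split: str = "unassigned"
    parent_id: str | None = None
    transform_tag: str | None = None

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.split not in SPLITS:
            raise ValueError(f"unknown split {self.split!r}")
        if (self.parent_id is None) != (self.transform_tag is None):
            raise ValueError("parent_id and transform_tag must be set together")
        if self.pixels is not None:
            px = np.asarray(self.pixels)
            if px.ndim != 2:
                raise ValueError("pixels must be a 2-D greyscale array")
            if px.dtype != np.uint8:
                raise ValueError("pixels must be uint8 (apply preprocessing first)")
            self.pixels = px

    def child(self, image_id: str, pixels: np.ndarray | None, transform_tag: str) -> "ImageRecord":
        """Derive a record inheriting label, patient, study and split."""
        return ImageRecord(
            image_id=image_id,
            pixels=pixels,
            label=self.label,
            patient_id=self.patient_id,
            study_id=self.study_id,
            split=self.split,
            parent_id=self.image_id,
            transform_tag=transform_tag,
        )

    def with_split(self, split: str) -> "ImageRecord":
        return replace(self, split=split)


def to_manifest(records: list[ImageRecord], paths: dict[str, str] | None = None) -> pd.DataFrame:
    paths = paths or {}
    rows = [
        {
            "image_id": r.image_id,
            "path": paths.get(r.image_id, ""),
            "label": r.label,
            "patient_id": r.patient_id,
            "study_id": r.study_id,
            "split": r.split,
            "parent_id": r.parent_id or "",
            "transform_tag": r.transform_tag or "",
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def from_manifest(df: pd.DataFrame, load_pixels: bool = False, root: str | Path = ".") -> list[ImageRecord]:
    from . import io as _io

    records = []
    for row in df.itertuples(index=False):
        pixels = None
        if load_pixels and getattr(row, "path", ""):
            pixels = _io.read_image(Path(root) / row.path)
        records.append(
            ImageRecord(
                image_id=str(row.image_id),
                pixels=pixels,
                label=str(row.label) if str(row.label) else "unknown",
                patient_id=str(getattr(row, "patient_id", "") or ""),
                study_id=str(getattr(row, "study_id", "") or ""),
                split=str(getattr(row, "split", "") or "unassigned"),
                parent_id=(str(row.parent_id) or None) if str(getattr(row, "parent_id", "")) else None,
                transform_tag=(str(row.transform_tag) or None) if str(getattr(row, "transform_tag", "")) else None,
            )
        )
    return records


def read_manifest(path: str | Path, load_pixels: bool = False) -> list[ImageRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return from_manifest(df, load_pixels=load_pixels, root=Path(path).parent)


def write_manifest(records: list[ImageRecord], path: str | Path, paths: dict[str, str] | None = None) -> None:
    to_manifest(records, paths).to_csv(path, index=False)
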