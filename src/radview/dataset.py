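"""Train/validation/test split assignment with leakage safeguards.

Splitting happens before augmentation, so siblings derived from one source
image can never straddle splits; augmented children then inherit the
parent's assignment. Sizes follow a floor-floor-remainder convention:
``floor(p_train*n)`` train, ``floor(p_val*n)`` validation, the rest test
(1882 records at 60/20/20 give 1129/376/377). An optional patient-level
mode keeps all images of a patient in one split.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import floor

import numpy as np

from .records import ImageRecord


@dataclass(frozen=True)
class SplitConfig:
    proportions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0
    patient_stratified: bool = False

    def __post_init__(self) -> None:
        if any(not 0.0 <= p <= 1.0 for p in self.proportions):
            raise ValueError("each proportion must lie in [0, 1]")
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")


def split_sizes(n: int, proportions: tuple[float, float, float]) -> tuple[int, int, int]:
    n_train = floor(proportions[0] * n)
    n_val = floor(proportions[1] * n)
    return n_train, n_val, n - n_train - n_val


def split(records: list[ImageRecord], config: SplitConfig) -> list[ImageRecord]:
    """Assign every record to exactly one split; returns new records in input order."""
    for rec in records:
        if rec.parent_id is not None:
            raise RuntimeError(
                f"record {rec.image_id} is an augmented child; split source images "
                "before augmenting to avoid sibling leakage across splits"
            )
    n = len(records)
    rng = np.random.default_rng(config.seed)
    n_train, n_val, _ = split_sizes(n, config.proportions)
    assignment = ["test"] * n

    if config.patient_stratified:
        by_patient: dict[str, list[int]] = {}
        for i, rec in enumerate(records):
            by_patient.setdefault(rec.patient_id, []).append(i)
        patients = list(by_patient)
        rng.shuffle(patients)
        placed = 0
        for pid in patients:
            idxs = by_patient[pid]
            target = "train" if placed < n_train else ("val" if placed < n_train + n_val else "test")
            for i in idxs:
                assignment[i] = target
            placed += len(idxs)
    else:
        order = rng.permutation(n)
        for pos, i in enumerate(order):
            assignment[i] = "train" if pos < n_train else ("val" if pos < n_train + n_val else "test")

    return [rec.with_split(s) for rec, s in zip(records, assignment)]
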