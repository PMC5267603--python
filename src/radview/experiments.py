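"""Canned desk-scale experiments combining all pipeline stages.

These drive the same library code as the CLI, at sizes chosen so a full
pretrain + fine-tune + evaluate cycle runs in seconds on one CPU: 64x64
phantoms, a 150-per-class generic pretraining set, and an 8-spec mini
augmentation plan that expands 50 parent phantoms into the 400 fine-tuning
children.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import augment as ag
from . import evaluate as ev
from . import synthetic as sy
from . import train as tr
from .records import ImageRecord

PHANTOM_SIZE = 64
PHANTOM_NOISE_SD = 8.0
PRETRAIN_PER_CLASS = 150
PRETRAIN_EPOCHS = 3
FINETUNE_PARENTS = 50
FINETUNE_EPOCHS = 5
TEST_PER_CLASS = 100


def mini_plan() -> ag.AugmentationPlan:
    """An 8-spec sub-plan of the default operator families (one per family
    plus both 2° rotations and two translations); 50 parents x 8 = 400
    children."""
    specs = (
        ag.TransformSpec("hflip"),
        ag.TransformSpec("vflip"),
        ag.TransformSpec("rotate", (2,)),
        ag.TransformSpec("rotate", (-2,)),
        ag.TransformSpec("translate", ("e",)),
        ag.TransformSpec("translate", ("w",)),
        ag.TransformSpec("pixel_spread"),
        ag.TransformSpec("random_noise"),
    )
    return ag.AugmentationPlan(specs=specs, name="mini-8")


def make_phantom_records(
    n_per_class: int,
    seed: int,
    size: int = PHANTOM_SIZE,
    noise_sd: float = PHANTOM_NOISE_SD,
    split: str = "unassigned",
    id_prefix: str = "ph",
) -> list[ImageRecord]:
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_per_class):
        for view in ("frontal", "lateral"):
            rec = sy.make_phantom(
                sy.PhantomConfig(size, size, view, noise_sd=noise_sd, seed=int(rng.integers(0, 2**31 - 1)))
            )
            records.append(
                ImageRecord(
                    image_id=f"{id_prefix}-{view}-{i}",
                    pixels=rec.pixels,
                    label=view,
                    patient_id=f"{id_prefix}-pt{i}-{view}",
                    split=split,
                )
            )
    return records


@dataclass(frozen=True)
class TransferResult:
    accuracy: float  # top-prediction accuracy on held-out phantoms
    max_j: float
    chosen_cutoff: float
    cutoff_accuracy: float  # accuracy at the Youden-chosen cutoff
    n_train: int
    n_test: int


def phantom_transfer_experiment(
    seed: int,
    *,
    regime: str = "all_layers",
    pretrain_mode: str = "greyscale_generic",
    finetune_parents: int = FINETUNE_PARENTS,
    finetune_epochs: int = FINETUNE_EPOCHS,
    pretrain_epochs: int = PRETRAIN_EPOCHS,
    test_per_class: int = TEST_PER_CLASS,
    noise_sd: float = PHANTOM_NOISE_SD,
) -> TransferResult:
    """Pretrain on generic shapes, fine-tune on augmented phantoms, evaluate.

    ``finetune_parents`` parent phantoms (balanced classes) are expanded by
    the 8-spec mini plan; with the 50-parent default that yields the 400
    fine-tuning images. Held-out evaluation uses fresh un-augmented phantoms.
    """
    pre_cfg = tr.TrainConfig(regime="all_layers", pretrain_mode=pretrain_mode, epochs=pretrain_epochs, seed=seed)
    channels = 3 if pretrain_mode == "color_generic" else 1
    X, y = sy.make_generic_set(PRETRAIN_PER_CLASS, size=PHANTOM_SIZE, channels=channels, seed=seed)
    model = tr.pretrain(X, y, pre_cfg)

    parents = make_phantom_records(
        finetune_parents // 2, seed=seed + 1, noise_sd=noise_sd, split="train", id_prefix="ft"
    )
    children = ag.augment_set(parents, mini_plan(), base_seed=seed)
    ft_cfg = tr.TrainConfig(regime=regime, use_augmented=True, epochs=finetune_epochs, seed=seed)
    model = tr.finetune(model, children, ft_cfg)

    test = make_phantom_records(test_per_class, seed=seed + 2, noise_sd=noise_sd, id_prefix="te")
    preds = tr.predict(model, test)
    acc = float(np.mean([(p.pfi >= 0.5) == (p.label == "frontal") for p in preds]))
    cut = ev.youden_cutoff(preds)
    table = ev.classify(preds, cut.chosen_cutoff)
    return TransferResult(
        accuracy=acc,
        max_j=cut.max_j,
        chosen_cutoff=cut.chosen_cutoff,
        cutoff_accuracy=table.accuracy,
        n_train=len(children),
        n_test=len(test),
    )
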