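import numpy as np
import pytest

from radview.records import ImageRecord
from radview.synthetic import PhantomConfig, make_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def smooth_frontal():
    """Noise-free 64x64 frontal phantom (pure geometry)."""
    return make_phantom(PhantomConfig(64, 64, "frontal", noise_sd=0, seed=1)).pixels


@pytest.fixture
def noisy_phantom():
    return make_phantom(PhantomConfig(64, 64, "frontal", noise_sd=8, seed=3)).pixels


@pytest.fixture
def train_record_pair():
    """One frontal and one lateral record with split already assigned."""
    recs = []
    for view in ("frontal", "lateral"):
        ph = make_phantom(PhantomConfig(64, 64, view, noise_sd=8, seed=11))
        recs.append(
            ImageRecord(
                image_id=f"src-{view}",
                pixels=ph.pixels,
                label=view,
                patient_id=f"pt-{view}",
                study_id=f"st-{view}",
                split="train",
            )
        )
    return recs
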