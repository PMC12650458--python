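import numpy as np
import pytest

from neurofuse.features import dataset_to_bundles
from neurofuse.synthetic import SimConfig, default_class_coupling, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_dataset():
    """1 subject, 4 classes, 6 clips/class, 6 s clips: fast but windowed."""
    cfg = SimConfig(
        n_subjects=1,
        n_clips_per_class=6,
        clip_duration=6.0,
        n_eeg_channels=6,
        n_fnirs_channels=3,
        class_coupling=default_class_coupling(6, 4),
        seed=42,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def tiny_bundles(tiny_dataset):
    """Feature bundles for the tiny dataset (fixed AR order for speed)."""
    return dataset_to_bundles(tiny_dataset, order_policy=3, seed=42)
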