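import numpy as np
import pytest

from ldg.optimizer import LDGHyperparams
from ldg.synthetic import SyntheticConfig, generate_multisubject_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset():
    """A small but structured multi-subject dataset (3 subjects, 3 classes)."""
    cfg = SyntheticConfig(
        n_subjects=3,
        n_classes=3,
        samples_per_class_per_subject=12,
        d=5,
        clusters_per_class=2,
        class_separation=6.0,
        subject_shift_scale=0.5,
        noise_sigma=1.0,
        seed=7,
    )
    X, y, subjects = generate_multisubject_dataset(cfg)
    return X, y, subjects


@pytest.fixture
def small_binary(small_dataset):
    X, y, _ = small_dataset
    return X, np.where(y == 0, 1.0, -1.0)


@pytest.fixture
def small_hyper():
    return LDGHyperparams(k1=3, k2=3, k_graph=3)
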