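import numpy as np
import pytest

from csbnet import SyntheticSpec, generate, train_val_split


@pytest.fixture(scope="session")
def leaf_dataset():
    """240 synthetic leaf images (60 per class), split 200 train / 40 val."""
    batch, manifest = generate(SyntheticSpec(n_per_class=60, seed=42))
    train_b, val_b = train_val_split(batch, val_fraction=1 / 6, seed=7)
    return batch, manifest, train_b, val_b


@pytest.fixture(scope="session")
def faint_leaf_dataset():
    """Same layout as leaf_dataset but with faint lesions (contrast 0.55),
    the regime where measurement capacity visibly limits accuracy."""
    batch, manifest = generate(
        SyntheticSpec(n_per_class=60, seed=42, lesion_contrast=0.55)
    )
    train_b, val_b = train_val_split(batch, val_fraction=1 / 6, seed=7)
    return batch, manifest, train_b, val_b


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small 4-class dataset for fast pipeline tests."""
    batch, manifest = generate(SyntheticSpec(n_per_class=6, seed=9))
    return batch, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
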