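import numpy as np
import pytest

from ppgqc import PreprocessConfig, generate_dataset, preprocess_dataset, stratified_split


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """60 synthetic signals (30 good / 15 fair / 15 poor) at 512 Hz."""
    return generate_dataset(30, 15, 15, seed=7)


@pytest.fixture(scope="session")
def small_splits(small_dataset):
    """Preprocessed 40/30/30 split matrices of the small dataset."""
    processed = preprocess_dataset(small_dataset, PreprocessConfig())
    train_ds, val_ds, test_ds = stratified_split(processed, seed=7)
    return {
        "train": (train_ds.as_matrix(), train_ds.binary_labels),
        "val": (val_ds.as_matrix(), val_ds.binary_labels),
        "test": (test_ds.as_matrix(), test_ds.binary_labels),
    }
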