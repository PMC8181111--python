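import numpy as np
import pytest

from ecgfusion.preprocess import segment_beats
from ecgfusion.synthetic import SyntheticConfig, make_record


@pytest.fixture(scope="session")
def clean_record():
    """A noise-free 300-beat strip with ground truth."""
    cfg = SyntheticConfig(n_beats=300, noise_sd=0.0, baseline_amp=0.0, seed=42)
    return make_record(cfg)


@pytest.fixture(scope="session")
def clean_dataset(clean_record):
    """Segmented beats (X, y) from the clean strip."""
    record, r_pos, _labels = clean_record
    ds = segment_beats(record, r_pos)
    return ds.to_matrix()


@pytest.fixture(scope="session")
def small_feature_problem():
    """A tiny separable feature matrix for tree unit tests."""
    rng = np.random.default_rng(5)
    X = np.vstack([
        rng.normal(0.0, 0.3, size=(20, 3)),
        rng.normal(3.0, 0.3, size=(20, 3)),
        rng.normal(-3.0, 0.3, size=(20, 3)),
    ])
    y = np.asarray(["a"] * 20 + ["b"] * 20 + ["c"] * 20, dtype=object)
    return X, y
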