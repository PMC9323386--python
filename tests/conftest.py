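import numpy as np
import pytest

from fuzzynir import (SyntheticConfig, generate_dataset,
                      well_separated_config)


@pytest.fixture(scope="session")
def default_dataset():
    """Default study conditions: 6 x 67 spectra, overlapping mid-days."""
    return generate_dataset(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def separated_dataset():
    """Well-separated preset used for parameter-recovery checks."""
    return generate_dataset(well_separated_config(seed=7))


@pytest.fixture()
def blobs_2d():
    """Two tight, far-apart 2-D blobs with known means."""
    rng = np.random.default_rng(42)
    a = rng.normal([0.0, 0.0], 0.05, size=(30, 2))
    b = rng.normal([10.0, 10.0], 0.05, size=(30, 2))
    X = np.vstack([a, b])
    labels = np.repeat([0, 1], 30)
    return X, labels, np.array([a.mean(axis=0), b.mean(axis=0)])
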