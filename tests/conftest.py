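import numpy as np
import pandas as pd
import pytest

from eeg2bold.features import SupervisedSet
from eeg2bold.synthetic import SyntheticConfig, generate_study


@pytest.fixture(scope="session")
def small_study():
    """A small coupled study shared by downstream tests."""
    cfg = SyntheticConfig(n_subjects=2, n_channels=4, n_regions=5,
                          n_scans=120, coupling_gain=2.0, noise_sd=0.8,
                          seed=7)
    return generate_study(cfg)


@pytest.fixture(scope="session")
def null_study():
    """A zero-coupling study: EEG and BOLD are independent."""
    cfg = SyntheticConfig(n_subjects=2, n_channels=4, n_regions=5,
                          n_scans=120, coupling_gain=0.0, seed=8)
    return generate_study(cfg)


def make_toy_set(n=120, dim=12, seed=0, noise=0.0, gap=0.0):
    """Linearly separable (optionally noisy) toy classification set.

    ``gap > 0`` pushes the two classes apart along the separating direction
    so that every family, including regularized ones, can fit exactly.
    """
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, dim))
    margin = X[:, 0] + X[:, 1] + noise * rng.normal(size=n)
    if gap > 0:
        shift = np.sign(margin) * gap
        X[:, 0] += shift
        X[:, 1] += shift
        margin = X[:, 0] + X[:, 1]
    y = np.where(margin >= 0, "increase", "decrease")
    y_reg = X[:, 0] * 2.0 + 1.0
    index = pd.DataFrame({"subject": 0, "condition": "toy", "region": "r0",
                          "scan": np.arange(n)})
    return SupervisedSet(X, y, y_reg, index)
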