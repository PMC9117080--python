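import numpy as np
import pytest

from wtdpsd import FeatureConfig
from wtdpsd.io import CLASS_CODES, extract_feature_table
from wtdpsd.synthetic import SyntheticSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A small strongly-separated phantom cohort shared across tests."""
    samples, manifest = generate(
        SyntheticSpec(n_per_class=20, image_size=128, class_signal=1.0, seed=42)
    )
    return samples, manifest


@pytest.fixture(scope="session")
def small_features(small_cohort):
    """Feature matrix and labels for the shared cohort."""
    samples, _ = small_cohort
    features, flags = extract_feature_table(samples, FeatureConfig())
    X = features.drop(columns=["image_id", "label"]).to_numpy()
    y = features["label"].map(CLASS_CODES).to_numpy()
    return X, y
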