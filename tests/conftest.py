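import numpy as np
import pytest

from zlda import SynthEEGConfig, fit_zlda, generate_synthetic_trials


@pytest.fixture
def separable_data():
    """Well-separated balanced 2-D Gaussian classes (fixed seed)."""
    rng = np.random.default_rng(42)
    X1 = rng.normal([-1.0, -0.6], 0.3, size=(50, 2))
    X2 = rng.normal([1.0, 0.6], 0.3, size=(50, 2))
    X = np.vstack([X1, X2])
    labels = np.array(["left"] * 50 + ["right"] * 50)
    return X, labels


@pytest.fixture
def fitted_model(separable_data):
    X, labels = separable_data
    return fit_zlda(X, labels)


@pytest.fixture(scope="session")
def synth_trials():
    """Default synthetic EEG trial set (two 4:1 variance-flip sources)."""
    return generate_synthetic_trials(SynthEEGConfig(), seed=7)
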