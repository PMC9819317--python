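import numpy as np
import pytest

from fundusdr import FundusSynthConfig, generate_arrays


@pytest.fixture(scope="session")
def small_dataset():
    """100 train / 25 test synthetic fundus images (25 per grade)."""
    cfg = FundusSynthConfig(per_grade_n=25, test_fraction=0.2)
    train, test = generate_arrays(cfg)
    return {
        "X_train": [s.image for s in train],
        "y_train": np.array([s.grade for s in train]),
        "X_test": [s.image for s in test],
        "y_test": np.array([s.grade for s in test]),
        "train": train,
        "test": test,
        "cfg": cfg,
    }


@pytest.fixture(scope="session")
def separable_dataset():
    """200 train / 50 test images — the larger learnability fixture."""
    cfg = FundusSynthConfig(per_grade_n=50, test_fraction=0.2)
    train, test = generate_arrays(cfg)
    return {
        "X_train": [s.image for s in train],
        "y_train": np.array([s.grade for s in train]),
        "X_test": [s.image for s in test],
        "y_test": np.array([s.grade for s in test]),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
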