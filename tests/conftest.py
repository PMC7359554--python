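import numpy as np
import pytest

from fmlp import ShapeSpec, make_mask


@pytest.fixture(scope="session")
def square_mask():
    """32x32 filled square centered in a 64x64 grid."""
    return make_mask(ShapeSpec(kind="square", image_side=64, base_radius=16))


@pytest.fixture(scope="session")
def regular_mask():
    return make_mask(ShapeSpec(kind="regular", image_side=128, base_radius=30, seed=5))


@pytest.fixture(scope="session")
def irregular_mask():
    return make_mask(
        ShapeSpec(
            kind="irregular", image_side=128, base_radius=30, roughness=0.4, seed=5
        )
    )


@pytest.fixture(scope="session")
def separable_features():
    """Two well-separated 2-D feature clusters (n=200), labels 1/0."""
    rng = np.random.default_rng(42)
    n = 100
    reg = rng.normal(loc=[1.25, 0.96], scale=[0.02, 0.005], size=(n, 2))
    irr = rng.normal(loc=[1.33, 0.66], scale=[0.03, 0.03], size=(n, 2))
    X = np.vstack([reg, irr])
    y = np.concatenate([np.ones(n, dtype=int), np.zeros(n, dtype=int)])
    return X, y
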