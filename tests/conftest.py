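import numpy as np
import pytest

from moctree import ObservationalDataset


@pytest.fixture
def four_sample_ds() -> ObservationalDataset:
    """Four samples with per-row propensities; full-data IPW CATE = 2.5/3.25."""
    return ObservationalDataset(
        covariates=np.arange(4.0).reshape(4, 1),
        outcome=[2.0, 1.0, 1.0, 0.0],
        treatment=[1, 1, 0, 0],
        propensity=[0.8, 0.5, 0.5, 0.2],
    )


def make_separable(n: int = 500, seed: int = 7) -> ObservationalDataset:
    """Noiseless randomized data with effect +1 for x1 > 0 and −1 otherwise.

    Y = (2W − 1)·sign(x1) with e ≡ 0.5, so the treated-minus-control
    difference within any pure region is ±2 and the optimal first split for
    every CATE criterion lies in the empirical gap around x1 = 0.
    """
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, 2))
    w = (rng.random(n) < 0.5).astype(int)
    tau = np.where(X[:, 0] > 0, 1.0, -1.0)
    y = (2.0 * w - 1.0) * tau
    return ObservationalDataset(X, y, w, propensity=np.full(n, 0.5))


@pytest.fixture
def separable_ds() -> ObservationalDataset:
    return make_separable()
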