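import numpy as np
import pandas as pd
import pytest

from mirmint.expression import ExprMatrix
from mirmint.simulate import SimConfig, simulate_all


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(n_genes=400, n_mirnas=80, seed=11)


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    return simulate_all(small_cfg)


def make_matrix(values, n_ctrl, n_trt, feature_ids=None):
    values = np.asarray(values, float)
    samples = [f"c{i}" for i in range(n_ctrl)] + [
        f"t{i}" for i in range(n_trt)
    ]
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(values.shape[0])]
    design = pd.Series(
        ["control"] * n_ctrl + ["treated"] * n_trt, index=samples
    )
    return ExprMatrix(
        values=pd.DataFrame(values, index=feature_ids, columns=samples),
        design=design,
    )


@pytest.fixture
def toy_matrix(rng):
    """50 features, 3v3, heterogeneous variances, some planted effects."""
    base = rng.normal(7, 2, 50)
    sd = np.exp(rng.normal(-0.7, 0.6, 50))
    eff = np.where(rng.random(50) < 0.3, rng.normal(0, 1.5, 50), 0.0)
    vals = (
        base[:, None]
        + np.r_[np.zeros(3), np.ones(3)][None, :] * eff[:, None]
        + rng.normal(0, 1, (50, 6)) * sd[:, None]
    )
    return make_matrix(vals, 3, 3)
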