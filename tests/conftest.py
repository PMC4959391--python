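import numpy as np
import pytest

from o2pls import PairedData, low_dimensional_design, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_paired(rng, n=60, p=8, q=6):
    """Small random paired dataset, centered."""
    X = rng.normal(size=(n, p))
    Y = rng.normal(size=(n, q))
    data = PairedData(
        X=X,
        Y=Y,
        sample_ids=[f"s{i}" for i in range(n)],
        x_var_ids=[f"x{j}" for j in range(p)],
        y_var_ids=[f"y{j}" for j in range(q)],
    )
    return data.center()


@pytest.fixture
def small_pair(rng):
    return make_paired(rng)


@pytest.fixture
def lowdim_data():
    """One centered replicate of the stock low-dimensional design."""
    data, truth = simulate_dataset(low_dimensional_design(0.05), seed=42)
    return data.center(), truth


def principal_angle(A, B):
    """Largest principal angle (radians) between column spans."""
    Qa, _ = np.linalg.qr(np.atleast_2d(A))
    Qb, _ = np.linalg.qr(np.atleast_2d(B))
    s = np.linalg.svd(Qa.T @ Qb, compute_uv=False)
    return float(np.arccos(np.clip(s.min(), -1.0, 1.0)))
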