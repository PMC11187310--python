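import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests/oracles.py

from compknot.knot_engine import ClosureConfig
from compknot.synthetic_data import CurveSpec, make_curve


@pytest.fixture
def closure_cfg():
    """Standard stochastic closure configuration with a fixed seed."""
    return ClosureConfig(seed=11, n_closures=100)


@pytest.fixture
def direct_cfg():
    return ClosureConfig(strategy="direct", n_closures=1, seed=0)


@pytest.fixture(scope="session")
def deep_trefoil():
    """Open chain with one deeply knotted trefoil core and its truth."""
    return make_curve(CurveSpec("torus", n_points=80, seed=5))


@pytest.fixture(scope="session")
def double_trefoil():
    """Open chain with two sequential trefoil cores (composite 3_1#3_1)."""
    return make_curve(CurveSpec("connected_sum", n_points=170, seed=5))


@pytest.fixture(scope="session")
def slipknot_chain():
    return make_curve(CurveSpec("slipknot", n_points=110, seed=5))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
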