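import numpy as np
import pytest

from screenmark import fit, simulate_panel
from screenmark.fixtures import ckb_like_generator
from screenmark.msm import IntensityMatrix, StateSpace


@pytest.fixture(scope="session")
def ckb_spec():
    """The calibrated three-category generator at full study size."""
    return ckb_like_generator("three_category", n_subjects=30_000, seed=1)


@pytest.fixture(scope="session")
def ckb_fit(ckb_spec):
    """One simulate-and-fit experiment shared across recovery checks."""
    panel = simulate_panel(ckb_spec)
    return fit(panel, ckb_spec.space)


@pytest.fixture()
def two_state():
    """low -> high at rate 0.05/year, high terminal."""
    lam = 0.05
    space = StateSpace(
        ("low", "high"),
        (True, False),
        np.array([[False, True], [False, False]]),
    )
    Q = IntensityMatrix(np.array([[-lam, lam], [0.0, 0.0]]), space)
    return lam, Q


def random_conservative_Q(n: int, rng: np.random.Generator, absorbing: int = 0):
    """A dense random generator matrix with optional absorbing tail states."""
    M = rng.uniform(0.05, 0.5, size=(n, n))
    np.fill_diagonal(M, 0.0)
    for a in range(n - absorbing, n):
        M[a, :] = 0.0
    np.fill_diagonal(M, -M.sum(axis=1))
    return M
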