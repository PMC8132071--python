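import numpy as np
import pytest

from drlandscape import (
    MISA_D,
    build_mixture,
    find_stable_states,
    fixture_misa,
)


@pytest.fixture(scope="session")
def misa():
    return fixture_misa()


@pytest.fixture(scope="session")
def misa_states(misa):
    return find_stable_states(misa, n_starts=800, seed=7)


@pytest.fixture(scope="session")
def misa_mixture(misa, misa_states):
    return build_mixture(misa, misa_states, MISA_D)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_network(rng, N, density=0.5):
    """A random valid Hill network for property tests."""
    from drlandscape import NetworkModel

    A = np.where(rng.random((N, N)) < density / 2, rng.uniform(0.1, 1.0, (N, N)), 0.0)
    B = np.where(rng.random((N, N)) < density / 2, rng.uniform(0.1, 1.0, (N, N)), 0.0)
    B[A > 0] = 0.0  # one sign per ordered pair
    return NetworkModel(
        node_names=[f"g{i}" for i in range(N)],
        A=A,
        B=B,
        S=rng.uniform(0.3, 1.0),
        n=int(rng.integers(2, 5)),
        k=rng.uniform(0.5, 2.0, N),
        g0=rng.uniform(0.0, 0.05),
    )
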