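import numpy as np
import pytest

import recotherm as rt


@pytest.fixture(scope="session")
def example():
    """The bundled 3x3 worked example (strictly positive channel, skewed prior)."""
    return rt.example_bundle()


@pytest.fixture(scope="session")
def channel(example):
    return example.channel


@pytest.fixture(scope="session")
def prior(example):
    return example.prior


def random_pairs(n, start_seed=0, n_src=3, n_rcv=3):
    """Stream of strictly positive random (channel, prior) bundles."""
    for s in range(start_seed, start_seed + n):
        yield rt.generate_random_fixture(n_src, n_rcv, seed=s)


@pytest.fixture(scope="session")
def random_potentials():
    """A batch of random potential tables with varied beta and sizes."""
    rng = np.random.default_rng(7)
    tables = []
    for _ in range(20):
        n_rcv = rng.integers(2, 5)
        n_src = rng.integers(2, 4)
        U = rng.normal(scale=2.0, size=(n_rcv, n_src))
        tables.append(rt.PotentialTable(U, beta=float(rng.uniform(0.2, 3.0))))
    return tables
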