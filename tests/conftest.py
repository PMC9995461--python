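import numpy as np
import pytest

import schemesens as ss


@pytest.fixture(scope="session")
def indep2():
    """Independent binding to 2 sites with unit dissociation constants."""
    return ss.make_independent_sites(2)


@pytest.fixture(scope="session")
def hopfield_eq():
    return ss.make_hopfield_kp(ss.hopfield_equilibrium_rates())


@pytest.fixture(scope="session")
def two_state():
    return ss.KineticScheme(
        ["a", "b"], [ss.Edge("a", "b", 1.0), ss.Edge("b", "a", 1.0)]
    )


def random_scheme_pool(count: int, max_N: int = 8, seed0: int = 0):
    """Deterministic pool of strongly connected random schemes."""
    out = []
    for i in range(count):
        N = 2 + (i + seed0) % (max_N - 1)
        out.append(ss.random_scheme(ss.RandomSpec(N=N, seed=seed0 + i)))
    return out


def random_x(seed: int, n: int = 1, span: float = 2.0) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return 10.0 ** rng.uniform(-span / 2, span / 2, size=n)
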