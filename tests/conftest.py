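import numpy as np
import pytest

from wmhnet.connectivity import BinaryNetwork


def random_adjacency(rng: np.random.Generator, n: int, p: float = 0.3) -> np.ndarray:
    """Symmetric 0/1 adjacency with zero diagonal."""
    upper = rng.random((n, n)) < p
    adj = np.triu(upper, 1).astype(np.uint8)
    return adj | adj.T


def random_network(rng: np.random.Generator, n: int, p: float = 0.3) -> BinaryNetwork:
    return BinaryNetwork(random_adjacency(rng, n, p), sparsity=p)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_cohort():
    """A tiny deterministic cohort shared across tests (session-scoped: ~0.1 s)."""
    from wmhnet.cohort import CohortParams, generate_cohort

    params = CohortParams(
        n_group_a=5,
        n_group_b=4,
        n_regions=20,
        n_timepoints=120,
        n_modules=4,
        within_module_r=0.6,
        between_module_r=0.1,
        group_b_attenuation=0.4,
        seed=7,
    )
    return params, generate_cohort(params)
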