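import numpy as np
import pytest

from assortnet import Connectome, SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Study-scale cohort (24/46/18 subjects, 400 nodes, planted effects)."""
    return generate_cohort(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(
        seed=7, node_count=60, group_sizes=(8, 10, 6),
        hypo_nodes=(3, 12, 21), hyper_nodes=(7, 16, 25),
        base_density=0.2,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """Reduced cohort for fast pipeline tests."""
    return generate_cohort(small_config)


def random_connectome(rng, n=10, p=0.3, weighted=True, modality="structural", ensure_edge=True):
    """Erdos-Renyi-style weighted test network."""
    while True:
        U = np.triu(rng.random((n, n)) < p, k=1).astype(float)
        if weighted:
            w = rng.uniform(0.1, 2.0, size=(n, n))
            if modality == "functional":
                w *= np.where(rng.random((n, n)) < 0.3, -1.0, 1.0)
            U = U * w
        A = U + U.T
        if not ensure_edge or A.any():
            return Connectome(A, modality=modality)
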