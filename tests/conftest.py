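import numpy as np
import pytest

from lncda import generate_network, generate_ontology


@pytest.fixture(scope="session")
def planted():
    """Small planted network shared by read-only tests."""
    return generate_network(n=20, m=25, rank=2, density=0.15, noise=0.0, seed=11)


@pytest.fixture(scope="session")
def ontology(planted):
    return generate_ontology(n_terms=25, seed=11,
                             term_ids=planted.network.disease_ids)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
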