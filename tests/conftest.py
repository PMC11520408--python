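import numpy as np
import pytest

from affinet import synthetic


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_bundle():
    """A compact, fully featurized fixture bundle shared across tests."""
    return synthetic.make_bundle(
        n_compounds=15,
        n_proteins=4,
        n_pairs=50,
        seed=7,
        duplicate_rate=0.1,
        conflict_rate=0.05,
        noise_sd=0.1,
        atoms_per=30,
    )


@pytest.fixture(scope="session")
def helix_cloud():
    """One reproducible synthetic structure for descriptor tests."""
    return synthetic.gen_structure_coords(40, seed=3)
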