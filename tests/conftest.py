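import numpy as np
import pytest

from deorphan import SyntheticFamilyConfig, simulate_family

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng, length):
    return "".join(AA[i] for i in rng.integers(0, 20, size=length))


@pytest.fixture(scope="session")
def rng300():
    return np.random.default_rng(300)


@pytest.fixture(scope="session")
def small_bundle():
    """A small simulated family reused across tests: 3 subfamilies, 5 species."""
    config = SyntheticFamilyConfig(
        n_subfamilies=3, decoy_duplicates=2, decoy_truncations=1, seed=7
    )
    return simulate_family(config)
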