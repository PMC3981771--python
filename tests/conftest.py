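import numpy as np
import pytest

from orgsnp import io, simulate
from orgsnp.cohort import CohortTable


@pytest.fixture(scope="session")
def mito_rows():
    return io.load_published_table(which="mito")


@pytest.fixture(scope="session")
def plastid_rows():
    return io.load_published_table(which="plastid")


@pytest.fixture(scope="session")
def mito_table(mito_rows):
    return CohortTable.from_published_rows(mito_rows, "mito")


@pytest.fixture(scope="session")
def plastid_table(plastid_rows):
    return CohortTable.from_published_rows(plastid_rows, "plastid")


@pytest.fixture(scope="session")
def small_refs():
    """Miniature reference trio for fast mapping/calling tests."""
    return simulate.simulate_references(
        plastid_len=2000, mito_len=5000, nuclear_len=0,
        transfer_fraction=0.2, n_segments=2, divergence=0.02, seed=42,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
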