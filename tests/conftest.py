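import numpy as np
import pytest

from gutmarkers.simulate import spike_worked_example
from gutmarkers.tables import OtuTable


@pytest.fixture(scope="session")
def worked_example():
    """The fixed 20-sample x 30-OTU fixture cohort with 5 planted markers."""
    return spike_worked_example()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def random_table(rng):
    """A small random count table with some zero cells."""
    counts = rng.integers(0, 50, size=(5, 8))
    counts[rng.random(counts.shape) < 0.3] = 0
    counts[:, 0] += 1  # keep every sample total positive
    return OtuTable(
        [f"S{i}" for i in range(5)],
        [f"O{j}" for j in range(8)],
        counts,
    )
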