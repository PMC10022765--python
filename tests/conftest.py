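import numpy as np
import pytest

from rqit import generate_tasks, load_default_table
from rqit.instrument import Dimension, Instrument


@pytest.fixture(scope="session")
def table():
    """Packaged ANZMUSC-RQIT utility table (published values)."""
    return load_default_table()


@pytest.fixture(scope="session")
def instrument(table):
    return table.instrument


@pytest.fixture(scope="session")
def tasks(instrument):
    """Full anti-chain choice-task design over the packaged instrument."""
    return generate_tasks(instrument)


def make_instrument(level_counts, letters=None):
    """Helper: an instrument with the given levels per dimension."""
    letters = letters or [chr(ord("A") + i) for i in range(len(level_counts))]
    dims = tuple(
        Dimension(
            code=let,
            label=f"dimension {let}",
            levels=tuple((f"{let}{j + 1}", f"level {j + 1}") for j in range(n)),
        )
        for let, n in zip(letters, level_counts)
    )
    return Instrument(dimensions=dims, name="toy", version="1")


@pytest.fixture
def rng():
    return np.random.default_rng(20230317)
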