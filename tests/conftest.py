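import numpy as np
import pandas as pd
import pytest

BASES = "ACGT"


@pytest.fixture
def rng():
    return np.random.default_rng(20230306)


@pytest.fixture
def sample_sheet_6():
    """Minimal 3+3 drought design."""
    return pd.DataFrame(
        {
            "library_id": [f"c{i}" for i in range(1, 4)] + [f"d{i}" for i in range(1, 4)],
            "condition": ["control_1"] * 3 + ["drought"] * 3,
            "replicate": [1, 2, 3, 1, 2, 3],
        }
    )


def random_seq(rng, length):
    return "".join(rng.choice(list(BASES), length))


@pytest.fixture
def random_seq_factory(rng):
    return lambda length: random_seq(rng, length)
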