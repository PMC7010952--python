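import numpy as np
import pytest

from ppiwsrc.fvector import STANDARD_RESIDUES


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_117)


def random_sequence(rng, length):
    letters = np.array(list(STANDARD_RESIDUES))
    return "".join(rng.choice(letters, size=length))


@pytest.fixture
def tiny_dataset():
    """Small synthetic interaction dataset for fast end-to-end tests."""
    from ppiwsrc.data import SyntheticSpec, generate_synthetic

    spec = SyntheticSpec(n_proteins=60, n_positive=30, n_negative=30, seed=11)
    records, pairs = generate_synthetic(spec)
    return records, pairs
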