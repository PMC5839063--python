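import numpy as np
import pytest

from argbox import boxdata, iimodel


@pytest.fixture(scope="session")
def records():
    return boxdata.load_table1()


@pytest.fixture(scope="session")
def training(records):
    return boxdata.select_training_set(records)


@pytest.fixture(scope="session")
def plain_model(training):
    """Model from the 37 curated boxes exactly as printed (one strand)."""
    return iimodel.build_model_from_sequences([r.sequence for r in training])


@pytest.fixture(scope="session")
def arg_model(training):
    """The production palindromic ARG box model (boxes + reverse complements)."""
    return iimodel.build_model_from_sequences(
        [r.sequence for r in training], palindromic=True
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def toy_model(width=5, n=8, seed=0, palindromic=False):
    """Small random model for exhaustive oracles."""
    from argbox.seqio import ALPHABET

    r = np.random.default_rng(seed)
    seqs = ["".join(ALPHABET[b] for b in r.integers(0, 4, size=width)) for _ in range(n)]
    return iimodel.build_model_from_sequences(
        seqs, palindromic=palindromic, zero_count_policy="pseudocount"
    )
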