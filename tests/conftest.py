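"""Shared fixtures: a toy sequence store and a small seeded synthetic world."""

import numpy as np
import pytest

from strinit import synthetic_data as sd
from strinit.genomic_io import GenomicInterval, SequenceStore


@pytest.fixture(scope="session")
def toy_store():
    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGT"), size=4000))
    return SequenceStore({"chrT": seq})


@pytest.fixture(scope="session")
def small_world():
    """400-STR world with default classes/signal model (seeded)."""
    return sd.generate_world(n_strs=400, seed=11)


@pytest.fixture(scope="session")
def small_coverage(small_world):
    return sd.generate_coverage(small_world, seed=12)


@pytest.fixture(scope="session")
def noiseless_world():
    """Deterministic limit: sigma = 0, no body scatter."""
    model = sd.default_signal_model()
    model.sigma = 0.0
    model.scatter_rate = 0.0
    return sd.generate_world(n_strs=120, signal_model=model, seed=21)
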