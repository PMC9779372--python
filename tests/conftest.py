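import random

import numpy as np
import pytest
from hypothesis import settings

from acpdesign import CANONICAL_AA, Peptide, PlantedModel, default_scale, generate_mock_db

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scale():
    return default_scale()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_peptide(rng, length, pid="p"):
    idx = rng.integers(0, 20, size=length)
    return Peptide(pid, "".join(CANONICAL_AA[i] for i in idx))


@pytest.fixture(scope="session")
def small_db():
    """Synthetic corpus covering every length 15-20, 30 sequences each."""
    return generate_mock_db(PlantedModel(n_per_length=30, seed=11))


@pytest.fixture
def small_db_fasta(tmp_path):
    path = tmp_path / "db.fasta"
    generate_mock_db(PlantedModel(n_per_length=30, seed=11), fasta_path=path)
    return path
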