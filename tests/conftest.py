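import random

import pytest
from hypothesis import settings

from seqvault.fixtures import SyntheticSpec, generate_records
from seqvault.repo import SeqVault

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def writable_repo(tmp_path):
    repo = SeqVault(tmp_path / "repo", writeable=True)
    yield repo
    repo.close()


@pytest.fixture
def loaded_repo(tmp_path):
    """A committed repository holding 20 seeded synthetic DNA sequences."""
    repo = SeqVault(tmp_path / "repo", writeable=True)
    spec = SyntheticSpec(n_records=20, length_range=(30, 3000), seed=11)
    for rec in generate_records(spec):
        repo.store(rec.seq, [f"test:{rec.id}"])
    repo.commit()
    yield repo
    repo.close()


@pytest.fixture
def rng():
    return random.Random(1729)
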