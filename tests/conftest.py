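import numpy as np
import pytest
from hypothesis import settings

from emsig.channels import channel_names

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def toy_reference():
    """Dict-backed reference with two small contigs."""
    return {
        "chr1": "ACATTGCCAGGTACGTAACGGTCA",
        "chr2": "TTCACGTGCATNACGT",
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20130429)


@pytest.fixture
def random_signatures(rng):
    def make(n, concentration=0.5):
        mu = rng.dirichlet(np.full(96, concentration), size=n)
        mu = np.maximum(mu, 1e-12)
        return mu / mu.sum(axis=1, keepdims=True)

    return make


@pytest.fixture
def toy_fasta(tmp_path, toy_reference):
    """The same toy reference written as an indexed FASTA file."""
    from pyfaidx import Fasta

    path = tmp_path / "ref.fa"
    with open(path, "w") as fh:
        for name, seq in toy_reference.items():
            fh.write(f">{name}\n{seq}\n")
    return Fasta(str(path))


def canonical_names():
    return channel_names()
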