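import numpy as np
import pytest

from granzymekit import SequenceRecord, load_chymotrypsinogen
from granzymekit.synthetic import ScaffoldSpec, make_scaffold


@pytest.fixture(scope="session")
def chymo():
    """Packaged canonical-numbering reference: (record, numbers 1..245)."""
    return load_chymotrypsinogen()


@pytest.fixture(scope="session")
def scaffold():
    """One default granzyme-like scaffold: (precursor, truth)."""
    return make_scaffold(ScaffoldSpec(seed=42))


@pytest.fixture(scope="session")
def scaffold_mature(scaffold):
    _, truth = scaffold
    return SequenceRecord(truth.query_id, "protein", truth.mature, role="mature")


def random_protein(rng: np.random.Generator, length: int) -> str:
    aa = "ACDEFGHIKLMNPQRSTVWY"
    return "".join(aa[i] for i in rng.integers(0, 20, size=length))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
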