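import numpy as np
import pytest

from tailscreen import builtin_motifs, classical_motifs, default_vector


@pytest.fixture(scope="session")
def registry():
    return builtin_motifs()


@pytest.fixture(scope="session")
def classical():
    return classical_motifs()


@pytest.fixture(scope="session")
def vector():
    return default_vector()


@pytest.fixture
def rng():
    return np.random.default_rng(20100405)


def random_tails(rng, n, max_len=60, alphabet="ACDEFGHIKLMNPQRSTVWY"):
    """Uniform-residue random tails for oracle-equivalence checks."""
    letters = list(alphabet)
    out = []
    for _ in range(n):
        length = int(rng.integers(0, max_len + 1))
        out.append("".join(rng.choice(letters, size=length)))
    return out
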