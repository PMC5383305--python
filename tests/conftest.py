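import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")

from hadroclad.nexus import INAPPLICABLE, MISSING, CharacterMatrix
from hadroclad.simulate import fixture_hadrosaurinae


def random_matrix(rng, n_taxa, n_char, n_states=3, missing=0.15,
                  polymorphic=0.0):
    """Random character matrix fixture generator used across test modules."""
    taxa = [f"T{i}" for i in range(n_taxa)]
    cells = []
    for _ in range(n_taxa):
        row = []
        for _ in range(n_char):
            u = rng.random()
            if u < missing:
                row.append(MISSING if rng.random() < 0.8 else INAPPLICABLE)
            elif u < missing + polymorphic:
                k = rng.integers(2, n_states + 1)
                row.append(frozenset(
                    str(s) for s in rng.choice(n_states, size=k, replace=False)
                ))
            else:
                row.append(frozenset([str(rng.integers(n_states))]))
        cells.append(row)
    return CharacterMatrix(taxa, cells)


@pytest.fixture(scope="session")
def hadrosaurinae():
    return fixture_hadrosaurinae()


@pytest.fixture
def rng():
    return np.random.default_rng(20090)
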