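import numpy as np
import pytest

from grammarscope import grammar_sim as gs
from grammarscope import motifs as mo


@pytest.fixture(scope="session")
def motif_set():
    return mo.synthetic_motif_set(26, (8, 15), info_bits=1.5, seed=7)


@pytest.fixture(scope="session")
def grammars(motif_set):
    return gs.default_grammars(motif_set, seed=1)


@pytest.fixture(scope="session")
def grammar_dict(grammars):
    return {g.id: g for g in grammars}


@pytest.fixture(scope="session")
def classes():
    return gs.default_classes()


@pytest.fixture(scope="session")
def small_dataset(classes, grammars, motif_set):
    """10 sequences (2 classes x 5) at 1500 bp with ground truth."""
    return gs.simulate_dataset(
        classes[:2], grammars, motif_set, n_per_class=5, length=1500, seed=11
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
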