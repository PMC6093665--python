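import os
import sys

import numpy as np
import pytest

sys.path.insert(0, os.path.dirname(__file__))

from maxpars.matrix import MISSING, CharacterMatrix, StateSet
from maxpars.simulate import simulate_tree

REPO_ROOT = os.path.dirname(os.path.dirname(os.path.abspath(__file__)))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_column(labels, rng, n_states=3, ordered=False,
                  p_missing=0.15, p_poly=0.1):
    """A random single-character column with missing and polymorphic cells."""
    col = {}
    for lab in labels:
        u = rng.random()
        if u < p_missing:
            col[lab] = MISSING
        elif u < p_missing + p_poly:
            pair = rng.choice(n_states, size=2, replace=False)
            col[lab] = StateSet(frozenset(int(s) for s in pair))
        else:
            col[lab] = StateSet.of(int(rng.integers(n_states)))
    return col


def random_matrix(rng, n_taxa=6, n_chars=5, n_states=3,
                  p_missing=0.15, p_poly=0.1, p_ordered=0.4):
    labels = [f"t{i+1}" for i in range(n_taxa)]
    ordered = [bool(rng.random() < p_ordered) for _ in range(n_chars)]
    cols = [random_column(labels, rng, n_states=n_states,
                          p_missing=p_missing, p_poly=p_poly)
            for _ in range(n_chars)]
    cells = [[cols[j][lab] for j in range(n_chars)] for lab in labels]
    return CharacterMatrix(labels, cells, ordered)


def random_tree(rng, labels):
    return simulate_tree(len(labels), rng, labels=list(labels))
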