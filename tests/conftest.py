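from __future__ import annotations

import numpy as np
import pytest

from paleocroc.io_formats import MISSING, CharacterMatrix
from paleocroc.parsimony import _insertions


def random_matrix(
    rng: np.random.Generator,
    n_taxa: int,
    n_chars: int,
    max_states: int = 4,
    p_missing: float = 0.15,
    p_poly: float = 0.1,
    p_ordered: float = 0.5,
) -> CharacterMatrix:
    """Random matrix with missing cells, polymorphism and mixed ordering."""
    taxa = [f"t{i}" for i in range(n_taxa)]
    ordered = [bool(rng.random() < p_ordered) for _ in range(n_chars)]
    n_states = [int(rng.integers(2, max_states + 1)) for _ in range(n_chars)]
    cells = []
    for _ in range(n_taxa):
        row = []
        for j in range(n_chars):
            u = rng.random()
            if u < p_missing:
                row.append(MISSING)
            elif u < p_missing + p_poly:
                k = int(rng.integers(2, n_states[j] + 1))
                row.append(frozenset(rng.choice(n_states[j], size=k, replace=False).tolist()))
            else:
                row.append(frozenset([int(rng.integers(n_states[j]))]))
        cells.append(row)
    return CharacterMatrix(taxa=taxa, cells=cells, ordered=ordered)


def random_tuple_tree(rng: np.random.Generator, taxa: list[str]):
    """Random rooted binary tuple tree on *taxa* by insertion at random edges."""
    tree = taxa[0]
    for leaf in taxa[1:]:
        options = list(_insertions(tree, leaf))
        tree = options[int(rng.integers(len(options)))]
    return tree


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
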