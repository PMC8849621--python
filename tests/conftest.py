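"""Shared fixtures: seeded generators for random matrices and trees."""

from __future__ import annotations

import random

import pytest

from morphoclade.matrix_io import INAPPLICABLE, MISSING, CharacterMatrix, CharacterMeta
from morphoclade.trees import Phylotree, random_binary_tree


def random_matrix(
    rng: random.Random,
    n_taxa: int,
    n_chars: int,
    n_states: int = 3,
    p_missing: float = 0.1,
    p_poly: float = 0.05,
    p_inapplicable: float = 0.05,
    with_meta: bool = False,
) -> CharacterMatrix:
    taxa = tuple(f"t{i + 1}" for i in range(n_taxa))
    rows = []
    for _ in range(n_taxa):
        row = []
        for _ in range(n_chars):
            u = rng.random()
            if u < p_missing:
                row.append(MISSING)
            elif u < p_missing + p_inapplicable:
                row.append(INAPPLICABLE)
            elif u < p_missing + p_inapplicable + p_poly:
                k = rng.randint(2, n_states)
                row.append(frozenset(rng.sample(range(n_states), k)))
            else:
                row.append(frozenset({rng.randrange(n_states)}))
        rows.append(tuple(row))
    meta = ()
    if with_meta:
        meta = tuple(
            CharacterMeta(
                ordered_flag=rng.random() < 0.3,
                active_flag=rng.random() > 0.1,
                weight=float(rng.choice([1, 1, 1, 2, 3])),
                source_label="",
            )
            for _ in range(n_chars)
        )
    return CharacterMatrix(taxa, tuple(rows), meta)


def matrix_to_columns(matrix: CharacterMatrix) -> dict[str, list]:
    """Columns in the cell convention the brute-force oracle uses."""
    cols: dict[str, list] = {}
    for i, taxon in enumerate(matrix.taxa):
        cells = []
        for cell in matrix.cells[i]:
            if isinstance(cell, frozenset):
                cells.append(set(cell))
            else:
                cells.append(None)
        cols[taxon] = cells
    return cols


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20240817)


@pytest.fixture
def six_taxon_tree(rng) -> Phylotree:
    return random_binary_tree([f"t{i + 1}" for i in range(6)], rng)
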