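"""Strict consensus and agreement subtrees."""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

from ..trees import Phylotree, tree_from_bipartitions
from ._search import TreeSet

#: Largest leaf count for which the agreement subtree is found exactly
#: (brute force over leaf subsets).
EXACT_MAST_MAX_LEAVES = 12


def _trees_of(trees: TreeSet | Sequence[Phylotree]) -> list[Phylotree]:
    if isinstance(trees, TreeSet):
        return list(trees.trees)
    return list(trees)


def strict_consensus(trees: TreeSet | Sequence[Phylotree]) -> Phylotree:
    """Tree containing exactly the bipartitions shared by every input tree."""
    ts = _trees_of(trees)
    if not ts:
        raise ValueError("strict consensus of an empty tree set")
    leafsets = {t.leaf_labels for t in ts}
    if len(leafsets) > 1:
        raise ValueError("trees have unequal leaf sets")
    shared = frozenset.intersection(*(t.bipartitions() for t in ts))
    return tree_from_bipartitions(leafsets.pop(), shared)


@dataclass(frozen=True)
class AgreementResult:
    """Maximum agreement subtree; ``exact`` records which path computed it."""

    tree: Phylotree
    leaves: frozenset[str]
    exact: bool


def agreement_subtree(
    trees: TreeSet | Sequence[Phylotree],
    exact_max_leaves: int = EXACT_MAST_MAX_LEAVES,
) -> AgreementResult:
    """Largest leaf set on which all trees induce the same unrooted topology.

    Exact (subset enumeration, decreasing size) when the leaf count is at
    most ``exact_max_leaves``; otherwise a greedy leaf-elimination heuristic
    flagged via ``exact=False``.
    """
    ts = _trees_of(trees)
    if len(ts) < 2:
        raise ValueError("agreement subtree needs at least 2 trees")
    leafsets = {t.leaf_labels for t in ts}
    if len(leafsets) > 1:
        raise ValueError("trees have unequal leaf sets")
    leaves = sorted(leafsets.pop())
    splits = [t.bipartitions() for t in ts]

    if len(leaves) <= exact_max_leaves:
        subset = _exact_mast(leaves, splits)
        exact = True
    else:
        subset = _greedy_mast(leaves, splits)
        exact = False
    induced = ts[0].restrict(subset)
    induced.rooted = False
    return AgreementResult(induced, frozenset(subset), exact)


def _restricted(
    splits: frozenset[frozenset[str]], subset: frozenset[str]
) -> frozenset[frozenset[str]]:
    ref = min(subset)
    out = set()
    for side in splits:
        s = frozenset(side) & subset
        if ref in s:
            s = subset - s
        if 2 <= len(s) <= len(subset) - 2:
            out.add(s)
    return frozenset(out)


def _agree(splitsets: list[frozenset], subset: frozenset[str]) -> bool:
    first = _restricted(splitsets[0], subset)
    return all(_restricted(s, subset) == first for s in splitsets[1:])


def _exact_mast(leaves: list[str], splits: list[frozenset]) -> frozenset[str]:
    n = len(leaves)
    for k in range(n, 2, -1):
        for combo in itertools.combinations(leaves, k):
            subset = frozenset(combo)
            if _agree(splits, subset):
                return subset
    return frozenset(leaves[:3])  # any 3 leaves always agree


def _greedy_mast(leaves: list[str], splits: list[frozenset]) -> frozenset[str]:
    current = frozenset(leaves)
    while len(current) > 3 and not _agree(splits, current):
        best_leaf, best_conflict = None, None
        for leaf in sorted(current):
            trial = current - {leaf}
            conflict = _conflict_size(splits, trial)
            if best_conflict is None or conflict < best_conflict:
                best_leaf, best_conflict = leaf, conflict
        current = current - {best_leaf}
    return current


def _conflict_size(splits: list[frozenset], subset: frozenset[str]) -> int:
    restricted = [_restricted(s, subset) for s in splits]
    total = 0
    for a, b in itertools.combinations(restricted, 2):
        total += len(a ^ b)
    return total
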