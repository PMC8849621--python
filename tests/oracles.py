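"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations that share no code with the package:
exhaustive internal-state assignment for tree length, recursive topology
enumeration, subset enumeration for agreement subtrees and monotone
alignment.  Everything here is O(exponential) and only run at desk scale.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Sequence

# Trees are nested tuples: a leaf is a string, an internal node a tuple of
# subtrees.  Unrooted trees are represented rooted at an internal node with
# three children.


def leaves(tree) -> list[str]:
    if isinstance(tree, str):
        return [tree]
    out = []
    for sub in tree:
        out.extend(leaves(sub))
    return out


def internal_count(tree) -> int:
    if isinstance(tree, str):
        return 0
    return 1 + sum(internal_count(sub) for sub in tree)


def brute_force_length(tree, columns: dict[str, Sequence], n_states: int) -> int:
    """Exhaustive minimisation over all internal state assignments.

    ``columns[taxon]`` is a sequence of cells; a cell is a set of allowed
    states or None for missing (any state).
    """
    ncols = len(next(iter(columns.values())))
    total = 0
    for j in range(ncols):
        total += _brute_force_char(
            tree, {t: columns[t][j] for t in columns}, n_states
        )
    return total


def _brute_force_char(tree, col: dict, n_states: int) -> int:
    internals = internal_count(tree)
    best = None
    for assignment in itertools.product(range(n_states), repeat=internals):
        cost, _ = _cost_with_assignment(tree, col, list(assignment), n_states)
        if best is None or cost < best:
            best = cost
    return best


def _cost_with_assignment(tree, col, assignment: list[int], n_states: int):
    """Returns (cost of subtree, state at its root); consumes assignment."""
    if isinstance(tree, str):
        cell = col[tree]
        return 0, cell  # leaf 'state' is its allowed set (resolved by parent)
    my_state = assignment.pop(0)
    cost = 0
    for sub in tree:
        sub_cost, sub_state = _cost_with_assignment(sub, col, assignment, n_states)
        cost += sub_cost
        if isinstance(sub_state, int):
            cost += 0 if sub_state == my_state else 1
        else:  # leaf: free choice within its allowed set
            allowed = sub_state if sub_state is not None else set(range(n_states))
            cost += 0 if my_state in allowed else 1
    return cost, my_state


def all_unrooted_trees(labels: Sequence[str]):
    """Every unrooted binary topology as a nested tuple rooted at a
    trifurcating node; built by recursive edge insertion."""
    labels = list(labels)
    base = (labels[0], labels[1], labels[2])
    trees = [base]
    for lab in labels[3:]:
        nxt = []
        for t in trees:
            nxt.extend(_insert_everywhere(t, lab, top=True))
        trees = nxt
    return trees


def _insert_everywhere(tree, lab: str, top: bool = False):
    out = []
    if not top:
        # insert on the edge above this subtree
        out.append((tree, lab))
    if not isinstance(tree, str):
        for i, sub in enumerate(tree):
            for replaced in _insert_everywhere(sub, lab):
                out.append(tree[:i] + (replaced,) + tree[i + 1 :])
    return out


def splits_of(tree) -> frozenset:
    """Non-trivial splits of a nested-tuple unrooted tree, each side given
    as a frozenset not containing the overall minimum label."""
    all_l = frozenset(leaves(tree))
    ref = min(all_l)
    out = set()

    def walk(sub):
        if isinstance(sub, str):
            return frozenset({sub})
        below = frozenset()
        for s in sub:
            below |= walk(s)
        side = all_l - below if ref in below else below
        if 2 <= len(side) <= len(all_l) - 2:
            out.add(side)
        return below

    for sub in tree:
        walk(sub)
    return frozenset(out)


def restrict_splits(splits: frozenset, subset: frozenset) -> frozenset:
    ref = min(subset)
    out = set()
    for side in splits:
        s = frozenset(side) & subset
        if ref in s:
            s = subset - s
        if 2 <= len(s) <= len(subset) - 2:
            out.add(s)
    return frozenset(out)


def mast_by_enumeration(split_sets: list[frozenset], labels: Iterable[str]) -> frozenset:
    """Largest leaf subset on which all split sets agree after restriction."""
    labels = sorted(labels)
    for k in range(len(labels), 2, -1):
        for combo in itertools.combinations(labels, k):
            subset = frozenset(combo)
            restricted = [restrict_splits(s, subset) for s in split_sets]
            if all(r == restricted[0] for r in restricted):
                return subset
    return frozenset(labels[:3])


def best_monotone_alignment(
    pcts: Sequence[float],
    slots: Sequence[tuple[int, float]],
    flags: Sequence[bool],
    bound: int | None,
):
    """Exhaustive minimal-|delta| strictly-increasing assignment.

    Returns (best cost, positions tuple) or (None, None) if infeasible.
    Ties resolved toward lexicographically smallest slot-index tuples.
    """
    k, m = len(pcts), len(slots)
    best_cost, best_pos = None, None
    for combo in itertools.combinations(range(m), k):
        cost = 0.0
        ok = True
        for i, j in enumerate(combo):
            pos, tpct = slots[j]
            if bound is not None and flags[i] and pos > bound:
                ok = False
                break
            cost += abs(pcts[i] - tpct)
        if not ok:
            continue
        if best_cost is None or cost < best_cost - 1e-12:
            best_cost = cost
            best_pos = tuple(slots[j][0] for j in combo)
    return best_cost, best_pos


def convex_hull_membership(points, query, tol=1e-9) -> bool:
    """Point-in-convex-hull via half-plane checks over all point pairs."""
    import numpy as np

    pts = np.asarray(points, dtype=float)
    q = np.asarray(query, dtype=float)
    n = len(pts)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            edge = pts[j] - pts[i]
            normal = np.array([-edge[1], edge[0]])
            side = (pts - pts[i]) @ normal
            if (side >= -tol).all():  # all points on one side: hull edge
                if (q - pts[i]) @ normal < -tol:
                    return False
    return True
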