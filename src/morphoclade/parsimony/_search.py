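"""Heuristic maximum-parsimony search.

Random-addition-sequence replicates followed by steepest-descent branch
swapping (NNI, SPR or TBR) to a local optimum, then breadth-first plateau
exploration to collect equal-length trees (up to ``hold``).  Search trees
are binary, stored rooted on the edge next to an anchor leaf; all reported
topology comparisons are unrooted.

Determinism: every random draw flows from the ``seed`` argument.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Callable, Iterator

from .. import matrix_io
from ..matrix_io import CharacterMatrix
from ..trees import Node, Phylotree
from ._scoring import MatrixEncoding, _as_steps

_EPS = 1e-9

SWAPPERS = ("NNI", "SPR", "TBR")


@dataclass(frozen=True)
class SearchConfig:
    """Effort knobs for one heuristic search."""

    n_replicates: int = 10
    swapper: str = "TBR"
    hold: int = 1000

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.hold < 1:
            raise ValueError("hold must be >= 1")
        if self.swapper not in SWAPPERS:
            raise ValueError(f"swapper must be one of {SWAPPERS}")


@dataclass(frozen=True)
class TreeSet:
    """Distinct best trees found, all scoring exactly ``length``."""

    trees: tuple[Phylotree, ...]
    length: float | int

    def __post_init__(self) -> None:
        if not self.trees:
            raise ValueError("empty tree set")
        leafsets = {t.leaf_labels for t in self.trees}
        if len(leafsets) > 1:
            raise ValueError("trees have unequal leaf sets")

    def __len__(self) -> int:
        return len(self.trees)


# ---------------------------------------------------------------------------
# search-tree plumbing (anchor-rooted binary trees)


def _clone(root: Node) -> Node:
    return root.copy()


def _postorder(root: Node) -> list[Node]:
    return list(root.walk_postorder())


def _subtree_ids(v: Node) -> set[int]:
    return {id(n) for n in v.walk_postorder()}


def _insert_on_edge(edge_node: Node, subtree: Node) -> None:
    parent = edge_node.parent
    mid = Node()
    idx = parent.children.index(edge_node)
    parent.children[idx] = mid
    mid.parent = parent
    mid.add(edge_node)
    mid.add(subtree)


def _splice_out(v: Node) -> None:
    """Detach subtree v; its parent (never the root) is smoothed away."""
    p = v.parent
    g = p.parent
    sibling = next(c for c in p.children if c is not v)
    idx = g.children.index(p)
    g.children[idx] = sibling
    sibling.parent = g
    v.parent = None


def _reroot_fragment(v: Node, u: Node) -> Node:
    """Re-handle the pruned fragment rooted at binary node v on edge (u, u.parent)."""

    def flip(node: Node, came_from: Node) -> Node:
        kids = [c for c in node.children if c is not came_from]
        if node is v:
            if len(kids) == 1:
                kids[0].parent = None
                return kids[0]
            n = Node()
            for k in kids:
                n.add(k)
            return n
        n = Node()
        for k in kids:
            n.add(k)
        n.add(flip(node.parent, node))
        return n

    p = u.parent
    h = Node()
    h.add(u)
    h.add(flip(p, u))
    return h


def _topology_key(root: Node) -> frozenset:
    """Unrooted topology key: non-trivial splits, each normalised to the
    side not containing the lexicographically smallest leaf."""
    leaves = frozenset(n.label for n in root.walk_postorder() if n.is_leaf)
    ref = min(leaves)
    below: dict[int, frozenset[str]] = {}
    sides = set()
    for node in root.walk_postorder():
        if node.is_leaf:
            below[id(node)] = frozenset({node.label})
        else:
            below[id(node)] = frozenset().union(
                *(below[id(c)] for c in node.children)
            )
            if node.parent is not None:
                side = below[id(node)]
                if ref in side:
                    side = leaves - side
                if 2 <= len(side) <= len(leaves) - 2:
                    sides.add(side)
    return frozenset(sides)


def _key_str(key: frozenset) -> str:
    return repr(sorted(sorted(side) for side in key))


def _as_phylotree(root: Node) -> Phylotree:
    return Phylotree(root.copy(), rooted=False)


# ---------------------------------------------------------------------------
# neighbourhoods


def _edge_nodes(root: Node) -> list[Node]:
    """One node per unrooted edge (skips the anchor child of the root)."""
    anchor = root.children[0]
    return [n for n in _postorder(root) if n is not root and n is not anchor]


def _neighbors(root: Node, swapper: str) -> Iterator[Node]:
    if swapper == "NNI":
        yield from _nni_neighbors(root)
        return
    reroot = swapper == "TBR"
    nodes = _postorder(root)
    index = {id(n): i for i, n in enumerate(nodes)}
    for v in nodes:
        if v.parent is None or v.parent.parent is None:
            continue
        pv = index[id(v)]
        sub_ids = _subtree_ids(v)
        p = v.parent
        sibling = next(c for c in p.children if c is not v)
        reroot_choices: list[int | None] = [None]
        if reroot:
            for u in v.walk_postorder():
                if u is v or u.parent is v:
                    continue  # v's own child edges give the original handle
                reroot_choices.append(index[id(u)])
        for ru in reroot_choices:
            for e in nodes:
                if (
                    e.parent is None
                    or id(e) in sub_ids
                    or e is p
                    or e is root.children[0]
                ):
                    continue
                if ru is None and (e is sibling):
                    continue  # recreates the current topology
                yield _apply_move(root, pv, ru, index[id(e)])


def _apply_move(root: Node, pv: int, ru: int | None, ge: int) -> Node:
    clone = _clone(root)
    nodes = _postorder(clone)
    v = nodes[pv]
    e = nodes[ge]
    u = nodes[ru] if ru is not None else None
    _splice_out(v)
    frag = v if u is None else _reroot_fragment(v, u)
    _insert_on_edge(e, frag)
    return clone


def _nni_neighbors(root: Node) -> Iterator[Node]:
    nodes = _postorder(root)
    index = {id(n): i for i, n in enumerate(nodes)}
    for v in nodes:
        # internal edge (v, v.parent) with both ends internal
        if v.is_leaf or v.parent is None or v.parent is root:
            continue
        p = v.parent
        sibling = next(c for c in p.children if c is not v)
        for ci in range(2):
            clone = _clone(root)
            cn = _postorder(clone)
            cv = cn[index[id(v)]]
            cp = cv.parent
            csib = next(c for c in cp.children if c is not cv)
            child = cv.children[ci]
            # swap child <-> sibling
            cv.children[ci] = csib
            csib.parent = cv
            cp.children[cp.children.index(csib)] = child
            child.parent = cp
            yield clone


# ---------------------------------------------------------------------------
# stepwise addition and swapping


def _stepwise_addition(
    order: list[str], objective: Callable[[Node], float], rng: random.Random
) -> Node:
    root = Node()
    root.add(Node(order[0]))
    root.add(Node(order[1]))
    for label in order[2:]:
        best_score = None
        best_edges: list[int] = []
        edges = _edge_nodes(root)
        index = {id(n): i for i, n in enumerate(_postorder(root))}
        for e in edges:
            clone = _clone(root)
            cn = _postorder(clone)
            _insert_on_edge(cn[index[id(e)]], Node(label))
            s = objective(clone)
            if best_score is None or s < best_score - _EPS:
                best_score = s
                best_edges = [index[id(e)]]
            elif s <= best_score + _EPS:
                best_edges.append(index[id(e)])
        choice = rng.choice(best_edges)
        _insert_on_edge(_postorder(root)[choice], Node(label))
    return root


def _swap_to_optimum(
    root: Node, objective: Callable[[Node], float], swapper: str
) -> tuple[Node, float]:
    current = objective(root)
    improved = True
    while improved:
        improved = False
        best, best_tree = current, None
        for nb in _neighbors(root, swapper):
            s = objective(nb)
            if s < best - _EPS:
                best, best_tree = s, nb
        if best_tree is not None:
            root, current, improved = best_tree, best, True
    return root, current


def _collect_plateau(
    root: Node,
    score: float,
    objective: Callable[[Node], float],
    swapper: str,
    hold: int,
) -> dict[frozenset, Node]:
    seen = {_topology_key(root): root}
    queue = [root]
    while queue and len(seen) < hold:
        t = queue.pop(0)
        for nb in _neighbors(t, swapper):
            if objective(nb) <= score + _EPS:
                k = _topology_key(nb)
                if k not in seen:
                    seen[k] = nb
                    queue.append(nb)
                    if len(seen) >= hold:
                        break
    return seen


def _search_with_objective(
    taxa: tuple[str, ...],
    objective: Callable[[Node], float],
    config: SearchConfig,
    rng: random.Random,
) -> tuple[float, dict[frozenset, Node]]:
    best_score = float("inf")
    best: dict[frozenset, Node] = {}
    for _ in range(config.n_replicates):
        order = list(taxa)
        rng.shuffle(order)
        root = _stepwise_addition(order, objective, rng)
        root, score = _swap_to_optimum(root, objective, config.swapper)
        if score < best_score - _EPS:
            best_score = score
            best = {}
        if score <= best_score + _EPS:
            for k, t in _collect_plateau(
                root, score, objective, config.swapper, config.hold
            ).items():
                best.setdefault(k, t)
    return best_score, best


# ---------------------------------------------------------------------------
# public API


def heuristic_search(
    matrix: CharacterMatrix,
    n_replicates: int = 10,
    swapper: str = "TBR",
    hold: int = 1000,
    seed: int = 0,
) -> TreeSet:
    """All distinct best trees across random-addition + swapping replicates."""
    if matrix.n_taxa < 3:
        raise ValueError("heuristic search needs at least 3 taxa")
    config = SearchConfig(n_replicates=n_replicates, swapper=swapper, hold=hold)
    enc = MatrixEncoding(matrix)
    rng = random.Random(seed)
    best_score, best = _search_with_objective(
        matrix.taxa, enc.score, config, rng
    )
    ordered = sorted(best.items(), key=lambda kv: _key_str(kv[0]))
    trees = tuple(_as_phylotree(t) for _, t in ordered)
    return TreeSet(trees, _as_steps(best_score, matrix))


def prune_and_reanalyze(
    matrix: CharacterMatrix,
    taxa_to_prune: list[str],
    config: SearchConfig = SearchConfig(),
    seed: int = 0,
) -> tuple[TreeSet, Phylotree]:
    """Drop taxa, re-search, and return (tree set, strict consensus)."""
    from ._consensus import strict_consensus

    pruned = matrix_io.drop_taxa(matrix, taxa_to_prune)
    if pruned.n_taxa < 3:
        raise ValueError("pruning left fewer than 3 taxa")
    result = heuristic_search(
        pruned,
        n_replicates=config.n_replicates,
        swapper=config.swapper,
        hold=config.hold,
        seed=seed,
    )
    return result, strict_consensus(result)
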