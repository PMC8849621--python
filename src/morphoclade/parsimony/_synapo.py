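"""Character-change (synapomorphy) mapping on a fixed tree.

For every active character a Sankoff down/up dynamic program yields, per
branch, the set of (ancestral, derived) state pairs realised by at least
one most-parsimonious reconstruction (MPR).  A change on a branch is
*unambiguous* when every MPR changes state there.  ACCTRAN/DELTRAN modes
report one concrete reconstruction (ties broken toward early/late changes
respectively); ``unambiguous`` mode reports only branch changes common to
all MPRs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..matrix_io import INAPPLICABLE, MISSING, CharacterMatrix
from ..trees import Node, Phylotree

_INF = 1e12

MODES = ("ACCTRAN", "DELTRAN", "unambiguous")


@dataclass(frozen=True)
class Change:
    character: int  # 1-based
    ancestral_state: int
    derived_state: int
    unambiguous: bool


@dataclass(frozen=True)
class SynapomorphyMap:
    """Changes per clade, keyed by the clade's leaf label set."""

    mode: str
    changes: dict[frozenset[str], tuple[Change, ...]]

    def for_clade(self, labels) -> tuple[Change, ...]:
        return self.changes.get(frozenset(labels), ())


def map_synapomorphies(
    tree: Phylotree, matrix: CharacterMatrix, mode: str = "ACCTRAN"
) -> SynapomorphyMap:
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    leaves = tree.leaf_labels
    taxa = frozenset(matrix.taxa)
    if leaves != taxa:
        raise ValueError(
            f"tree/matrix taxon mismatch; only in tree: "
            f"{sorted(leaves - taxa)}, only in matrix: {sorted(taxa - leaves)}"
        )

    tree = _merge_root_edge(tree)
    nodes = list(tree.root.walk_postorder())
    below: dict[int, frozenset[str]] = {}
    for node in nodes:
        if node.is_leaf:
            below[id(node)] = frozenset({node.label})
        else:
            below[id(node)] = frozenset().union(
                *(below[id(c)] for c in node.children)
            )

    changes: dict[frozenset[str], list[Change]] = {}
    for j, meta in enumerate(matrix.char_meta):
        if not meta.active_flag or meta.weight == 0:
            continue
        obs = set()
        for row in matrix.cells:
            if isinstance(row[j], frozenset):
                obs |= row[j]
        if len(obs) < 2:
            continue  # constant or empty character: no changes anywhere
        S = max(obs) + 1
        if meta.ordered_flag:
            W = np.abs(
                np.arange(S)[:, None] - np.arange(S)[None, :]
            ).astype(float)
        else:
            W = 1.0 - np.eye(S)
        per_edge = _mpr_edges(tree, matrix, j, S, W, mode)
        for node, anc, der, unamb in per_edge:
            changes.setdefault(below[id(node)], []).append(
                Change(j + 1, anc, der, unamb)
            )
    return SynapomorphyMap(
        mode, {k: tuple(v) for k, v in changes.items()}
    )


def _merge_root_edge(tree: Phylotree) -> Phylotree:
    """A two-child root splits one unrooted edge in half, which would make
    every stem change look ambiguous (the change could sit on either half).
    Re-hang the tree so the root has >= 3 children, preserving unrooted
    edge semantics; changes on the former root edge are reported under the
    clade that was the root's other side."""
    if len(tree.root.children) != 2:
        return tree
    work = tree.copy()
    a, b = work.root.children
    host, guest = (a, b) if not a.is_leaf else (b, a)
    if host.is_leaf:  # two-leaf tree: nothing to analyse
        return tree
    host.parent = None
    guest.parent = None
    host.add(guest)
    return Phylotree(host, tree.rooted)


def _leaf_costs(
    matrix: CharacterMatrix, j: int, S: int, taxon: str
) -> np.ndarray:
    cell = matrix.row(taxon)[j]
    d = np.full(S, _INF)
    if cell is MISSING or cell is INAPPLICABLE:
        d[:] = 0.0
    else:
        d[sorted(cell)] = 0.0
    return d


def _mpr_edges(
    tree: Phylotree,
    matrix: CharacterMatrix,
    j: int,
    S: int,
    W: np.ndarray,
    mode: str,
) -> list[tuple[Node, int, int, bool]]:
    """Per-branch changes for character j under the requested mode."""
    nodes = list(tree.root.walk_postorder())

    D: dict[int, np.ndarray] = {}
    # minCH[id(child)][t] = min_s D[child][s] + W[t, s]
    minCH: dict[int, np.ndarray] = {}
    for node in nodes:
        if node.is_leaf:
            D[id(node)] = _leaf_costs(matrix, j, S, node.label)
        else:
            D[id(node)] = np.zeros(S)
            for c in node.children:
                minCH[id(c)] = (W + D[id(c)][None, :]).min(axis=1)
                D[id(node)] += minCH[id(c)]
    root = tree.root
    L = D[id(root)].min()

    # uppass: U[v][s] = min cost of the tree outside v's subtree with v = s
    U: dict[int, np.ndarray] = {id(root): np.zeros(S)}
    for node in reversed(nodes):  # preorder
        if node.is_leaf:
            continue
        base = U[id(node)] + D[id(node)]
        for c in node.children:
            out_t = base - minCH[id(c)]  # tree minus c's subtree, node state t
            U[id(c)] = (out_t[:, None] + W).min(axis=0)

    results: list[tuple[Node, int, int, bool]] = []

    if mode in ("ACCTRAN", "DELTRAN"):
        assign: dict[int, int] = {}
        prefer_change = mode == "ACCTRAN"
        root_best = D[id(root)]
        assign[id(root)] = int(root_best.argmin())
        for node in reversed(nodes):
            if node.is_leaf and node.parent is None:
                continue
            for c in node.children if not node.is_leaf else ():
                t = assign[id(node)]
                vals = W[t] + D[id(c)]
                m = vals.min()
                cand = [int(s) for s in np.flatnonzero(vals <= m + 1e-9)]
                changed = [s for s in cand if s != t]
                same = [s for s in cand if s == t]
                if prefer_change:
                    s = changed[0] if changed else same[0]
                else:
                    s = same[0] if same else changed[0]
                assign[id(c)] = s
        for node in nodes:
            if node.parent is None:
                continue
            t, s = assign[id(node.parent)], assign[id(node)]
            if t != s:
                unamb = _edge_always_changes(
                    node, D, U, minCH, W, L
                )
                results.append((node, t, s, unamb))
    else:  # unambiguous-only
        for node in nodes:
            if node.parent is None:
                continue
            pairs = _optimal_pairs(node, D, U, minCH, W, L)
            changing = sorted((t, s) for t, s in pairs if t != s)
            if changing and all(t != s for t, s in pairs):
                t, s = changing[0]
                results.append((node, t, s, True))
    return results


def _pair_costs(
    node: Node,
    D: dict[int, np.ndarray],
    U: dict[int, np.ndarray],
    minCH: dict[int, np.ndarray],
    W: np.ndarray,
) -> np.ndarray:
    """A[t, s]: min total cost with parent(node)=t and node=s."""
    p = node.parent
    out_t = U[id(p)] + D[id(p)] - minCH[id(node)]
    return out_t[:, None] + W + D[id(node)][None, :]


def _optimal_pairs(node, D, U, minCH, W, L) -> set[tuple[int, int]]:
    A = _pair_costs(node, D, U, minCH, W)
    ts, ss = np.nonzero(A <= L + 1e-9)
    return {(int(t), int(s)) for t, s in zip(ts, ss)}


def _edge_always_changes(node, D, U, minCH, W, L) -> bool:
    pairs = _optimal_pairs(node, D, U, minCH, W, L)
    return all(t != s for t, s in pairs)
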