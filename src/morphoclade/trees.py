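"""Leaf-labelled trees, Newick IO and bipartition algebra.

A :class:`Phylotree` wraps a mutable node structure.  Unrooted trees are
stored rooted at an arbitrary node with ``rooted=False``; topological
comparisons go through unrooted bipartitions so the storage rooting never
leaks into results.
"""

from __future__ import annotations

import itertools
import random
from typing import Callable, Iterable, Iterator, Sequence


class Node:
    """Tree node; leaves carry a ``label``, internals may carry annotations."""

    __slots__ = ("label", "children", "parent", "annotation")

    def __init__(self, label: str | None = None) -> None:
        self.label = label
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.annotation: str | None = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk_postorder(self) -> Iterator["Node"]:
        stack: list[tuple[Node, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for c in reversed(node.children):
                    stack.append((c, False))

    def leaves(self) -> list["Node"]:
        return [n for n in self.walk_postorder() if n.is_leaf]

    def copy(self) -> "Node":
        clone = Node(self.label)
        clone.annotation = self.annotation
        for c in self.children:
            clone.add(c.copy())
        return clone


class Phylotree:
    """Leaf-labelled tree with optional root designation and polytomies."""

    def __init__(self, root: Node, rooted: bool = True) -> None:
        self.root = root
        self.rooted = rooted
        labels = [n.label for n in root.walk_postorder() if n.is_leaf]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate leaf labels")
        for n in root.walk_postorder():
            if n is not root and len(n.children) == 1:
                raise ValueError("internal node with a single child")

    @property
    def leaf_labels(self) -> frozenset[str]:
        return frozenset(n.label for n in self.root.leaves())

    def copy(self) -> "Phylotree":
        return Phylotree(self.root.copy(), self.rooted)

    # -- bipartitions -----------------------------------------------------

    def bipartitions(self) -> frozenset[frozenset[str]]:
        """Non-trivial unrooted bipartitions, each given as the side not
        containing the reference leaf (lexicographically smallest label)."""
        all_leaves = self.leaf_labels
        if len(all_leaves) < 4:
            return frozenset()
        ref = min(all_leaves)
        out: set[frozenset[str]] = set()
        below: dict[int, frozenset[str]] = {}
        for node in self.root.walk_postorder():
            if node.is_leaf:
                below[id(node)] = frozenset({node.label})
            else:
                below[id(node)] = frozenset().union(
                    *(below[id(c)] for c in node.children)
                )
        for node in self.root.walk_postorder():
            if node is self.root or node.is_leaf:
                continue
            side = below[id(node)]
            if ref in side:
                side = all_leaves - side
            if 2 <= len(side) <= len(all_leaves) - 2:
                out.add(side)
        return frozenset(out)

    def topology_key(self) -> frozenset:
        """Canonical key identifying the unrooted topology."""
        return frozenset({self.leaf_labels}) | self.bipartitions()

    def same_unrooted_topology(self, other: "Phylotree") -> bool:
        return (
            self.leaf_labels == other.leaf_labels
            and self.bipartitions() == other.bipartitions()
        )

    # -- restriction ------------------------------------------------------

    def restrict(self, labels: Iterable[str]) -> "Phylotree":
        """Induced tree on a leaf subset (suppressing degree-2 nodes)."""
        keep = set(labels)
        missing = keep - self.leaf_labels
        if missing:
            raise KeyError(f"labels not in tree: {sorted(missing)}")
        root = self.root.copy()
        root = _prune_to(root, keep)
        if root is None:
            raise ValueError("restriction removed every leaf")
        root.parent = None
        return Phylotree(root, self.rooted)

    # -- IO ---------------------------------------------------------------

    def to_newick(self, annotations: bool = False) -> str:
        return _write_newick(self.root, annotations) + ";"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "rooted" if self.rooted else "unrooted"
        return f"<Phylotree {kind} {self.to_newick()}>"


def _prune_to(node: Node, keep: set[str]) -> Node | None:
    if node.is_leaf:
        return node if node.label in keep else None
    kept = [c2 for c in node.children if (c2 := _prune_to(c, keep)) is not None]
    if not kept:
        return None
    if len(kept) == 1:
        return kept[0]
    node.children = []
    for c in kept:
        node.add(c)
    return node


# ---------------------------------------------------------------------------
# Newick


def parse_newick(text: str, rooted: bool = True) -> Phylotree:
    text = text.strip()
    if not text.endswith(";"):
        raise ValueError("newick string must end with ';'")
    pos = 0
    s = text[:-1]

    def parse_node() -> Node:
        nonlocal pos
        node = Node()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                node.add(parse_node())
                if pos >= len(s):
                    raise ValueError("unbalanced parentheses in newick")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise ValueError(f"unexpected character {s[pos]!r} in newick")
        start = pos
        while pos < len(s) and s[pos] not in ",():;":
            pos += 1
        label = s[start:pos].strip()
        if pos < len(s) and s[pos] == ":":  # branch length: parsed and dropped
            pos += 1
            while pos < len(s) and s[pos] not in ",();":
                pos += 1
        if label:
            if node.is_leaf:
                node.label = label.strip("'")
            else:
                node.annotation = label.strip("'")
        return node

    root = parse_node()
    if pos != len(s):
        raise ValueError(f"trailing characters in newick: {s[pos:]!r}")
    return Phylotree(root, rooted)


def _write_newick(node: Node, annotations: bool) -> str:
    if node.is_leaf:
        return _quote(node.label or "")
    inner = ",".join(_write_newick(c, annotations) for c in node.children)
    label = ""
    if annotations and node.annotation is not None:
        label = _quote(node.annotation)
    return f"({inner}){label}"


def _quote(label: str) -> str:
    if any(c in label for c in "(),:; \t"):
        return "'" + label + "'"
    return label


# ---------------------------------------------------------------------------
# construction helpers


def tree_from_clusters(
    all_leaves: Iterable[str],
    clusters: Iterable[frozenset[str]],
    rooted: bool = False,
) -> Phylotree:
    """Build a tree from nested leaf clusters (no two may partially overlap).

    Each cluster becomes an internal node; leaves not inside any cluster
    hang off the root.  Used by consensus construction and bipartition
    round-trips.
    """
    leaves = sorted(set(all_leaves))
    nested = sorted((c for c in set(clusters) if len(c) >= 2), key=len, reverse=True)
    for a, b in itertools.combinations(nested, 2):
        if a & b and not (a <= b or b <= a):
            raise ValueError(f"incompatible clusters {sorted(a)} / {sorted(b)}")
    root = Node()
    node_of: dict[frozenset[str], Node] = {}

    def enclosing(target: frozenset[str]) -> Node:
        best: frozenset[str] | None = None
        for cl in nested:
            if target < cl and (best is None or cl < best):
                best = cl
        return root if best is None else node_of[best]

    for cl in nested:
        node_of[cl] = enclosing(cl).add(Node())
    for leaf in leaves:
        enclosing(frozenset({leaf})).add(Node(leaf))
    _collapse_unary(root)
    return Phylotree(root, rooted)


def _collapse_unary(node: Node) -> None:
    for c in list(node.children):
        _collapse_unary(c)
    if len(node.children) == 1 and node.parent is not None:
        child = node.children[0]
        idx = node.parent.children.index(node)
        node.parent.children[idx] = child
        child.parent = node.parent


def tree_from_bipartitions(
    all_leaves: Iterable[str], bipartitions: Iterable[frozenset[str]]
) -> Phylotree:
    """Unrooted tree whose non-trivial bipartitions equal the given set.

    Bipartitions must be expressed as sides not containing the reference
    leaf (minimum label), as produced by :meth:`Phylotree.bipartitions`.
    """
    leaves = frozenset(all_leaves)
    ref = min(leaves)
    clusters = []
    for bp in bipartitions:
        side = frozenset(bp)
        if ref in side:
            side = leaves - side
        clusters.append(side)
    return tree_from_clusters(leaves, clusters, rooted=False)


def random_binary_tree(
    labels: Sequence[str], rng: random.Random | None = None
) -> Phylotree:
    """Uniform-at-random addition-order unrooted binary tree."""
    rng = rng or random.Random()
    labels = list(labels)
    if len(labels) < 3:
        raise ValueError("need at least 3 leaves")
    rng.shuffle(labels)
    root = Node()
    for lab in labels[:3]:
        root.add(Node(lab))
    edges: list[Node] = list(root.children)
    for lab in labels[3:]:
        target = rng.choice(edges)
        parent = target.parent
        mid = Node()
        idx = parent.children.index(target)
        parent.children[idx] = mid
        mid.parent = parent
        mid.add(target)
        leaf = mid.add(Node(lab))
        edges.extend([mid, leaf])
    return Phylotree(root, rooted=False)


def enumerate_unrooted_topologies(labels: Sequence[str]) -> Iterator[Phylotree]:
    """Yield every unrooted binary topology over the labels.

    (2n-5)!! trees; practical up to ~9 leaves.  Trees are emitted rooted at
    an internal node with ``rooted=False``.
    """
    labels = list(labels)
    if len(labels) < 3:
        raise ValueError("need at least 3 leaves")

    def build(tree_edges: list[tuple[int, ...]], next_label: int) -> Iterator:
        if next_label == len(labels):
            yield tree_edges
            return
        for i in range(len(tree_edges)):
            # split edge i, hang next_label off the new midpoint
            new_edges = tree_edges[:i] + tree_edges[i + 1 :]
            a = tree_edges[i]
            mid = ("m", next_label, i)
            new_edges = new_edges + [
                (a[0], mid),
                (mid, a[1]),
                (mid, ("leaf", next_label)),
            ]
            yield from build(
                [(_norm(e[0]), _norm(e[1])) for e in new_edges], next_label + 1
            )

    def _norm(x):
        return x

    # seed: star over first three leaves centred at "c"
    seed = [
        (("c",), ("leaf", 0)),
        (("c",), ("leaf", 1)),
        (("c",), ("leaf", 2)),
    ]
    for edge_list in build(seed, 3):
        yield _edges_to_tree(edge_list, labels)


def _edges_to_tree(edge_list: list[tuple], labels: Sequence[str]) -> Phylotree:
    adj: dict = {}
    for a, b in edge_list:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    start = next(k for k in adj if len(adj[k]) > 1)

    def grow(key, parent_key) -> Node:
        if isinstance(key, tuple) and len(key) == 2 and key[0] == "leaf":
            return Node(labels[key[1]])
        node = Node()
        for nb in adj[key]:
            if nb != parent_key:
                node.add(grow(nb, key))
        return node

    return Phylotree(grow(start, None), rooted=False)


def reroot_at_leaf(tree: Phylotree, label: str) -> Phylotree:
    """Return a copy rooted on the edge leading to the given leaf.

    The leaf becomes the root's first child; used for display rooting with
    an outgroup taxon.
    """
    work = tree.copy()
    target = next((n for n in work.root.leaves() if n.label == label), None)
    if target is None:
        raise KeyError(f"leaf {label!r} not in tree")
    if target.parent is None:
        return Phylotree(target, rooted=True)

    def flipped(node: Node, came_from: Node) -> Node | None:
        """Subtree seen from ``came_from`` looking 'up' through ``node``."""
        out = Node()
        out.annotation = node.annotation
        for c in node.children:
            if c is not came_from:
                c.parent = None
                out.add(c)
        if node.parent is not None:
            up = flipped(node.parent, node)
            if up is not None:
                out.add(up)
        if not out.children:
            return None
        if len(out.children) == 1:
            only = out.children[0]
            only.parent = None
            return only
        return out

    old_parent = target.parent
    new_root = Node()
    new_root.add(target)
    up = flipped(old_parent, target)
    if up is not None:
        new_root.add(up)
    return Phylotree(new_root, rooted=True)
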