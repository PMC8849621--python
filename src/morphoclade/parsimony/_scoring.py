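"""Tree-length scoring and ensemble indices.

Unordered characters are scored with Hartigan's generalisation of the Fitch
downpass (exact on polytomies, identical to Fitch on binary nodes) using
per-character state bitmasks vectorised with numpy.  Ordered (additive)
characters use a min-plus dynamic program with linear change costs.
MISSING and INAPPLICABLE cells both behave as "any observed state".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..matrix_io import INAPPLICABLE, MISSING, CharacterMatrix
from ..trees import Node, Phylotree

_INF = 1e12


class MatrixEncoding:
    """Numeric encoding of a CharacterMatrix for repeated tree scoring."""

    def __init__(self, matrix: CharacterMatrix) -> None:
        self.matrix = matrix
        self.taxon_index = {t: i for i, t in enumerate(matrix.taxa)}
        ntax = matrix.n_taxa

        u_cols: list[int] = []  # 0-based indices of active unordered chars
        o_cols: list[int] = []
        for j, meta in enumerate(matrix.char_meta):
            if not meta.active_flag or meta.weight == 0:
                continue
            (o_cols if meta.ordered_flag else u_cols).append(j)
        self.u_cols = u_cols
        self.o_cols = o_cols

        # --- unordered: bitmasks ---------------------------------------
        observed = [_observed_states(matrix, j) for j in u_cols]
        self.S_u = max((max(o) + 1 for o in observed if o), default=1)
        if self.S_u > 63:
            raise ValueError("unordered characters support at most 64 states")
        self.u_masks = np.zeros((ntax, len(u_cols)), dtype=np.uint64)
        self.u_weights = np.array(
            [matrix.char_meta[j].weight for j in u_cols], dtype=float
        )
        for k, j in enumerate(u_cols):
            universal = 0
            for s in observed[k] or {0}:
                universal |= 1 << s
            for i in range(ntax):
                cell = matrix.cells[i][j]
                if cell is MISSING or cell is INAPPLICABLE:
                    self.u_masks[i, k] = universal
                else:
                    m = 0
                    for s in cell:
                        m |= 1 << s
                    self.u_masks[i, k] = m

        # --- ordered: leaf cost vectors --------------------------------
        o_observed = [_observed_states(matrix, j) for j in o_cols]
        self.S_o = max((max(o) + 1 for o in o_observed if o), default=1)
        self.o_weights = np.array(
            [matrix.char_meta[j].weight for j in o_cols], dtype=float
        )
        self.o_costs = np.full((ntax, len(o_cols), self.S_o), _INF)
        for k, j in enumerate(o_cols):
            states = sorted(o_observed[k] or {0})
            for i in range(ntax):
                cell = matrix.cells[i][j]
                if cell is MISSING or cell is INAPPLICABLE:
                    self.o_costs[i, k, states] = 0.0
                else:
                    self.o_costs[i, k, sorted(cell)] = 0.0

    @property
    def has_ordered(self) -> bool:
        return len(self.o_cols) > 0

    @property
    def has_unordered(self) -> bool:
        return len(self.u_cols) > 0

    # -----------------------------------------------------------------
    def score(self, root: Node) -> float:
        """Weighted parsimony length of the (sub)tree hanging from root."""
        total = 0.0
        masks: dict[int, np.ndarray] = {}
        ocost: dict[int, np.ndarray] = {}
        for node in root.walk_postorder():
            if node.is_leaf:
                i = self.taxon_index[node.label]
                if self.has_unordered:
                    masks[id(node)] = self.u_masks[i]
                if self.has_ordered:
                    ocost[id(node)] = self.o_costs[i]
                continue
            ch = node.children
            if self.has_unordered:
                if len(ch) == 2:
                    a = masks.pop(id(ch[0]))
                    b = masks.pop(id(ch[1]))
                    inter = a & b
                    disjoint = inter == 0
                    if disjoint.any():
                        total += float(self.u_weights[disjoint].sum())
                    masks[id(node)] = np.where(disjoint, a | b, inter)
                elif len(ch) == 1:  # root of a pruned fragment
                    masks[id(node)] = masks.pop(id(ch[0]))
                else:
                    counts = np.zeros((self.S_u, len(self.u_cols)), dtype=np.int64)
                    one = np.uint64(1)
                    for c in ch:
                        m = masks.pop(id(c))
                        for s in range(self.S_u):
                            counts[s] += ((m >> np.uint64(s)) & one).astype(np.int64)
                    K = counts.max(axis=0)
                    total += float((self.u_weights * (len(ch) - K)).sum())
                    newmask = np.zeros(len(self.u_cols), dtype=np.uint64)
                    for s in range(self.S_u):
                        sel = counts[s] == K
                        newmask |= sel.astype(np.uint64) << np.uint64(s)
                    masks[id(node)] = newmask
            if self.has_ordered:
                acc: np.ndarray | None = None
                for c in ch:
                    f = _linear_minplus(ocost.pop(id(c)))
                    acc = f if acc is None else acc + f
                ocost[id(node)] = acc  # type: ignore[assignment]
        if self.has_ordered:
            total += float((self.o_weights * ocost[id(root)].min(axis=1)).sum())
        return total


def _linear_minplus(d: np.ndarray) -> np.ndarray:
    """min over t of d[.., t] + |s - t| for every s (linear-cost transform)."""
    f = d.copy()
    for s in range(1, f.shape[-1]):
        np.minimum(f[..., s], f[..., s - 1] + 1.0, out=f[..., s])
    for s in range(f.shape[-1] - 2, -1, -1):
        np.minimum(f[..., s], f[..., s + 1] + 1.0, out=f[..., s])
    return f


def _observed_states(matrix: CharacterMatrix, j: int) -> set[int]:
    out: set[int] = set()
    for row in matrix.cells:
        cell = row[j]
        if isinstance(cell, frozenset):
            out |= cell
    return out


def _as_steps(x: float, matrix: CharacterMatrix) -> float | int:
    if all(float(m.weight).is_integer() for m in matrix.char_meta):
        return int(round(x))
    return x


# ---------------------------------------------------------------------------
# public operations


def fitch_length(tree: Phylotree, matrix: CharacterMatrix) -> float | int:
    """Minimum weighted state changes of the matrix on the given tree.

    Polytomies are scored as given (Hartigan), not resolved.  Raises
    ``ValueError`` on a leaf/taxon mismatch.
    """
    _check_leaves(tree, matrix)
    enc = MatrixEncoding(matrix)
    return _as_steps(enc.score(tree.root), matrix)


def _check_leaves(tree: Phylotree, matrix: CharacterMatrix) -> None:
    leaves = tree.leaf_labels
    taxa = frozenset(matrix.taxa)
    if leaves != taxa:
        raise ValueError(
            f"tree/matrix taxon mismatch; only in tree: "
            f"{sorted(leaves - taxa)}, only in matrix: {sorted(taxa - leaves)}"
        )


def min_steps(matrix: CharacterMatrix) -> float | int:
    """Minimum conceivable steps M summed over active characters.

    Polymorphic cells count toward every state they contain; MISSING and
    INAPPLICABLE are ignored.  Ordered characters contribute their observed
    state range.
    """
    total = 0.0
    for j, meta in enumerate(matrix.char_meta):
        if not meta.active_flag:
            continue
        obs = _observed_states_col(matrix, j)
        if not obs:
            continue
        if meta.ordered_flag:
            steps = max(obs) - min(obs)
        else:
            steps = len(obs) - 1
        total += meta.weight * steps
    return _as_steps(total, matrix)


def max_steps(matrix: CharacterMatrix) -> float | int:
    """Maximum conceivable steps G: each character's length on a star tree."""
    total = 0.0
    for j, meta in enumerate(matrix.char_meta):
        if not meta.active_flag:
            continue
        cells = [
            c
            for c in matrix.column(j)
            if isinstance(c, frozenset)
        ]
        if not cells:
            continue
        obs = sorted(set().union(*cells))
        best = min(
            sum(min(abs(s - centre) for s in cell) for cell in cells)
            if meta.ordered_flag
            else sum(0 if centre in cell else 1 for cell in cells)
            for centre in obs
        )
        total += meta.weight * best
    return _as_steps(total, matrix)


def _observed_states_col(matrix: CharacterMatrix, j: int) -> set[int]:
    out: set[int] = set()
    for row in matrix.cells:
        if isinstance(row[j], frozenset):
            out |= row[j]
    return out


def informative_characters(matrix: CharacterMatrix) -> list[int]:
    """1-based indices of parsimony-informative characters.

    A character is informative iff its star-tree length exceeds its minimum
    conceivable length (i.e. its score can vary across topologies).
    """
    out = []
    for j, meta in enumerate(matrix.char_meta):
        if not meta.active_flag:
            continue
        sub = _single_char(matrix, j)
        if max_steps(sub) > min_steps(sub):
            out.append(j + 1)
    return out


def _single_char(matrix: CharacterMatrix, j: int) -> CharacterMatrix:
    return CharacterMatrix(
        matrix.taxa,
        tuple((row[j],) for row in matrix.cells),
        (matrix.char_meta[j],),
    )


@dataclass(frozen=True)
class ParsimonyStats:
    """Ensemble tree statistics: L observed, M minimum, G star-tree steps."""

    L: float
    M: float
    G: float
    ci: float | None
    ri: float | None

    @property
    def ci_rounded(self) -> float | None:
        return None if self.ci is None else round(self.ci, 3)

    @property
    def ri_rounded(self) -> float | None:
        return None if self.ri is None else round(self.ri, 3)


def ensemble_indices(L: float, M: float, G: float) -> ParsimonyStats:
    """CI = M/L and RI = (G-L)/(G-M); degenerate cases reported as None."""
    if not (M <= L <= G or (M == L == G)):
        raise ValueError(f"expected M <= L <= G, got M={M}, L={L}, G={G}")
    ci = None if L == 0 else M / L
    ri = None if G == M else (G - L) / (G - M)
    return ParsimonyStats(L=L, M=M, G=G, ci=ci, ri=ri)
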