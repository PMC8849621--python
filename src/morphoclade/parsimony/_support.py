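"""Bootstrap and Bremer (decay) support values."""

from __future__ import annotations

import random
from dataclasses import dataclass

from ..matrix_io import CharacterMatrix
from ._consensus import strict_consensus
from ._scoring import MatrixEncoding, _as_steps, informative_characters
from ._search import (
    SearchConfig,
    TreeSet,
    _key_str,
    _search_with_objective,
    _topology_key,
)

Bipartition = frozenset


@dataclass(frozen=True)
class BootstrapResult:
    """Per-bipartition support percentages; ``supports is None`` means NA
    (no parsimony-informative characters)."""

    supports: dict[Bipartition, float] | None
    n_reps: int

    def support(self, bipartition: Bipartition) -> float | None:
        if self.supports is None:
            return None
        return self.supports.get(frozenset(bipartition), 0.0)


def bootstrap_support(
    matrix: CharacterMatrix,
    n_reps: int = 1000,
    search_config: SearchConfig = SearchConfig(n_replicates=10, swapper="SPR"),
    seed: int = 0,
) -> BootstrapResult:
    """Character resampling with replacement; support of a bipartition is the
    percentage of replicates whose strict consensus of best trees contains it."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if not informative_characters(matrix):
        return BootstrapResult(None, n_reps)
    rng = random.Random(seed)
    ref = min(matrix.taxa)
    full = frozenset(matrix.taxa)
    counts: dict[Bipartition, int] = {}
    nchar = matrix.n_characters
    for _ in range(n_reps):
        cols = [rng.randrange(nchar) for _ in range(nchar)]
        resampled = CharacterMatrix(
            matrix.taxa,
            tuple(tuple(row[j] for j in cols) for row in matrix.cells),
            tuple(matrix.char_meta[j] for j in cols),
        )
        enc = MatrixEncoding(resampled)
        _, best = _search_with_objective(
            resampled.taxa, enc.score, search_config, rng
        )
        shared = frozenset.intersection(
            *(frozenset(k) for k in best.keys())
        )
        for side in shared:
            norm = full - side if ref in side else side
            counts[norm] = counts.get(norm, 0) + 1
    supports = {bp: 100.0 * c / n_reps for bp, c in counts.items()}
    return BootstrapResult(supports, n_reps)


@dataclass(frozen=True)
class BremerResult:
    """Decay values per strict-consensus bipartition; ``capped`` lists the
    bipartitions whose reverse-constraint search hit ``max_decay``."""

    decays: dict[Bipartition, float | int]
    capped: frozenset[Bipartition]

    def decay(self, bipartition: Bipartition) -> float | int:
        # a bipartition absent from the consensus decays at zero extra steps
        return self.decays.get(frozenset(bipartition), 0)


def bremer_support(
    matrix: CharacterMatrix,
    mpts: TreeSet,
    max_decay: int = 10,
    search_config: SearchConfig = SearchConfig(n_replicates=10, swapper="TBR"),
    seed: int = 0,
) -> BremerResult:
    """Reverse-constraint decay: for each consensus bipartition, the extra
    steps of the best tree lacking it."""
    if max_decay < 1:
        raise ValueError("max_decay must be >= 1")
    consensus = strict_consensus(mpts)
    targets = sorted(consensus.bipartitions(), key=lambda b: sorted(b))
    L = float(mpts.length)
    enc = MatrixEncoding(matrix)
    penalty = float(max_decay) + L + 1.0
    ref = min(matrix.taxa)
    full = frozenset(matrix.taxa)
    decays: dict[Bipartition, float | int] = {}
    capped: set[Bipartition] = set()
    rng = random.Random(seed)
    for bp in targets:
        def objective(root, _bp=frozenset(bp)):
            s = enc.score(root)
            key = _topology_key(root)
            sides = set()
            for side in key:
                sides.add(side)
                sides.add(full - side)
            if _bp in sides:
                s += penalty
            return s

        best_score, _ = _search_with_objective(
            matrix.taxa, objective, search_config, rng
        )
        decay = best_score - L
        if decay >= max_decay:
            decays[frozenset(bp)] = max_decay
            capped.add(frozenset(bp))
        else:
            decays[frozenset(bp)] = _as_steps(decay, matrix)
    return BremerResult(decays, frozenset(capped))
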