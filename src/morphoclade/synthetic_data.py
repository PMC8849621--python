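"""Seeded generators for every input the analysis stages consume.

All generators are deterministic given their spec's ``seed`` and produce
the same in-memory objects the analysis modules take, so the whole
pipeline is testable without external files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .caudal_series import VertebraRecord
from .matrix_io import MISSING, CharacterMatrix
from .trees import Phylotree

PROCESSES = ("homoplasy-free", "poisson")


# ---------------------------------------------------------------------------
# discrete character matrices


@dataclass(frozen=True)
class MatrixSimSpec:
    """Characters evolved independently on a known tree.

    ``homoplasy-free``: each character changes exactly once, on one branch
    drawn uniformly at random (derived state 1 against ancestral 0), so the
    generating tree scores the matrix with CI = 1.  ``poisson``: a root
    state plus Poisson(rate x branch_length) changes per branch, each to a
    fresh uniformly drawn different state.
    """

    tree: Phylotree
    n_characters: int
    n_states: int = 4
    process: str = "homoplasy-free"
    rate: float = 0.5
    missing_fraction: float = 0.0
    seed: int = 0
    branch_lengths: float = 1.0

    def __post_init__(self) -> None:
        if self.n_characters < 1:
            raise ValueError("n_characters must be >= 1")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must be in [0, 1)")
        if self.process not in PROCESSES:
            raise ValueError(f"process must be one of {PROCESSES}")
        if self.n_states < 2:
            raise ValueError("n_states must be >= 2")
        if self.rate < 0 or self.branch_lengths < 0:
            raise ValueError("rate and branch lengths must be >= 0")


def simulate_matrix(spec: MatrixSimSpec) -> tuple[CharacterMatrix, Phylotree]:
    """Evolve a matrix on ``spec.tree``; returns (matrix, generating tree)."""
    tree = spec.tree
    leaves = tree.root.leaves()
    if len(leaves) < 3:
        raise ValueError("generating tree needs at least 3 leaves")
    rng = np.random.default_rng(spec.seed)
    nodes = list(tree.root.walk_postorder())
    branches = [n for n in nodes if n.parent is not None]
    taxa = tuple(n.label for n in leaves)
    leaf_ids = {id(n): i for i, n in enumerate(leaves)}

    columns = np.zeros((len(leaves), spec.n_characters), dtype=np.int64)
    for c in range(spec.n_characters):
        if spec.process == "homoplasy-free":
            branch = branches[rng.integers(len(branches))]
            derived = {id(n) for n in branch.walk_postorder()}
            for n in leaves:
                columns[leaf_ids[id(n)], c] = 1 if id(n) in derived else 0
        else:
            state: dict[int, int] = {id(tree.root): int(rng.integers(spec.n_states))}
            for n in reversed(nodes):  # preorder: parents before children
                if n.parent is None:
                    continue
                s = state[id(n.parent)]
                k = rng.poisson(spec.rate * spec.branch_lengths)
                for _ in range(k):
                    step = int(rng.integers(spec.n_states - 1))
                    s = step if step < s else step + 1  # uniform over others
                state[id(n)] = s
            for n in leaves:
                columns[leaf_ids[id(n)], c] = state[id(n)]

    mask = rng.random(columns.shape) < spec.missing_fraction
    cells = tuple(
        tuple(
            MISSING if mask[i, c] else frozenset({int(columns[i, c])})
            for c in range(spec.n_characters)
        )
        for i in range(len(leaves))
    )
    return CharacterMatrix(taxa, cells), tree.copy()


# ---------------------------------------------------------------------------
# caudal series


@dataclass(frozen=True)
class CaudalSimSpec:
    """Geometric ASI/length decay with lognormal multiplicative noise."""

    n_vertebrae: int
    anchor_asi: float = 1.0
    asi_decay: float = 0.9
    length_decay: float = 0.97
    noise_sd: float = 0.0
    diapophysis_cutoff: int = 10
    anchor_length: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_vertebrae < 1:
            raise ValueError("n_vertebrae must be >= 1")
        for name in ("asi_decay", "length_decay"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.anchor_asi <= 0 or self.anchor_length <= 0:
            raise ValueError("anchor ASI and length must be > 0")


def simulate_caudal_series(
    spec: CaudalSimSpec,
) -> tuple[list[VertebraRecord], tuple[str, ...]]:
    """Returns (records in shuffled order, true anterior-to-posterior ids).

    Facet diameters are back-computed from the target ASI under the ellipse
    model with a circular facet, so re-deriving ASI from the records
    reproduces the generated profile exactly (at noise 0).
    """
    rng = np.random.default_rng(spec.seed)
    records = []
    true_order = []
    for p in range(1, spec.n_vertebrae + 1):
        noise_a = float(np.exp(rng.normal(0.0, spec.noise_sd))) if spec.noise_sd else 1.0
        noise_l = float(np.exp(rng.normal(0.0, spec.noise_sd))) if spec.noise_sd else 1.0
        asi_p = spec.anchor_asi * spec.asi_decay ** (p - 1) * noise_a
        length = spec.anchor_length * spec.length_decay ** (p - 1) * noise_l
        area = asi_p * length * length
        diameter = float(np.sqrt(4.0 * area / np.pi))
        vid = f"V{p:02d}"
        true_order.append(vid)
        records.append(
            VertebraRecord(
                vertebra_id=vid,
                centrum_length=length,
                facet_dv_diameter=diameter,
                facet_ml_diameter=diameter,
                has_diapophysis=p <= spec.diapophysis_cutoff,
                anchor_flag=p == 1,
            )
        )
    perm = rng.permutation(len(records))
    shuffled = [records[i] for i in perm]
    return shuffled, tuple(true_order)


# ---------------------------------------------------------------------------
# grouped measurement tables


@dataclass(frozen=True)
class GroupSpec:
    label: str
    mean: tuple[float, ...]
    cov: tuple[tuple[float, ...], ...]
    n: int


@dataclass(frozen=True)
class MeasurementSimSpec:
    """Multi-group multivariate-normal measurements times a shared positive
    size factor (lognormal); large ``size_factor_var`` drives a dominant
    PC1 as in size-driven morphometric data."""

    groups: tuple[GroupSpec, ...]
    variables: tuple[str, ...]
    size_factor_var: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("need at least one group")
        p = len(self.variables)
        for g in self.groups:
            if g.n < 1:
                raise ValueError(f"group {g.label!r} needs n >= 1")
            if len(g.mean) != p:
                raise ValueError(f"group {g.label!r} mean has wrong length")
            cov = np.asarray(g.cov, dtype=float)
            if cov.shape != (p, p):
                raise ValueError(f"group {g.label!r} covariance has wrong shape")
            if not np.allclose(cov, cov.T):
                raise ValueError(f"group {g.label!r} covariance not symmetric")
            if np.linalg.eigvalsh(cov).min() < -1e-9:
                raise ValueError(f"group {g.label!r} covariance not PSD")
        if self.size_factor_var < 0:
            raise ValueError("size_factor_var must be >= 0")


def simulate_measurements(spec: MeasurementSimSpec) -> pd.DataFrame:
    """Draws rejected and redrawn until strictly positive."""
    rng = np.random.default_rng(spec.seed)
    sd_log = float(np.sqrt(spec.size_factor_var))
    rows = []
    for g in spec.groups:
        mean = np.asarray(g.mean, dtype=float)
        cov = np.asarray(g.cov, dtype=float)
        for i in range(g.n):
            for _ in range(10000):
                x = rng.multivariate_normal(mean, cov, method="svd")
                size = np.exp(rng.normal(0.0, sd_log)) if sd_log else 1.0
                x = x * size
                if (x > 0).all():
                    break
            else:
                raise RuntimeError(
                    f"could not draw a positive sample for group {g.label!r}"
                )
            row = {"specimen_id": f"{g.label}-{i + 1:03d}", "group": g.label}
            row.update({v: float(val) for v, val in zip(spec.variables, x)})
            rows.append(row)
    return pd.DataFrame(rows)
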