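"""Tooth, dentary and ungual quantitative comparisons.

Measurement rows are plain dataclasses (or any mapping/DataFrame with the
same column names); ratios are always recomputed from the base
measurements, never stored.  PCA is an eigendecomposition of the
covariance (raw or log) or correlation matrix of the chosen variables,
with loadings signed so the largest-magnitude loading of each component
is positive.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SCALINGS = ("covariance-raw", "covariance-log", "correlation")

#: |loading| threshold (as a fraction of the component's largest |loading|)
#: separating "strong" from "weak" in loading sign reports.
STRENGTH_FRACTION = 0.3


@dataclass(frozen=True)
class ToothRecord:
    """Crown measurements in mm; AL optional. CBR/CHR are derived."""

    specimen_id: str
    group: str
    CBL: float
    CBW: float
    CH: float
    AL: float | None = None

    def __post_init__(self) -> None:
        for name in ("CBL", "CBW", "CH"):
            v = getattr(self, name)
            if v is None or v <= 0:
                raise ValueError(f"{name} must be > 0, got {v!r}")
        if self.AL is not None and self.AL <= 0:
            raise ValueError(f"AL must be > 0 when present, got {self.AL}")

    @property
    def CBR(self) -> float:
        return self.CBW / self.CBL

    @property
    def CHR(self) -> float:
        return self.CH / self.CBL


@dataclass(frozen=True)
class UngualRecord:
    specimen_id: str
    group: str
    total_length: float
    proximal_ml_diameter: float
    proximal_dv_diameter: float
    midlength_ml_diameter: float | None = None
    midlength_dv_diameter: float | None = None
    curvature_deg: float | None = None

    def __post_init__(self) -> None:
        for name in (
            "total_length",
            "proximal_ml_diameter",
            "proximal_dv_diameter",
            "midlength_ml_diameter",
            "midlength_dv_diameter",
        ):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        if self.curvature_deg is not None and not 0 < self.curvature_deg < 180:
            raise ValueError(
                f"curvature must be in (0, 180) degrees, got {self.curvature_deg}"
            )


@dataclass(frozen=True)
class AlveolusRecord:
    specimen_id: str
    position: int  # 1-based from the mesial end
    mesiodistal_diameter: float
    labiolingual_diameter: float
    height_labial: float
    height_lingual: float

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("alveolus position is 1-based")
        for name in (
            "mesiodistal_diameter",
            "labiolingual_diameter",
            "height_labial",
            "height_lingual",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


# ---------------------------------------------------------------------------


def derive_tooth_ratios(record: ToothRecord) -> tuple[float, float]:
    """(CBR, CHR) = (CBW/CBL, CH/CBL); scale-invariant."""
    return record.CBR, record.CHR


def drop_incomplete(
    records: Sequence, required_fields: Iterable[str]
) -> list:
    """Keep only records with every required field present (not None/NaN)."""
    required = list(required_fields)
    kept = []
    for r in records:
        row = _as_mapping(r)
        if all(_present(row.get(f)) for f in required):
            kept.append(r)
    return kept


def _present(v) -> bool:
    if v is None:
        return False
    if isinstance(v, float) and math.isnan(v):
        return False
    return True


def _as_mapping(record) -> Mapping:
    if isinstance(record, Mapping):
        return record
    if dataclasses.is_dataclass(record):
        row = dataclasses.asdict(record)
        # expose derived ratios so they can be PCA variables
        for derived in ("CBR", "CHR"):
            if hasattr(type(record), derived):
                row[derived] = getattr(record, derived)
        return row
    if isinstance(record, pd.Series):
        return record.to_dict()
    raise TypeError(f"unsupported record type {type(record)!r}")


def records_frame(records: Sequence) -> pd.DataFrame:
    """Tabulate records (dataclasses or mappings) into a DataFrame."""
    return pd.DataFrame([_as_mapping(r) for r in records])


# ---------------------------------------------------------------------------
# PCA


@dataclass(frozen=True)
class PCAResult:
    eigenvalues: np.ndarray  # descending
    variance_fractions: np.ndarray
    loadings: pd.DataFrame  # variables x components
    scores: pd.DataFrame  # specimens x components (+ group column)
    scaling: str

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


def run_pca(
    records: Sequence | pd.DataFrame,
    variables: Sequence[str],
    scaling: str = "covariance-raw",
) -> PCAResult:
    """PCA of the chosen variables under the chosen scaling.

    ``covariance-raw`` centres the raw data, ``covariance-log`` centres
    log-transformed data, ``correlation`` standardises each variable.
    """
    if scaling not in SCALINGS:
        raise ValueError(f"scaling must be one of {SCALINGS}")
    if len(variables) < 2:
        raise ValueError("need at least 2 variables")
    df = records if isinstance(records, pd.DataFrame) else records_frame(records)
    missing_cols = [v for v in variables if v not in df.columns]
    if missing_cols:
        raise KeyError(f"variables not in table: {missing_cols}")
    X = df.loc[:, list(variables)].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError(
            "missing values in PCA variables; apply drop_incomplete first"
        )
    if X.shape[0] < 2:
        raise ValueError("need at least 2 complete records")
    if scaling == "covariance-log":
        if (X <= 0).any():
            raise ValueError("log scaling requires positive measurements")
        X = np.log(X)
    Xc = X - X.mean(axis=0)
    if scaling == "correlation":
        sd = X.std(axis=0, ddof=1)
        zero = [v for v, s in zip(variables, sd) if s == 0]
        if zero:
            raise ValueError(f"zero-variance variables under correlation scaling: {zero}")
        Xc = Xc / sd
    cov = (Xc.T @ Xc) / (X.shape[0] - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # sign convention: largest-|loading| entry of each component positive
    for k in range(eigvecs.shape[1]):
        pivot = np.argmax(np.abs(eigvecs[:, k]))
        if eigvecs[pivot, k] < 0:
            eigvecs[:, k] = -eigvecs[:, k]
    total = eigvals.sum()
    fractions = eigvals / total if total > 0 else np.zeros_like(eigvals)
    comps = [f"PC{i + 1}" for i in range(len(eigvals))]
    loadings = pd.DataFrame(eigvecs, index=list(variables), columns=comps)
    scores_arr = Xc @ eigvecs
    index = (
        df["specimen_id"].tolist()
        if "specimen_id" in df.columns
        else list(range(len(df)))
    )
    scores = pd.DataFrame(scores_arr, index=index, columns=comps)
    if "group" in df.columns:
        scores["group"] = df["group"].tolist()
    return PCAResult(eigvals, fractions, loadings, scores, scaling)


def loading_sign_report(
    pca: PCAResult, component: int, strength_fraction: float = STRENGTH_FRACTION
) -> dict[str, tuple[str, str]]:
    """Per-variable (sign, strength) on a 1-based component."""
    if not 1 <= component <= pca.n_components:
        raise ValueError(
            f"component {component} out of range 1..{pca.n_components}"
        )
    col = pca.loadings[f"PC{component}"]
    cutoff = strength_fraction * col.abs().max()
    out = {}
    for var, val in col.items():
        sign = "positive" if val >= 0 else "negative"
        strength = "strong" if abs(val) >= cutoff else "weak"
        out[var] = (sign, strength)
    return out


# ---------------------------------------------------------------------------
# morphospace membership


@dataclass(frozen=True)
class HullResult:
    status: str  # "inside" | "outside"
    method: str  # "hull" | "pc1-interval"

    def __eq__(self, other: object) -> bool:
        if isinstance(other, str):
            return self.status == other
        if isinstance(other, HullResult):
            return (self.status, self.method) == (other.status, other.method)
        return NotImplemented


def hull_membership(
    scores: pd.DataFrame, group_label: str, query_id: str, tol: float = 1e-9
) -> HullResult:
    """Is the query inside the group's convex hull in the PC1-PC2 plane?

    Boundary points count as inside.  Degenerate groups (<3 points or
    collinear) fall back to an interval test on PC1, flagged by ``method``.
    """
    if "group" not in scores.columns:
        raise KeyError("scores table lacks a 'group' column")
    if query_id not in scores.index:
        raise KeyError(f"unknown query specimen {query_id!r}")
    pts = scores.loc[scores["group"] == group_label, ["PC1", "PC2"]].to_numpy()
    if len(pts) == 0:
        raise ValueError(f"no specimens in group {group_label!r}")
    q = scores.loc[query_id, ["PC1", "PC2"]].to_numpy(dtype=float)
    if q.ndim > 1:
        raise ValueError(f"query id {query_id!r} is not unique")
    scale = max(1.0, float(np.abs(pts).max()))
    if len(pts) < 3 or _collinear(pts, tol * scale):
        lo, hi = pts[:, 0].min(), pts[:, 0].max()
        inside = lo - tol * scale <= q[0] <= hi + tol * scale
        return HullResult("inside" if inside else "outside", "pc1-interval")
    from scipy.spatial import ConvexHull

    hull = ConvexHull(pts)
    # hull.equations: outward normals; inside iff all n.x + b <= 0
    vals = hull.equations[:, :2] @ q + hull.equations[:, 2]
    inside = bool((vals <= tol * scale).all())
    return HullResult("inside" if inside else "outside", "hull")


def _collinear(pts: np.ndarray, tol: float) -> bool:
    if len(pts) < 3:
        return True
    centered = pts - pts.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    return s[-1] <= tol * max(1.0, s[0])


# ---------------------------------------------------------------------------
# dentary alveoli


def alveolus_profiles(
    records: Sequence[AlveolusRecord], specimen_id: str
) -> pd.DataFrame:
    """Per-position compression ratio and mean dentary height, sorted."""
    rows = [r for r in records if r.specimen_id == specimen_id]
    if not rows:
        raise ValueError(f"no alveoli for specimen {specimen_id!r}")
    positions = [r.position for r in rows]
    if len(set(positions)) != len(positions):
        dupes = sorted({p for p in positions if positions.count(p) > 1})
        raise ValueError(f"duplicate alveolus positions {dupes} for {specimen_id!r}")
    rows.sort(key=lambda r: r.position)
    return pd.DataFrame(
        {
            "position": [r.position for r in rows],
            "compression_ratio": [
                r.labiolingual_diameter / r.mesiodistal_diameter for r in rows
            ],
            "mean_height": [
                (r.height_labial + r.height_lingual) / 2 for r in rows
            ],
        }
    ).set_index("position")


# ---------------------------------------------------------------------------
# curvature vs length nearest neighbour


def nearest_specimen(
    dataset: Sequence[tuple[str, float, float]] | pd.DataFrame,
    query: tuple[float, float],
    standardize: bool = True,
) -> str:
    """Closest specimen to (curvature_deg, length_mm) under Euclidean
    distance after per-axis z-scoring over the dataset; ties go to the
    earlier row."""
    if isinstance(dataset, pd.DataFrame):
        ids = dataset["specimen_id"].tolist()
        pts = dataset[["curvature_deg", "length_mm"]].to_numpy(dtype=float)
    else:
        ids = [d[0] for d in dataset]
        pts = np.array([[d[1], d[2]] for d in dataset], dtype=float)
    if len(ids) == 0:
        raise ValueError("empty dataset")
    q = np.asarray(query, dtype=float)
    if standardize:
        mean = pts.mean(axis=0)
        sd = pts.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        pts = (pts - mean) / sd
        q = (q - mean) / sd
    d2 = ((pts - q) ** 2).sum(axis=1)
    return ids[int(np.argmin(d2))]
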