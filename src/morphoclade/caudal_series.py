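"""Anterior Surface Index (ASI) and caudal-vertebra seriation.

ASI = anterior centrum facet area / centrum length², a dimensionless size
profile.  A qualitatively identified anchor vertebra defines 100%; the
rest of a series is ordered by descending ASI and can be matched against a
template profile (per-position %ASI of a reference tail) by a monotone
minimum-|Δ%ASI| dynamic-programming alignment, subject to the constraint
that diapophysis-bearing vertebrae sit at or before the template's last
diapophysis position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

AREA_MODELS = ("ellipse", "rectangle")

#: Last caudal position bearing a diapophysis, per comparative taxon
#: (transcribed from the cited osteological literature).
LAST_DIAPOPHYSIS: dict[str, tuple[int, int]] = {
    "Dilophosaurus": (17, 17),
    "Spinosaurus": (16, 19),
    "Concavenator": (19, 20),
    "Majungasaurus": (25, 25),
    "Gorgosaurus": (12, 12),
    "Tyrannosaurus": (17, 17),
}


@dataclass(frozen=True)
class VertebraRecord:
    """One caudal vertebra; give the facet area directly or both facet
    diameters (area is then derived under the chosen model)."""

    vertebra_id: str
    centrum_length: float
    facet_dv_diameter: float | None = None
    facet_ml_diameter: float | None = None
    facet_area: float | None = None
    has_diapophysis: bool = False
    anchor_flag: bool = False

    def __post_init__(self) -> None:
        if self.centrum_length <= 0:
            raise ValueError("centrum length must be > 0")
        if self.facet_area is not None and self.facet_area <= 0:
            raise ValueError("facet area must be > 0 when present")
        has_diams = (
            self.facet_dv_diameter is not None
            and self.facet_ml_diameter is not None
        )
        if self.facet_area is None and not has_diams:
            raise ValueError(
                f"{self.vertebra_id}: need facet area or both facet diameters"
            )
        for d in (self.facet_dv_diameter, self.facet_ml_diameter):
            if d is not None and d <= 0:
                raise ValueError("facet diameters must be > 0")

    def area(self, model: str = "ellipse") -> float:
        if self.facet_area is not None:
            return self.facet_area
        return facet_area(
            self.facet_dv_diameter, self.facet_ml_diameter, model
        )

    def asi(self, model: str = "ellipse") -> float:
        return asi(self.area(model), self.centrum_length)


@dataclass(frozen=True)
class TemplateProfile:
    """Reference tail: per caudal position, optional %ASI (relative to
    position 1), optional %length, optional diapophysis presence."""

    taxon: str
    positions: tuple[int, ...]
    pct_asi: tuple[float | None, ...]
    pct_length: tuple[float | None, ...] = ()
    has_diapophysis: tuple[bool | None, ...] = ()
    last_diapophysis: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if list(self.positions) != sorted(set(self.positions)):
            raise ValueError("template positions must be strictly increasing")
        if len(self.pct_asi) != len(self.positions):
            raise ValueError("pct_asi length mismatch")
        for p in self.pct_asi:
            if p is not None and not 0 < p <= 150:
                raise ValueError(f"%ASI {p} outside (0, 150]")

    def asi_positions(self) -> list[tuple[int, float]]:
        return [
            (pos, pct)
            for pos, pct in zip(self.positions, self.pct_asi)
            if pct is not None
        ]


@dataclass(frozen=True)
class SeriesAssignment:
    order: tuple[str, ...]
    asi: dict[str, float]
    pct_asi: dict[str, float]
    positions: dict[str, int]
    notes: tuple[str, ...] = ()


# ---------------------------------------------------------------------------


def facet_area(dv_diameter: float, ml_diameter: float, model: str = "ellipse") -> float:
    """Facet area from its two diameters: pi*dv*ml/4 (ellipse) or dv*ml."""
    if model not in AREA_MODELS:
        raise ValueError(f"model must be one of {AREA_MODELS}")
    if dv_diameter <= 0 or ml_diameter <= 0:
        raise ValueError("diameters must be > 0")
    if model == "ellipse":
        return math.pi * dv_diameter * ml_diameter / 4.0
    return dv_diameter * ml_diameter


def asi(area: float, length: float) -> float:
    """Anterior Surface Index: facet area / centrum length² (dimensionless)."""
    if area <= 0 or length <= 0:
        raise ValueError("area and length must be > 0")
    return area / (length * length)


def _anchor(series: Sequence[VertebraRecord]) -> VertebraRecord:
    anchors = [v for v in series if v.anchor_flag]
    if not anchors:
        raise ValueError("no anchor vertebra designated")
    if len(anchors) > 1:
        raise ValueError(
            f"multiple anchors: {[v.vertebra_id for v in anchors]}"
        )
    return anchors[0]


def asi_profile(
    series: Sequence[VertebraRecord], model: str = "ellipse"
) -> dict[str, tuple[float, float]]:
    """Per vertebra: (ASI, %ASI of the anchor). Anchor maps to exactly 100."""
    anchor = _anchor(series)
    a0 = anchor.asi(model)
    return {
        v.vertebra_id: (v.asi(model), 100.0 * v.asi(model) / a0)
        for v in series
    }


def length_profile(series: Sequence[VertebraRecord]) -> dict[str, float]:
    """Per vertebra: centrum length as % of the anchor's."""
    anchor = _anchor(series)
    return {
        v.vertebra_id: 100.0 * v.centrum_length / anchor.centrum_length
        for v in series
    }


def order_series(
    series: Sequence[VertebraRecord], model: str = "ellipse"
) -> tuple[str, ...]:
    """Anchor first, then descending ASI; ties broken by descending centrum
    length, then id."""
    ids = [v.vertebra_id for v in series]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate vertebra ids: {dupes}")
    anchor = _anchor(series)
    rest = sorted(
        (v for v in series if v is not anchor),
        key=lambda v: (-v.asi(model), -v.centrum_length, v.vertebra_id),
    )
    return (anchor.vertebra_id,) + tuple(v.vertebra_id for v in rest)


def diapophysis_bounds(template_taxon: str) -> int | tuple[int, int]:
    """Literature-derived last-diapophysis caudal position for a taxon."""
    try:
        lo, hi = LAST_DIAPOPHYSIS[template_taxon]
    except KeyError:
        raise KeyError(
            f"unknown template taxon {template_taxon!r}; "
            f"known: {sorted(LAST_DIAPOPHYSIS)}"
        ) from None
    return lo if lo == hi else (lo, hi)


def assign_positions(
    profile: Sequence[tuple[str, float]],
    template: TemplateProfile,
    diapophysis_flags: dict[str, bool] | None = None,
) -> SeriesAssignment:
    """Monotone nearest-%ASI alignment of an ordered series onto a template.

    ``profile`` is the ordered series as (vertebra_id, %ASI) pairs (anchor
    first at 100).  Positions are strictly increasing along the order and
    any diapophysis-bearing vertebra must land at or before the template's
    last-diapophysis upper bound; total |Δ%ASI| is minimised by dynamic
    programming and ties go to earlier template positions.
    """
    flags = diapophysis_flags or {}
    slots = template.asi_positions()
    if not slots:
        raise ValueError("template has no %ASI values")
    k, m = len(profile), len(slots)
    if k > m:
        raise ValueError(
            f"{k} vertebrae cannot map to {m} template positions"
        )
    bound = None
    if template.last_diapophysis is not None:
        bound = template.last_diapophysis[1]
    INF = float("inf")

    def cell_cost(i: int, j: int) -> float:
        vid, pct = profile[i]
        pos, tpct = slots[j]
        if bound is not None and flags.get(vid, False) and pos > bound:
            return INF
        return abs(pct - tpct)

    # dp[i][j]: min cost assigning vertebrae 0..i with vertebra i at slot j
    dp = [[INF] * m for _ in range(k)]
    back = [[-1] * m for _ in range(k)]
    for j in range(m):
        dp[0][j] = cell_cost(0, j)
    for i in range(1, k):
        best_prev, best_idx = INF, -1
        for j in range(i, m):
            if dp[i - 1][j - 1] < best_prev:  # strict '<': earlier slot wins ties
                best_prev, best_idx = dp[i - 1][j - 1], j - 1
            c = cell_cost(i, j)
            if best_prev < INF and c < INF:
                dp[i][j] = best_prev + c
                back[i][j] = best_idx
    end = min(range(k - 1, m), key=lambda j: (dp[k - 1][j], j))
    if dp[k - 1][end] == INF:
        raise ValueError(
            "no feasible assignment: diapophysis constraint cannot be met"
        )
    chosen = [0] * k
    j = end
    for i in range(k - 1, -1, -1):
        chosen[i] = j
        j = back[i][j]
    positions = {profile[i][0]: slots[chosen[i]][0] for i in range(k)}
    pct = {vid: p for vid, p in profile}
    notes = []
    if bound is not None:
        notes.append(f"diapophysis positions constrained to <= {bound}")
    return SeriesAssignment(
        order=tuple(vid for vid, _ in profile),
        asi={},
        pct_asi=pct,
        positions=positions,
        notes=tuple(notes),
    )
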