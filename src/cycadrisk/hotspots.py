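"""Hotspot extraction, overlap (Venn) analysis, and protected-area coverage.

A hotspot set is the richest ``p`` percent of occupied grid cells for one
diversity metric (2.5% and 5% tiers by default): cells are ranked by value
descending with ties broken by ascending cell id, and ceil(p/100 * n) cells
are taken, so membership is invariant under any strictly monotone transform
of the metric.  A cell counts as protected when at least half of its area is
covered by protected areas (protected fraction >= 0.5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "HotspotError",
    "HotspotSet",
    "ProtectionReport",
    "CumulativeHotspots",
    "select_hotspots",
    "hotspot_overlap",
    "cumulative_hotspots",
    "protection_coverage",
    "DEFAULT_CELL_AREA_KM2",
    "PROTECTED_CELL_THRESHOLD",
]

#: nominal area of one grid cell (100 x 100 km).
DEFAULT_CELL_AREA_KM2 = 10_000.0

#: a cell is protected iff its protected fraction is at least this value.
PROTECTED_CELL_THRESHOLD = 0.5


class HotspotError(ValueError):
    """Invalid hotspot input."""


@dataclass
class HotspotSet:
    metric: str
    threshold_percent: float
    cells: frozenset[int]
    #: cells in rank order (best first), for reporting
    ranked_cells: tuple[int, ...] = field(default=(), repr=False)

    def __len__(self) -> int:
        return len(self.cells)


def select_hotspots(values: pd.Series, threshold_percent: float) -> HotspotSet:
    """Top ``threshold_percent`` of occupied cells by metric value.

    ``values`` maps occupied cell ids to the metric; the count of selected
    cells is ceil(p/100 * n_occupied), ties resolved by ascending cell id.
    """
    if len(values) == 0:
        raise HotspotError("no occupied cells to rank")
    if not (0.0 < threshold_percent <= 100.0):
        raise HotspotError("threshold percent must be in (0, 100]")
    k = math.ceil(threshold_percent / 100.0 * len(values))
    ranked = sorted(values.items(), key=lambda kv: (-kv[1], kv[0]))
    chosen = tuple(int(c) for c, _ in ranked[:k])
    return HotspotSet(
        metric=str(values.name or "metric"),
        threshold_percent=float(threshold_percent),
        cells=frozenset(chosen),
        ranked_cells=chosen,
    )


def hotspot_overlap(sets: Sequence[HotspotSet]) -> dict[tuple[str, ...], int]:
    """Exclusive Venn region counts over the hotspot sets.

    Returns every nonempty combination of set names (tuple, in input order)
    mapped to the number of cells belonging to exactly those sets; the
    counts partition the union.
    """
    if len(sets) < 2:
        raise HotspotError("overlap needs at least two hotspot sets")
    names = [s.metric for s in sets]
    if len(set(names)) != len(names):
        raise HotspotError("hotspot sets must have distinct metric names")
    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, len(sets) + 1):
        for combo in combinations(range(len(sets)), r):
            regions[tuple(names[i] for i in combo)] = 0
    union = set().union(*(s.cells for s in sets))
    for cell in union:
        signature = tuple(names[i] for i, s in enumerate(sets) if cell in s.cells)
        regions[signature] += 1
    return regions


@dataclass
class CumulativeHotspots:
    union_cells: frozenset[int]
    area_km2: float
    percent_of_occupied: float | None

    def to_dict(self) -> dict:
        return {
            "n_cells": len(self.union_cells),
            "area_km2": self.area_km2,
            "percent_of_occupied": self.percent_of_occupied,
        }


def cumulative_hotspots(
    sets: Sequence[HotspotSet],
    cell_area_km2: float = DEFAULT_CELL_AREA_KM2,
    n_occupied: int | None = None,
) -> CumulativeHotspots:
    """Union of the hotspot sets with its total area.

    The area is |union| * cell area (10,000 km2 per nominal 100 x 100 km
    cell); when the number of occupied cells is supplied the union is also
    expressed as a percent of occupied cells.
    """
    if not sets:
        raise HotspotError("need at least one hotspot set")
    union = frozenset().union(*(s.cells for s in sets))
    pct = 100.0 * len(union) / n_occupied if n_occupied else None
    return CumulativeHotspots(union, len(union) * cell_area_km2, pct)


@dataclass
class ProtectionReport:
    per_set: dict[str, dict]
    overall_coverage: float
    rule_threshold: float
    gaps: list[str]   # hotspot sets not fully inside protected cells

    def to_dict(self) -> dict:
        return {
            "rule_threshold": self.rule_threshold,
            "per_set": self.per_set,
            "overall_coverage": self.overall_coverage,
            "gaps": self.gaps,
        }


def protection_coverage(
    sets: Sequence[HotspotSet],
    mask: pd.Series,
    threshold: float = PROTECTED_CELL_THRESHOLD,
) -> ProtectionReport:
    """Fraction of each hotspot set falling in protected cells.

    ``mask`` maps cell ids to the protected fraction of the cell; a cell is
    protected iff its fraction is >= ``threshold`` (strict at-least-half
    rule).  Sets with coverage < 1 are flagged as protection gaps.
    """
    if not sets:
        raise HotspotError("need at least one hotspot set")
    union = set().union(*(s.cells for s in sets))
    missing = sorted(c for c in union if c not in mask.index)
    if missing:
        raise HotspotError(
            "mask missing cells: " + ", ".join(map(str, missing))
        )
    protected = {int(c) for c in union if mask.loc[c] >= threshold}
    per_set = {}
    gaps = []
    for s in sets:
        n = len(s.cells)
        n_prot = len(s.cells & protected)
        cov = n_prot / n if n else 0.0
        per_set[s.metric] = {
            "n_cells": n,
            "n_protected": n_prot,
            "coverage": cov,
        }
        if cov < 1.0:
            gaps.append(s.metric)
    overall = len(union & protected) / len(union) if union else 0.0
    return ProtectionReport(
        per_set=per_set,
        overall_coverage=overall,
        rule_threshold=float(threshold),
        gaps=gaps,
    )
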