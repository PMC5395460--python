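"""Species-level (ED, GE, EDGE) and grid-cell (SR, PD, WE, CWE, PE, mean EDGE) metrics.

Species scores follow the EDGE framework: fair-proportion evolutionary
distinctiveness (each branch length split equally among its descendant tips),
an integer global-endangerment code for the IUCN category, and
``EDGE = ln(1 + ED) + GE * ln(2)``.  Data-deficient (DD) species are excluded
before scoring.

Grid metrics operate on a binary species-by-cell presence matrix.  Because a
subset's phylogenetic diversity retains the path to the root, three exact
conservation laws hold and are used as oracles throughout the test suite:

* sum of ED over species  = PD of all tips,
* sum of WE over cells    = number of species,
* sum of PE over cells    = PD of the species with nonempty ranges.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .tree import Phylogeny, TreeError

__all__ = [
    "MetricsError",
    "CATEGORIES",
    "THREATENED_CATEGORIES",
    "GE_CODES",
    "ge_code",
    "is_threatened",
    "validate_threat_table",
    "OccurrenceMatrix",
    "faith_pd",
    "pd_of_tip_masks",
    "fair_proportion_ed",
    "edge_scores",
    "percent_pd_lost",
    "grid_sr",
    "grid_pd",
    "weighted_endemism",
    "phylogenetic_endemism",
    "grid_mean_edge",
]


class MetricsError(ValueError):
    """Invalid metric input."""


#: IUCN red-list vocabulary used throughout (CD = Conservation Dependent).
CATEGORIES = ("LC", "NT", "CD", "VU", "EN", "CR", "DD")

#: Categories counted as threatened in loss scenarios and the signal test.
THREATENED_CATEGORIES = frozenset({"VU", "EN", "CR"})

#: Global endangerment coding: LC=0, NT and CD=1, VU=2, EN=3, CR=4.
GE_CODES = {"LC": 0, "NT": 1, "CD": 1, "VU": 2, "EN": 3, "CR": 4}

LN2 = math.log(2.0)


def ge_code(category: str) -> int:
    """Integer GE code of an IUCN category; DD is rejected."""
    if category == "DD":
        raise MetricsError("data-deficient (DD) species are excluded before EDGE evaluation")
    try:
        return GE_CODES[category]
    except KeyError:
        raise MetricsError(f"unknown IUCN category {category!r}") from None


def is_threatened(category: str) -> bool:
    """Threatened means VU, EN or CR; DD counts as nonthreatened."""
    if category not in CATEGORIES:
        raise MetricsError(f"unknown IUCN category {category!r}")
    return category in THREATENED_CATEGORIES


def validate_threat_table(threats: pd.DataFrame) -> pd.DataFrame:
    """Check a species/category table: one row per species, known categories."""
    if not {"species", "category"}.issubset(threats.columns):
        raise MetricsError("threat table needs 'species' and 'category' columns")
    tab = threats[["species", "category"]].copy()
    dup = tab["species"][tab["species"].duplicated()]
    if len(dup):
        raise MetricsError("duplicate species in threat table: " + ", ".join(sorted(set(dup))))
    bad = sorted(set(tab["category"]) - set(CATEGORIES))
    if bad:
        raise MetricsError("unknown categories in threat table: " + ", ".join(bad))
    return tab


# ---------------------------------------------------------------------- #
# occurrence container


class OccurrenceMatrix:
    """Binary species-by-grid-cell presences on an abstract equal-area lattice.

    Cells are integer ids; on a ``width x height`` lattice cell ``id`` sits at
    ``(id % width, id // width)``, each cell nominally 100 x 100 km.  Only
    occupied cells are stored.  Every species must occupy at least one cell.
    """

    def __init__(self, presence: pd.DataFrame, grid_width: int | None = None,
                 grid_height: int | None = None):
        presence = presence.astype(bool)
        presence = presence.loc[sorted(presence.index), sorted(presence.columns)]
        presence = presence.loc[:, presence.any(axis=0)]
        empty = [s for s, any_ in presence.any(axis=1).items() if not any_]
        if empty:
            raise MetricsError(
                "species with no occurrences: " + ", ".join(map(str, empty))
            )
        if presence.index.duplicated().any():
            raise MetricsError("duplicate species rows in occurrence matrix")
        self.presence = presence
        self.grid_width = grid_width
        self.grid_height = grid_height

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, int]], grid_width=None,
                     grid_height=None) -> "OccurrenceMatrix":
        """Build from (species, cell_id) pairs."""
        df = pd.DataFrame(records, columns=["species", "cell_id"])
        return cls.from_long(df, grid_width, grid_height)

    @classmethod
    def from_long(cls, df: pd.DataFrame, grid_width=None, grid_height=None):
        if not {"species", "cell_id"}.issubset(df.columns):
            raise MetricsError("occurrence table needs 'species' and 'cell_id' columns")
        wide = pd.crosstab(df["species"], df["cell_id"].astype(int)) > 0
        return cls(wide, grid_width, grid_height)

    def to_long(self) -> pd.DataFrame:
        rows = [
            (s, int(c))
            for s in self.presence.index
            for c in self.presence.columns[self.presence.loc[s].to_numpy()]
        ]
        return pd.DataFrame(rows, columns=["species", "cell_id"])

    @property
    def species(self) -> list[str]:
        return list(self.presence.index)

    @property
    def cells(self) -> np.ndarray:
        """Occupied cell ids, ascending."""
        return self.presence.columns.to_numpy(dtype=np.int64)

    @property
    def n_species(self) -> int:
        return self.presence.shape[0]

    @property
    def n_cells(self) -> int:
        return self.presence.shape[1]

    def range_sizes(self) -> pd.Series:
        """Number of occupied cells per species."""
        return self.presence.sum(axis=1)

    def __repr__(self):  # pragma: no cover
        return f"<OccurrenceMatrix {self.n_species} species x {self.n_cells} cells>"


# ---------------------------------------------------------------------- #
# species-level scores


def pd_of_tip_masks(tree: Phylogeny, tip_mask: np.ndarray) -> np.ndarray:
    """Faith PD for many tip subsets at once.

    ``tip_mask`` has one row per tip (in ``tree.tip_indices`` order) and one
    column per subset; returns a PD value per column.  A column with no tips
    gets PD 0.  The minimal spanning subtree always includes the root path.
    """
    tip_mask = np.asarray(tip_mask, dtype=bool)
    if tip_mask.ndim == 1:
        tip_mask = tip_mask[:, None]
    if tip_mask.shape[0] != tree.n_tips:
        raise MetricsError("tip mask rows must equal the number of tips")
    n = tree.n_nodes
    flags = np.zeros((n, tip_mask.shape[1]), dtype=bool)
    flags[tree._tip_indices] = tip_mask
    parents = tree._parents
    for i in tree._postorder:
        p = parents[i]
        if p >= 0:
            flags[p] |= flags[i]
    lengths = tree._lengths.copy()
    lengths[tree.root] = 0.0
    return lengths @ flags


def faith_pd(tree: Phylogeny, subset: Iterable[str]) -> float:
    """Faith's phylogenetic diversity of a tip subset (root path included)."""
    labels = set(subset)
    if not labels:
        raise MetricsError("PD of an empty species set is undefined")
    unknown = labels.difference(tree._tip_index_of)
    if unknown:
        raise TreeError("unknown tip label(s): " + ", ".join(sorted(unknown)))
    mask = np.array([lab in labels for lab in tree.tip_labels])
    return float(pd_of_tip_masks(tree, mask)[0])


def fair_proportion_ed(tree: Phylogeny) -> pd.Series:
    """Fair-proportion evolutionary distinctiveness per species (Myr).

    Each branch length is divided equally among its descendant tips and the
    shares are summed per tip, so the ED values sum to the total PD exactly.
    """
    if tree.n_tips < 1:
        raise MetricsError("tree has no tips")
    n = tree.n_nodes
    share = np.zeros(n)
    lengths = tree._lengths
    ndesc = tree._n_desc
    for i in tree._preorder:
        p = tree._parents[i]
        base = share[p] if p >= 0 else 0.0
        own = lengths[i] / ndesc[i] if i != tree.root else 0.0
        share[i] = base + own
    ed = pd.Series(
        share[tree._tip_indices], index=pd.Index(tree.tip_labels, name="species"),
        name="ED",
    )
    return ed


def edge_scores(ed: Mapping[str, float] | pd.Series, threats: pd.DataFrame) -> pd.DataFrame:
    """EDGE table: species, category, GE, ED, EDGE and rank, sorted by EDGE.

    DD species are excluded before scoring.  Ties in EDGE are broken by
    species label so the ranking is reproducible.
    """
    tab = validate_threat_table(threats)
    ed = pd.Series(ed, dtype=float)
    scored = tab[tab["category"] != "DD"].copy()
    missing = sorted(set(scored["species"]) - set(ed.index))
    if missing:
        raise MetricsError("missing ED value for species: " + ", ".join(missing))
    scored["GE"] = [ge_code(c) for c in scored["category"]]
    scored["ED"] = ed.reindex(scored["species"]).to_numpy()
    if (scored["ED"] < 0).any():
        raise MetricsError("ED values must be nonnegative")
    scored["EDGE"] = np.log1p(scored["ED"]) + scored["GE"] * LN2
    scored = scored.sort_values(
        ["EDGE", "species"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    scored["rank"] = np.arange(1, len(scored) + 1)
    return scored[["species", "category", "GE", "ED", "EDGE", "rank"]]


def percent_pd_lost(remaining_pd: float, total_pd: float) -> float:
    """Percent of total PD lost: 100 * (1 - remaining / total)."""
    if total_pd <= 0:
        raise MetricsError("total PD must be positive")
    return 100.0 * (1.0 - remaining_pd / total_pd)


# ---------------------------------------------------------------------- #
# grid-cell maps (values only for occupied cells)


def _occ_arrays(occ: OccurrenceMatrix):
    mat = occ.presence.to_numpy(dtype=bool)
    return mat, occ.presence.index, occ.presence.columns


def grid_sr(occ: OccurrenceMatrix) -> pd.Series:
    """Species richness per occupied cell."""
    mat, _, cells = _occ_arrays(occ)
    return pd.Series(mat.sum(axis=0), index=cells, name="SR")


def _tree_tip_mask(tree: Phylogeny, occ: OccurrenceMatrix) -> np.ndarray:
    missing = sorted(set(occ.species) - set(tree.tip_labels))
    if missing:
        raise MetricsError("occurrence species missing from tree: " + ", ".join(missing))
    order = {lab: i for i, lab in enumerate(tree.tip_labels)}
    mask = np.zeros((tree.n_tips, occ.n_cells), dtype=bool)
    mat = occ.presence.to_numpy(dtype=bool)
    for r, s in enumerate(occ.species):
        mask[order[s]] |= mat[r]
    return mask


def grid_pd(tree: Phylogeny, occ: OccurrenceMatrix) -> pd.Series:
    """Faith PD of the species present in each occupied cell."""
    mask = _tree_tip_mask(tree, occ)
    values = pd_of_tip_masks(tree, mask)
    return pd.Series(values, index=occ.presence.columns, name="PD")


def weighted_endemism(occ: OccurrenceMatrix) -> tuple[pd.Series, pd.Series]:
    """Weighted endemism and its richness-corrected form per occupied cell.

    WE(c) = sum over species present in c of 1/range; CWE(c) = WE(c)/SR(c).
    WE sums to the number of species over all cells.
    """
    mat, _, cells = _occ_arrays(occ)
    ranges = mat.sum(axis=1).astype(float)
    we = (1.0 / ranges) @ mat
    sr = mat.sum(axis=0)
    cwe = we / sr
    return (
        pd.Series(we, index=cells, name="WE"),
        pd.Series(cwe, index=cells, name="CWE"),
    )


def phylogenetic_endemism(tree: Phylogeny, occ: OccurrenceMatrix) -> pd.Series:
    """Range-weighted PD per cell.

    A branch's range is the union of the cells of its descendant tips; each
    branch contributes length/|range| to every cell of its range, so PE sums
    over cells to the PD of the species with nonempty ranges.
    """
    mask = _tree_tip_mask(tree, occ)  # tips x cells
    n = tree.n_nodes
    node_range = np.zeros((n, occ.n_cells), dtype=bool)
    node_range[tree._tip_indices] = mask
    parents = tree._parents
    for i in tree._postorder:
        p = parents[i]
        if p >= 0:
            node_range[p] |= node_range[i]
    sizes = node_range.sum(axis=1).astype(float)
    lengths = tree._lengths.copy()
    lengths[tree.root] = 0.0
    nonempty = sizes > 0
    weights = np.zeros(n)
    weights[nonempty] = lengths[nonempty] / sizes[nonempty]
    pe = weights @ node_range
    return pd.Series(pe, index=occ.presence.columns, name="PE")


def grid_mean_edge(edge_table: pd.DataFrame, occ: OccurrenceMatrix) -> pd.Series:
    """Arithmetic mean EDGE of the scored species present in each cell.

    Cells whose only occupants are unscored (DD) species are dropped from
    the map (they are unoccupied for this metric).
    """
    if not {"species", "EDGE"}.issubset(edge_table.columns):
        raise MetricsError("edge table needs 'species' and 'EDGE' columns")
    scores = edge_table.set_index("species")["EDGE"]
    scored = [s for s in occ.species if s in scores.index]
    if not scored:
        raise MetricsError("no scored species present in the occurrence matrix")
    sub = occ.presence.loc[scored].to_numpy(dtype=float)
    vals = scores.reindex(scored).to_numpy()
    counts = sub.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = (vals @ sub) / counts
    out = pd.Series(mean, index=occ.presence.columns, name="meanEDGE")
    return out[counts > 0]
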