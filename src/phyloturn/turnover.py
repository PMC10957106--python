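"""Pairwise taxonomic and phylogenetic dissimilarities between grid cells.

The workhorse statistic is Simpson's pairwise dissimilarity (beta-sim),
``min(b, c) / (a + min(b, c))``: the turnover component of Sorensen
dissimilarity, insensitive to richness differences.  In the taxonomic case
a/b/c are shared/unique species counts; in the phylogenetic case they are
shared/unique branch lengths (Faith's PD) on the tree spanning both cells'
species.  The root-path convention follows the standard pairwise PD
decomposition: only branches strictly below the MRCA of the two cells'
union contribute, so the statistic depends on the spanning subtree alone
and reduces exactly to the taxonomic index on a star tree.

Ancient turnover repeats the computation after collapsing the tree at a
past time slice and mapping each cell's species to the lineages alive then.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import OccurrenceGrid
from .trees import TimeTree, slice_tree_at

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "PairComponents",
    "simpson_turnover",
    "sorensen_dissimilarity",
    "taxonomic_components",
    "phylo_components",
    "PhyloBranchClassifier",
    "pbd_dev_reverse",
    "haversine_km",
    "pairwise_table",
    "table_to_matrix",
]


@dataclass(frozen=True)
class PairComponents:
    """Shared (a) and unique (b, c) quantities for one cell pair."""

    a: float
    b: float
    c: float

    def __post_init__(self):
        if self.a < 0 or self.b < 0 or self.c < 0:
            raise ValueError("components must be non-negative")


def simpson_turnover(components: PairComponents) -> float:
    """beta-sim = min(b, c) / (a + min(b, c)); NaN if undefined."""
    m = min(components.b, components.c)
    denom = components.a + m
    if denom == 0:
        return float("nan")
    return m / denom


def sorensen_dissimilarity(components: PairComponents) -> float:
    """Sorensen dissimilarity (b + c) / (2a + b + c); NaN if undefined."""
    denom = 2 * components.a + components.b + components.c
    if denom == 0:
        return float("nan")
    return (components.b + components.c) / denom


def taxonomic_components(set_i, set_j) -> PairComponents:
    si, sj = frozenset(set_i), frozenset(set_j)
    shared = len(si & sj)
    return PairComponents(a=shared, b=len(si) - shared, c=len(sj) - shared)


class PhyloBranchClassifier:
    """Precomputed bitset machinery for fast per-branch classification.

    For each branch (identified with its child node) the descendant tip set
    is stored as a Python integer bitmask; for a pair of tip sets the shared
    and unique branch lengths are accumulated over branches strictly below
    the MRCA of the union.
    """

    def __init__(self, tree: TimeTree):
        self.tree = tree
        tips = tree.tip_labels()
        self.tip_pos = {t: i for i, t in enumerate(tips)}
        self.masks: list[int] = []
        self.lengths: list[float] = []
        self.names: list[str] = []
        mask_of: dict[str, int] = {}
        for n in tree.postorder():
            if n.is_leaf:
                mask_of[n.name] = 1 << self.tip_pos[n.name]
            else:
                m = 0
                for c in n.children:
                    m |= mask_of[c.name]
                mask_of[n.name] = m
            if n.parent is not None:
                self.masks.append(mask_of[n.name])
                self.lengths.append(n.length)
                self.names.append(n.name)
        self._mask_of = mask_of

    def tipset_mask(self, labels) -> int:
        m = 0
        for t in labels:
            m |= 1 << self.tip_pos[t]
        return m

    def components(self, set_i, set_j) -> PairComponents:
        mi = self.tipset_mask(set_i)
        mj = self.tipset_mask(set_j)
        union = mi | mj
        if union == 0:
            return PairComponents(0.0, 0.0, 0.0)
        if union.bit_count() == 1:
            # both cells hold the same single species: the spanning subtree
            # degenerates to that terminal branch, fully shared
            k = self.masks.index(union)
            return PairComponents(self.lengths[k], 0.0, 0.0)
        # MRCA of the union: smallest-popcount superset mask among nodes
        mrca_mask = None
        for n in self.tree.postorder():
            m = self._mask_of[n.name]
            if union & ~m == 0:
                mrca_mask = m
                break
        a = b = c = 0.0
        for mask, length in zip(self.masks, self.lengths):
            if mask & ~mrca_mask == 0 and mask != mrca_mask:
                hit_i = bool(mask & mi)
                hit_j = bool(mask & mj)
                if hit_i and hit_j:
                    a += length
                elif hit_i:
                    b += length
                elif hit_j:
                    c += length
        return PairComponents(a=a, b=b, c=c)


def phylo_components(tree: TimeTree, set_i, set_j) -> PairComponents:
    """Shared/unique branch-length components for two cells' species sets."""
    return PhyloBranchClassifier(tree).components(set_i, set_j)


def pbd_dev_reverse(taxonomic_bd: float, phylo_bd: float) -> float:
    """-(TBD - PBD) / TBD; NaN when taxonomic turnover is zero.

    Increases with phylogenetic beta diversity at fixed taxonomic beta
    diversity, i.e., with lineage-level turnover beyond species turnover.
    """
    if not np.isfinite(taxonomic_bd) or taxonomic_bd <= 0 or not np.isfinite(phylo_bd):
        return float("nan")
    return -(taxonomic_bd - phylo_bd) / taxonomic_bd


def haversine_km(lon1, lat1, lon2, lat2) -> float:
    """Great-circle distance on a 6371-km sphere."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h)))


def pairwise_table(
    grid: OccurrenceGrid,
    tree: TimeTree | None = None,
    mode: str = "full",
    cutoff_ma: float = 0.0,
    predictors: list[str] | None = None,
) -> pd.DataFrame:
    """All unordered cell pairs with dissimilarities and predictor values.

    ``mode`` is ``"full"`` (tip-level phylogenetic turnover), ``"ancient"``
    (tree sliced at ``cutoff_ma``; cell incidences mapped to the lineages
    alive then), or ``"taxonomic"`` (no tree needed).  Predictor columns are
    emitted twice per pair with ``_i``/``_j`` suffixes; geographic distance
    is always included.  Cells left without lineages after slicing are
    dropped with a logged count.
    """
    if mode not in {"full", "ancient", "taxonomic"}:
        raise ValueError(f"unknown mode {mode!r}")
    species_sets = grid.species_sets()
    cells = list(grid.cells)

    classifier = None
    unit_sets = species_sets
    if mode in {"full", "ancient"}:
        if tree is None:
            raise ValueError("phylogenetic modes require a tree")
        work_tree = tree
        if mode == "ancient" and cutoff_ma > 0:
            work_tree, mapping = slice_tree_at(tree, cutoff_ma)
            tip_to_lineage = {}
            for lineage, members in mapping.items():
                for t in members:
                    tip_to_lineage[t] = lineage
            unit_sets = {
                cell: frozenset(
                    tip_to_lineage[s] for s in sp if s in tip_to_lineage
                )
                for cell, sp in species_sets.items()
            }
            empty = [c for c in cells if not unit_sets[c]]
            if empty:
                logger.warning("dropping %d cells with no lineages at %.1f Ma", len(empty), cutoff_ma)
                cells = [c for c in cells if unit_sets[c]]
        tree_tips = set(work_tree.tip_labels())
        unit_sets = {c: frozenset(s & tree_tips) for c, s in unit_sets.items()}
        classifier = PhyloBranchClassifier(work_tree)

    clim = grid.cell_climate
    if predictors is None:
        predictors = [] if clim is None else list(clim.columns)

    rows = []
    centers = grid.cell_centers
    for ci, cj in itertools.combinations(cells, 2):
        tax = taxonomic_components(species_sets[ci], species_sets[cj])
        row = {
            "cell_i": ci,
            "cell_j": cj,
            "taxonomic_sim": simpson_turnover(tax),
            "taxonomic_sorensen": sorensen_dissimilarity(tax),
        }
        if classifier is not None:
            phy = classifier.components(unit_sets[ci], unit_sets[cj])
            row["phylo_sim"] = simpson_turnover(phy)
            row["phylo_sorensen"] = sorensen_dissimilarity(phy)
            row["pbd_dev_reverse"] = pbd_dev_reverse(
                row["taxonomic_sim"], row["phylo_sim"]
            )
        row["geographic_distance_km"] = haversine_km(
            centers.loc[ci, "lon"], centers.loc[ci, "lat"],
            centers.loc[cj, "lon"], centers.loc[cj, "lat"],
        )
        for p in predictors:
            row[f"{p}_i"] = clim.loc[ci, p]
            row[f"{p}_j"] = clim.loc[cj, p]
        if grid.cell_biome is not None:
            bi, bj = grid.cell_biome.get(ci), grid.cell_biome.get(cj)
            if bi is not None and bj is not None and bi == bi and bj == bj:
                from .grids import biome_distance

                row["biome_distance"] = biome_distance(bi, bj)
            else:
                row["biome_distance"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def table_to_matrix(
    table: pd.DataFrame, column: str, cells: list[int] | None = None
) -> tuple[np.ndarray, list[int]]:
    """Square symmetric dissimilarity matrix from a pairwise table."""
    if cells is None:
        cells = sorted(set(table["cell_i"]) | set(table["cell_j"]))
    pos = {c: i for i, c in enumerate(cells)}
    n = len(cells)
    mat = np.zeros((n, n))
    for _, r in table.iterrows():
        i, j = pos.get(r["cell_i"]), pos.get(r["cell_j"])
        if i is None or j is None:
            continue
        mat[i, j] = mat[j, i] = r[column]
    return mat, cells
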