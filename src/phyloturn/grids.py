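"""From occurrence records and climate layers to the analysis grid.

Occurrences are binned onto a half-degree lon/lat lattice anchored at
(-180, -90); cells are half-open with the west and south edges inclusive, so
every finite coordinate lands in exactly one cell.  Cells are then filtered
by species richness and by the tropical latitude band (default +/-33
degrees, with an optional exempt region such as Australia that bypasses the
latitude rule only), climate layers are summarized per cell, and dry-season
length and biome distances are derived.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .rasters import AsciiGrid

logger = logging.getLogger(__name__)

__all__ = [
    "OccurrenceGrid",
    "cell_index",
    "cell_center",
    "grid_occurrences",
    "attach_climate",
    "apply_filters",
    "dry_season_length",
    "species_climate_summary",
    "biome_distance",
    "attach_biomes",
]

MONTH_LAYERS = [f"precip_{m:02d}" for m in range(1, 13)]


def _global_ncols(resolution: float) -> int:
    return int(round(360.0 / resolution))


def cell_index(row: int, col: int, resolution: float = 0.5) -> int:
    """Integer id of the (row, col) cell on the global lattice."""
    return int(row) * _global_ncols(resolution) + int(col)


def cell_rowcol(cell: int, resolution: float = 0.5) -> tuple[int, int]:
    ncols = _global_ncols(resolution)
    return cell // ncols, cell % ncols


def cell_center(cell: int, resolution: float = 0.5) -> tuple[float, float]:
    """(lon, lat) of a cell's center."""
    row, col = cell_rowcol(cell, resolution)
    return (
        -180.0 + (col + 0.5) * resolution,
        -90.0 + (row + 0.5) * resolution,
    )


def coords_to_cell(lon, lat, resolution: float = 0.5):
    """Vectorized point -> cell id by floor division (west/south inclusive)."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    col = np.floor((lon + 180.0) / resolution).astype(int)
    row = np.floor((lat + 90.0) / resolution).astype(int)
    return row * _global_ncols(resolution) + col


@dataclass(frozen=True)
class OccurrenceGrid:
    """Species-by-cell incidence with per-cell metadata.

    ``incidence`` is a boolean DataFrame (species rows, cell-id columns);
    ``cell_centers`` holds lon/lat of each retained cell; ``cell_climate``
    (optional) one named predictor per column; ``cell_biome`` (optional) a
    categorical label per cell.
    """

    incidence: pd.DataFrame
    cell_centers: pd.DataFrame
    resolution: float = 0.5
    cell_climate: pd.DataFrame | None = None
    cell_biome: pd.Series | None = None

    @property
    def cells(self) -> list[int]:
        return list(self.incidence.columns)

    @property
    def species(self) -> list[str]:
        return list(self.incidence.index)

    def richness(self) -> pd.Series:
        return self.incidence.sum(axis=0)

    def species_sets(self) -> dict[int, frozenset[str]]:
        """Cell -> set of species present."""
        out = {}
        for cell in self.incidence.columns:
            mask = self.incidence[cell].to_numpy()
            out[cell] = frozenset(np.asarray(self.incidence.index)[mask])
        return out

    def subset_cells(self, cells) -> "OccurrenceGrid":
        cells = [c for c in self.incidence.columns if c in set(cells)]
        return replace(
            self,
            incidence=self.incidence[cells],
            cell_centers=self.cell_centers.loc[cells],
            cell_climate=None if self.cell_climate is None else self.cell_climate.loc[cells],
            cell_biome=None if self.cell_biome is None else self.cell_biome.loc[cells],
        )


def grid_occurrences(records: pd.DataFrame, resolution: float = 0.5) -> OccurrenceGrid:
    """Bin occurrence records (taxon, lon, lat) onto the lattice.

    Non-finite or out-of-range coordinates are rejected per record with a
    logged count; duplicate records collapse to presence.
    """
    req = {"taxon", "lon", "lat"}
    if not req <= set(records.columns):
        raise ValueError(f"records must have columns {sorted(req)}")
    lon = records["lon"].to_numpy(dtype=float)
    lat = records["lat"].to_numpy(dtype=float)
    ok = (
        np.isfinite(lon) & np.isfinite(lat)
        & (lon >= -180.0) & (lon < 180.0)
        & (lat >= -90.0) & (lat < 90.0)
    )
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("rejected %d occurrence records with invalid coordinates", n_bad)
    good = records.loc[ok]
    cells = coords_to_cell(good["lon"].to_numpy(), good["lat"].to_numpy(), resolution)

    pairs = pd.DataFrame({"taxon": good["taxon"].to_numpy(), "cell": cells})
    incidence = (
        pd.crosstab(pairs["taxon"], pairs["cell"]).astype(bool)
    )
    incidence = incidence.sort_index(axis=0).sort_index(axis=1)
    centers = pd.DataFrame(
        [cell_center(c, resolution) for c in incidence.columns],
        index=incidence.columns,
        columns=["lon", "lat"],
    )
    return OccurrenceGrid(incidence=incidence, cell_centers=centers, resolution=resolution)


def _in_region(lon: float, lat: float, region) -> bool:
    if region is None:
        return False
    if isinstance(region, (tuple, list)) and len(region) == 4:
        x0, y0, x1, y1 = region
        return x0 <= lon <= x1 and y0 <= lat <= y1
    # duck-typed shapely geometry
    from shapely.geometry import Point  # local import; optional dependency

    return bool(region.covers(Point(lon, lat)))


def apply_filters(
    grid: OccurrenceGrid,
    min_taxa: int = 3,
    lat_limit: float = 33.0,
    exempt_region=None,
) -> OccurrenceGrid:
    """Drop cells failing the richness or latitude filters.

    The latitude rule applies to the cell center; cells inside
    ``exempt_region`` (a (x0, y0, x1, y1) box or shapely geometry) bypass
    the latitude filter only, never the richness filter.  The two filters
    commute.
    """
    if min_taxa < 1:
        raise ValueError("min_taxa must be at least 1")
    rich = grid.richness()
    keep = []
    for cell in grid.cells:
        lon, lat = grid.cell_centers.loc[cell, ["lon", "lat"]]
        lat_ok = abs(lat) <= lat_limit or _in_region(lon, lat, exempt_region)
        if lat_ok and rich[cell] >= min_taxa:
            keep.append(cell)
    return grid.subset_cells(keep)


def dry_season_length(monthly_precip) -> int:
    """Longest circular run of months with < 100 mm precipitation.

    Evaluated circularly across the December -> January boundary, so a dry
    season spanning the calendar year-end is counted as one run.
    """
    p = np.asarray(monthly_precip, dtype=float)
    if p.shape != (12,):
        raise ValueError("monthly precipitation must have exactly 12 values")
    if (p < 0).any():
        raise ValueError("monthly precipitation must be non-negative")
    dry = p < 100.0
    if dry.all():
        return 12
    best = run = 0
    for flag in np.concatenate([dry, dry]):
        run = run + 1 if flag else 0
        best = max(best, run)
    return int(min(best, 12))


def _aggregate_to_cell(layer: AsciiGrid, cell: int, resolution: float) -> float:
    """Mean of the layer's native cells whose centers fall inside the cell."""
    lon, lat = cell_center(cell, resolution)
    half = resolution / 2.0
    cs = layer.cellsize
    lons = np.arange(lon - half + cs / 2.0, lon + half, cs)
    lats = np.arange(lat - half + cs / 2.0, lat + half, cs)
    gl, gt = np.meshgrid(lons, lats)
    vals = layer.value_at(gl.ravel(), gt.ravel())
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if vals.size else float("nan")


def attach_climate(
    grid: OccurrenceGrid,
    layers: dict[str, AsciiGrid],
    derive_dsl: bool = True,
) -> OccurrenceGrid:
    """Summarize climate layers per retained cell (mean within the cell).

    If all twelve monthly precipitation layers are present, the dry-season
    length predictor ``DSL`` is derived per cell.
    """
    named = {k: v for k, v in layers.items() if k not in MONTH_LAYERS}
    table = {}
    for name, layer in named.items():
        table[name] = [_aggregate_to_cell(layer, c, grid.resolution) for c in grid.cells]
    if derive_dsl and all(m in layers for m in MONTH_LAYERS):
        monthly = np.array(
            [
                [_aggregate_to_cell(layers[m], c, grid.resolution) for m in MONTH_LAYERS]
                for c in grid.cells
            ]
        )
        table["DSL"] = [
            dry_season_length(row) if np.isfinite(row).all() else np.nan
            for row in monthly
        ]
    climate = pd.DataFrame(table, index=pd.Index(grid.cells))
    return replace(grid, cell_climate=climate)


def species_climate_summary(
    records: pd.DataFrame,
    layers: dict[str, AsciiGrid],
    resolution: float = 0.5,
    derive_dsl: bool = True,
) -> pd.DataFrame:
    """Per-species median of each predictor over its occupied cells.

    Records falling outside a layer's coverage are skipped for that
    predictor, with a logged count.  Returns a DataFrame indexed by taxon.
    """
    grid = grid_occurrences(records, resolution)
    grid = attach_climate(grid, layers, derive_dsl=derive_dsl)
    clim = grid.cell_climate
    out = {}
    n_skipped = 0
    for sp in grid.species:
        mask = grid.incidence.loc[sp].to_numpy()
        cells = np.asarray(grid.incidence.columns)[mask]
        vals = clim.loc[cells]
        n_skipped += int(vals.isna().any(axis=1).sum())
        out[sp] = vals.median(axis=0, skipna=True)
    if n_skipped:
        logger.warning("skipped %d cell values lacking climate coverage", n_skipped)
    summary = pd.DataFrame(out).T
    summary.index.name = "taxon"
    return summary


# --------------------------------------------------------------------- #
# biomes
# --------------------------------------------------------------------- #
@dataclass(frozen=True)
class BiomeScheme:
    """Categorical biome scheme with an optional intermediate overlap class.

    Pairs of cells in the same biome are at distance 0, in different biomes
    at distance 1; pairs of the overlap class with either of its member
    biomes are at distance 0.5.
    """

    overlap_label: str | None = "savanna_succulent_overlap"
    overlap_members: frozenset = frozenset({"savanna", "succulent"})


def biome_distance(biome_i: str, biome_j: str, scheme: BiomeScheme | None = None) -> float:
    if scheme is None:
        scheme = BiomeScheme()
    if biome_i is None or biome_j is None or biome_i != biome_i or biome_j != biome_j:
        raise ValueError("both cells must carry a biome label")
    if biome_i == biome_j:
        return 0.0
    if scheme.overlap_label is not None:
        pair = {biome_i, biome_j}
        if scheme.overlap_label in pair and pair & set(scheme.overlap_members):
            return 0.5
    return 1.0


def attach_biomes(grid: OccurrenceGrid, biome_raster: AsciiGrid, labels: dict[int, str]) -> OccurrenceGrid:
    """Label each retained cell from a categorical raster; unlabeled -> NaN."""
    vals = [
        biome_raster.value_at(*grid.cell_centers.loc[c, ["lon", "lat"]])
        for c in grid.cells
    ]
    series = pd.Series(
        [labels.get(int(v)) if np.isfinite(v) else None for v in vals],
        index=pd.Index(grid.cells),
        dtype=object,
    )
    return replace(grid, cell_biome=series)
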