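#!/usr/bin/env python
"""Stage 2 -- grid the occurrence records.

Bins occurrences onto the half-degree lattice, applies the richness and
tropical-latitude filters, attaches per-cell climate (MAP and dry-season
length derived from the monthly layers), and writes the retained cells.
"""

import argparse
from pathlib import Path

import pandas as pd

from phyloturn import grids
from phyloturn.rasters import AsciiGrid

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--sim", type=Path, default=Path("results/sim"))
parser.add_argument("--out", type=Path, default=Path("results/grid"))
parser.add_argument("--min-taxa", type=int, default=3)
parser.add_argument("--lat-limit", type=float, default=33.0)
args = parser.parse_args()

occ = pd.read_csv(args.sim / "occurrences.csv")
layers = {p.stem: AsciiGrid.read(p) for p in sorted(args.sim.glob("*.asc"))}

grid = grids.grid_occurrences(occ)
grid = grids.apply_filters(grid, min_taxa=args.min_taxa, lat_limit=args.lat_limit)
grid = grids.attach_climate(grid, layers)

args.out.mkdir(parents=True, exist_ok=True)
grid.incidence.to_csv(args.out / "incidence.csv")
grid.cell_centers.join(grid.cell_climate).to_csv(args.out / "cells.csv")

rich = grid.richness()
print(f"{len(grid.cells)} cells retained (min {args.min_taxa} taxa, "
      f"|lat| <= {args.lat_limit}); richness {rich.min()}-{rich.max()}, "
      f"median {rich.median():.0f} -> {args.out}")
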