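"""Seeded end-to-end run over a synthetic world.

One call chains every stage -- simulate, grid, turnover, GDM with variation
partitioning, phyloregionalization, niche-shift detection and biogeographic
reconstruction -- on a world small enough to finish in minutes on one CPU,
and writes plain-text outputs (Newick, CSV, JSON) to a directory.  Running
it twice with the same seed produces byte-identical files, which the test
suite checks.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import biogeo, gdm, grids, niche, regions, simulate, turnover
from .simulate import SimulationConfig

__all__ = ["run_pipeline"]


def run_pipeline(
    seed: int,
    outdir: str | Path | None = None,
    n_tips: int = 60,
    n_occurrences: int = 40,
    n_maps: int = 50,
) -> dict:
    """Run the full pipeline on a synthetic world; returns summary numbers.

    The synthetic world keeps the stated defaults (birth 0.3 / death 0.1
    per lineage per Ma, Brownian MAP niche with lambda = 1, a linear MAP
    gradient landscape) but a desk-scale tip count so the whole chain runs
    in well under 15 minutes.
    """
    config = SimulationConfig(
        n_tips=n_tips,
        n_occurrences_per_species=n_occurrences,
        occurrence_noise_deg=1.0,
        seed=seed,
    )

    # --- simulate ----------------------------------------------------- #
    tree = simulate.simulate_tree(config)
    root_map = 0.5 * (config.map_min + config.map_max)
    values = simulate.simulate_bm_trait(
        tree, config.trait_sigma2, config.lambda_true, root_state=root_map,
        rng=config.rng(simulate._TRAIT_STREAM),
    )
    tip_traits = {t: float(np.clip(values[t], config.map_min, config.map_max))
                  for t in tree.tip_labels()}
    layers, occ, gt = simulate.simulate_landscape_and_occurrences(
        tree, tip_traits, config
    )

    # --- grid --------------------------------------------------------- #
    grid = grids.grid_occurrences(occ, config.resolution)
    grid = grids.apply_filters(grid, min_taxa=3, lat_limit=33.0)
    grid = grids.attach_climate(grid, layers)

    # --- turnover ----------------------------------------------------- #
    table = turnover.pairwise_table(grid, tree, mode="full", predictors=["MAP"])

    # --- GDM + partition ---------------------------------------------- #
    partition = gdm.variation_partition(
        table.dropna(subset=["phylo_sim"]),
        response="phylo_sim",
        set_a=["MAP"],
        set_b=["geographic_distance_km"],
    )
    resid_table = gdm.geographic_residuals(table, "phylo_sim")

    # --- phyloregionalization ----------------------------------------- #
    mat, cells = turnover.table_to_matrix(table, "phylo_sim")
    fits = regions.select_algorithm(mat, cells)
    ward = fits["ward"]
    k2 = ward.labels_for(2)
    climate_test = regions.cluster_climate_tests(
        k2, grid.cell_climate.loc[cells, "MAP"].to_numpy(), variable="MAP"
    )

    # --- niche reconstruction ----------------------------------------- #
    asr = niche.ancestral_states_bm(tree, tip_traits)
    node_states = {k: v[0] for k, v in asr.items()}
    shifts = niche.detect_niche_shifts(tree, node_states, niche.MAP_CATEGORIES)
    lam_hat, lam_logl, lam_p = niche.pagels_lambda(tree, tip_traits)
    bins = niche.shifts_per_time_bin(shifts, tree, bin_width=5.0)

    # --- biogeography -------------------------------------------------- #
    areas = ["Africa", "Madagascar", "Asia"]
    q_geo = np.array([
        [-0.06, 0.03, 0.03],
        [0.03, -0.06, 0.03],
        [0.03, 0.03, -0.06],
    ])
    tips_area, _ = simulate.simulate_mk_history(
        tree, q_geo, root_state=0, rng=config.rng(simulate._MK_STREAM)
    )
    tip_ranges = {t: frozenset([areas[s]]) for t, s in tips_area.items()}
    dec = biogeo.fit_dec(tree, tip_ranges, with_j=False, areas=areas)
    decj = biogeo.fit_dec(tree, tip_ranges, with_j=True, areas=areas)
    marg = [biogeo.dec_node_marginals(m, tree, tip_ranges) for m in (dec, decj)]
    avg, weights = biogeo.aic_average([dec, decj], marg)
    grouping = {a: a for a in areas}  # three singleton groups
    recon, events = biogeo.decide_ranges_and_count_dispersals(
        avg, dec.space, tree, grouping, tip_ranges
    )

    # Mk + stochastic maps on a binary (wet/dry affinity) coding
    tip_band = {t: "wet" if tip_traits[t] >= root_map else "dry"
                for t in tree.tip_labels()}
    if len(set(tip_band.values())) > 1:
        mk = biogeo.fit_mk_ard(tree, tip_band)
        maps = biogeo.stochastic_maps(mk, tree, tip_band, n=n_maps, seed=seed + 7)
        transitions = biogeo.count_transitions(maps, tree)
        n_transitions = len(transitions)
    else:
        n_transitions = 0

    summary = {
        "seed": seed,
        "n_tips": tree.n_tips,
        "root_age_ma": round(tree.root_age, 6),
        "n_cells": len(grid.cells),
        "n_pairs": len(table),
        "mean_phylo_sim": round(float(np.nanmean(table["phylo_sim"])), 6),
        "partition": {k: round(v, 6) for k, v in partition.as_dict().items()},
        "cophenetic_r": {m: round(f.cophenetic_r, 6) for m, f in fits.items()},
        "climate_test_p": float(climate_test.p_value),
        "lambda_hat": round(lam_hat, 6),
        "lambda_p": float(lam_p),
        "n_niche_shifts": len(shifts),
        "dec": {"d": round(dec.d, 6), "e": round(dec.e, 6), "aic": round(dec.aic, 4)},
        "decj": {"d": round(decj.d, 6), "e": round(decj.e, 6),
                 "j": round(decj.j, 6), "aic": round(decj.aic, 4)},
        "aic_weights": [round(float(w), 6) for w in weights],
        "n_dispersal_events": len(events),
        "n_mk_transitions": n_transitions,
    }

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        tree.write(out / "tree.nwk")
        occ.to_csv(out / "occurrences.csv", index=False)
        layers["MAP"].write(out / "map.asc")
        table.to_csv(out / "pairwise_table.csv", index=False)
        ward.as_frame().to_csv(out / "phyloregions.csv")
        pd.DataFrame([{
            "branch": s.branch, "parent_age": s.parent_age,
            "child_age": s.child_age, "shift_age": s.age,
            "delta": s.delta, "parent_category": s.parent_category,
            "child_category": s.child_category,
        } for s in shifts]).to_csv(out / "niche_shifts.csv", index=False)
        bins.to_csv(out / "shift_bins.csv", index=False)
        recon.as_frame(tree).to_csv(out / "range_reconstruction.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
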