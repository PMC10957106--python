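"""Synthetic-data generators: trees, traits, Mk histories, landscapes."""

import random

import dendropy
import numpy as np
import pytest
from dendropy.model import birthdeath

from phyloturn import grids
from phyloturn.simulate import (
    GroundTruth,
    SimulationConfig,
    impose_niche_shifts,
    monthly_profile,
    simulate_bm_trait,
    simulate_landscape_and_occurrences,
    simulate_mk_history,
    simulate_tree,
    true_dry_season_length,
)
from phyloturn.trees import TimeTree


def gamma_statistic(internal_ages: np.ndarray, n_tips: int) -> float:
    """Pybus & Harvey's gamma from internal node ages (tips at 0)."""
    a = np.sort(np.asarray(internal_ages))[::-1]
    assert len(a) == n_tips - 1
    # g_k: interval with k lineages, k = 2..n
    bounds = np.concatenate([a, [0.0]])
    g = bounds[:-1] - bounds[1:]
    ks = np.arange(2, n_tips + 1)
    T = float(np.sum(ks * g))
    cum = np.cumsum(ks * g)
    inner = cum[:-1].mean()  # (1/(n-2)) sum_{i=2}^{n-1} T_i
    return (inner - T / 2.0) / (T * np.sqrt(1.0 / (12.0 * (n_tips - 2))))


class TestConfig:
    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(birth_rate=0.1, death_rate=0.2)
        with pytest.raises(ValueError):
            SimulationConfig(lambda_true=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(mk_rates=np.array([[0.0, 0.1], [0.1, 0.0]]))


class TestSimulateTree:
    def test_smallest_tree(self):
        t = simulate_tree(SimulationConfig(n_tips=2, seed=0))
        assert t.n_tips == 2
        assert len(t.internal_nodes()) == 1
        a, b = t.tips()
        assert a.length == pytest.approx(b.length)

    def test_determinism_byte_identical(self):
        n1 = simulate_tree(SimulationConfig(n_tips=100, seed=1)).to_newick()
        n2 = simulate_tree(SimulationConfig(n_tips=100, seed=1)).to_newick()
        assert n1 == n2

    def test_ultrametric_binary(self):
        t = simulate_tree(SimulationConfig(n_tips=50, seed=7))
        assert t.is_ultrametric(1e-9)
        assert all(len(n.children) == 2 for n in t.internal_nodes())

    def test_gamma_against_independent_simulator(self):
        """Mean gamma statistic agrees with an independent birth-death
        simulator (dendropy) at b=0.3, d=0.1, n=200, over 500 replicates."""
        n, reps = 200, 500
        ours = []
        for i in range(reps):
            t = simulate_tree(SimulationConfig(
                n_tips=n, birth_rate=0.3, death_rate=0.1, seed=10_000 + i))
            ages = t.ages()
            ours.append(gamma_statistic(
                np.array([ages[nd.name] for nd in t.internal_nodes()]), n))
        theirs = []
        for i in range(reps):
            dt = birthdeath.birth_death_tree(
                birth_rate=0.3, death_rate=0.1, num_extant_tips=n,
                rng=random.Random(i),
            )
            dt.calc_node_ages(ultrametricity_precision=False)
            ages = [nd.age for nd in dt if not nd.is_leaf()]
            theirs.append(gamma_statistic(np.array(ages), n))
        diff = abs(np.mean(ours) - np.mean(theirs))
        se = np.sqrt(np.var(ours) / reps + np.var(theirs) / reps)
        assert diff < max(4 * se, 0.25)


class TestBMTrait:
    def test_lambda_zero_iid(self, balanced_tree):
        """lambda=0: tips are i.i.d. Normal(root_state, sigma2*depth)."""
        rng = np.random.default_rng(5)
        reps = 2000
        sims = [simulate_bm_trait(balanced_tree, 1.0, 0.0, 3.0, rng)
                for _ in range(reps)]
        draws = np.array([[s[t] for t in balanced_tree.tip_labels()] for s in sims])
        cov = np.cov(draws.T)
        depth = 40.0
        assert np.allclose(np.diag(cov), depth, rtol=0.15)
        off = cov[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.1 * depth
        assert draws.mean() == pytest.approx(3.0, abs=0.5)

    def test_lambda_one_covariance_matches_hand_computed_C(self, balanced_tree):
        """Sample covariance at lambda=1 matches sigma2*C from branch lengths."""
        rng = np.random.default_rng(6)
        reps = 2000
        sims = [simulate_bm_trait(balanced_tree, 2.0, 1.0, 0.0, rng)
                for _ in range(reps)]
        draws = np.array([[s[t] for t in ("A", "B", "C", "D")] for s in sims])
        cov = np.cov(draws.T)
        # hand-computed C for ((A:10,B:10):30,(C:10,D:10):30): depth 40,
        # shared path 30 within cherries, 0 across
        C = 2.0 * np.array([
            [40, 30, 0, 0], [30, 40, 0, 0], [0, 0, 40, 30], [0, 0, 30, 40],
        ], dtype=float)
        # per-entry 4-sd Monte-Carlo band: Var(c_hat_ij) ~ (c_ii c_jj + c_ij^2)/n
        tol = 4.0 * np.sqrt((np.outer(np.diag(C), np.diag(C)) + C**2) / reps)
        assert np.all(np.abs(cov - C) < tol)

    def test_sigma_zero_degenerate(self, balanced_tree):
        vals = simulate_bm_trait(balanced_tree, 0.0, 1.0, 7.0,
                                 np.random.default_rng(0))
        assert all(v == 7.0 for v in vals.values())

    def test_negative_sigma_rejected(self, balanced_tree):
        with pytest.raises(ValueError):
            simulate_bm_trait(balanced_tree, -1.0, 1.0, 0.0)

    def test_variance_grows_linearly_with_depth(self):
        """Tip variance regressed on tip depth has slope within 10% of sigma2."""
        # non-ultrametric caterpillar: tips at depths 1..6
        t = TimeTree.from_newick(
            "(A:1,(B:1,(C:1,(D:1,(E:1,F:2):1):1):1):1);"
        )
        depths = t.depths()
        tips = t.tip_labels()
        rng = np.random.default_rng(11)
        sigma2 = 3.0
        sims = [simulate_bm_trait(t, sigma2, 1.0, 0.0, rng) for _ in range(1000)]
        draws = np.array([[s[x] for x in tips] for s in sims])
        var = draws.var(axis=0)
        d = np.array([depths[x] for x in tips])
        slope = np.polyfit(d, var, 1)[0]
        assert abs(slope - sigma2) / sigma2 < 0.10


class TestNicheShifts:
    def test_empty_spec_unchanged(self, balanced_tree):
        states = {n.name: 1.0 for n in balanced_tree.preorder()}
        out, gt = impose_niche_shifts(balanced_tree, states, [])
        assert out == states
        assert gt.true_shift_branches == frozenset()

    def test_single_shift_offsets_exactly_the_subtree(self, balanced_tree):
        states = {n.name: 1000.0 for n in balanced_tree.preorder()}
        cherry = balanced_tree.mrca({"A", "B"})
        out, gt = impose_niche_shifts(balanced_tree, states, [(cherry.name, 900.0)])
        assert out[cherry.name] == 1900.0
        assert out["A"] == 1900.0 and out["B"] == 1900.0
        assert out["C"] == 1000.0 and out[balanced_tree.root.name] == 1000.0
        assert gt.true_shift_branches == {cherry.name}

    def test_unknown_branch_rejected(self, balanced_tree):
        states = {n.name: 0.0 for n in balanced_tree.preorder()}
        with pytest.raises(Exception):
            impose_niche_shifts(balanced_tree, states, [("nope", 1.0)])


class TestMkHistory:
    def test_zero_rates_no_events(self, balanced_tree):
        q = np.zeros((2, 2))
        tips, gt = simulate_mk_history(balanced_tree, q, 1, np.random.default_rng(0))
        assert set(tips.values()) == {1}
        assert all(len(e) == 0 for e in gt.true_range_history.values())

    def test_two_state_transition_probability(self):
        """P(state change) over one branch matches the closed-form 2-state
        transition probability within Monte-Carlo error."""
        t_len = 4.0
        tree = TimeTree.from_newick(f"(A:{t_len},B:{t_len});")
        q01, q10 = 0.12, 0.3
        q = np.array([[-q01, q01], [q10, -q10]])
        # closed form: P01(t) = pi1 (1 - exp(-(q01+q10) t))
        s = q01 + q10
        p01 = q01 / s * (1 - np.exp(-s * t_len))
        rng = np.random.default_rng(42)
        reps = 5000
        flips = 0
        for _ in range(reps):
            tips, _ = simulate_mk_history(tree, q, 0, rng)
            flips += tips["A"] == 1
        phat = flips / reps
        assert abs(phat - p01) < 4 * np.sqrt(p01 * (1 - p01) / reps)

    def test_fixed_seed_identical_histories(self, five_tip_tree):
        q = np.array([[-0.4, 0.4], [0.2, -0.2]])
        r1 = simulate_mk_history(five_tip_tree, q, 0, np.random.default_rng(9))
        r2 = simulate_mk_history(five_tip_tree, q, 0, np.random.default_rng(9))
        assert r1[0] == r2[0]
        assert r1[1].true_range_history == r2[1].true_range_history


class TestLandscape:
    def test_zero_noise_occurrences_track_trait(self):
        cfg = SimulationConfig(n_tips=10, seed=2, occurrence_noise_deg=0.0,
                               n_occurrences_per_species=10)
        tree = simulate_tree(cfg)
        traits = {t: 500.0 + 200.0 * i for i, t in enumerate(tree.tip_labels())}
        layers, occ, _ = simulate_landscape_and_occurrences(tree, traits, cfg)
        # one gradient step = MAP difference between adjacent rows
        x0, y0, x1, y1 = cfg.landscape_extent
        step = (cfg.map_max - cfg.map_min) * cfg.resolution / (y1 - y0)
        for sp, sub in occ.groupby("taxon"):
            cell_map = layers["MAP"].value_at(sub["lon"].to_numpy(), sub["lat"].to_numpy())
            assert np.all(np.abs(cell_map - traits[sp]) <= step + 1e-9)

    def test_occurrences_never_leave_extent(self):
        cfg = SimulationConfig(n_tips=20, seed=3, occurrence_noise_deg=8.0)
        tree = simulate_tree(cfg)
        traits = {t: 1500.0 for t in tree.tip_labels()}
        _, occ, _ = simulate_landscape_and_occurrences(tree, traits, cfg)
        x0, y0, x1, y1 = cfg.landscape_extent
        assert occ["lon"].between(x0, x1).all()
        assert occ["lat"].between(y0, y1).all()

    def test_disjoint_trait_clades_occupy_disjoint_bands(self):
        cfg = SimulationConfig(n_tips=10, seed=4, occurrence_noise_deg=0.0)
        tree = simulate_tree(cfg)
        tips = tree.tip_labels()
        half = len(tips) // 2
        traits = {t: (600.0 if i < half else 2600.0) for i, t in enumerate(tips)}
        _, occ, _ = simulate_landscape_and_occurrences(tree, traits, cfg)
        lat_a = occ[occ["taxon"].isin(tips[:half])]["lat"]
        lat_b = occ[occ["taxon"].isin(tips[half:])]["lat"]
        assert lat_a.max() < lat_b.min()

    def test_monthly_layers_consistent_with_map(self):
        cfg = SimulationConfig(n_tips=5, seed=5)
        tree = simulate_tree(cfg)
        traits = {t: 1500.0 for t in tree.tip_labels()}
        layers, _, _ = simulate_landscape_and_occurrences(tree, traits, cfg)
        total = sum(layers[f"precip_{m:02d}"].data for m in range(1, 13))
        assert np.allclose(total, layers["MAP"].data, atol=1e-8)

    def test_true_dsl_matches_module_dsl(self):
        for map_val in (300.0, 900.0, 1500.0, 2500.0):
            monthly = map_val * monthly_profile(0.9)
            assert true_dry_season_length(map_val, 0.9) == grids.dry_season_length(monthly)


class TestGroundTruth:
    def test_validation_catches_unknown_nodes(self, balanced_tree):
        gt = GroundTruth(true_node_states={"missing": 1.0})
        with pytest.raises(ValueError):
            gt.validate_against(balanced_tree)
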