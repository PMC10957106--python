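"""Synthetic worlds with known ground truth.

Every downstream stage of the pipeline (gridding, turnover, GDM,
regionalization, niche and range reconstruction) is exercised on data
produced here, so each generator records the quantities the estimators are
later asked to recover:

* a birth--death tree conditioned on its tip count (ultrametric, binary),
* continuous niche traits evolved by Brownian motion with a Pagel's-lambda
  transformation, with every internal node's true value retained,
* discrete-state (Mk) histories with the full event sequence per branch,
* a climate landscape with a monotone mean-annual-precipitation (MAP)
  gradient, twelve monthly layers derived from it by a fixed seasonal
  profile (so dry-season length has a closed-form ground truth), and
  occurrence clouds drawn around each species' niche optimum.

Reproducibility: each generator draws from its own ``numpy`` Generator
seeded from ``config.seed`` plus a fixed per-stage offset, so a stage can be
re-run bit-identically without replaying the stages before it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import cell_index
from .rasters import AsciiGrid
from .trees import Node, TimeTree

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulationError",
    "simulate_tree",
    "simulate_bm_trait",
    "impose_niche_shifts",
    "simulate_mk_history",
    "simulate_landscape_and_occurrences",
]

# fixed per-stage RNG offsets (stage-level reproducibility)
_TREE_STREAM = 11
_TRAIT_STREAM = 23
_MK_STREAM = 37
_OCC_STREAM = 53


class SimulationError(RuntimeError):
    """Raised when conditioned simulation fails to produce a valid draw."""


@dataclass
class SimulationConfig:
    """Parameters of the stated synthetic world.

    Rates are per lineage per Ma; ``trait_sigma2`` is trait variance
    accumulated per Ma; ``lambda_true`` the Pagel transformation in [0, 1];
    ``mk_rates`` a square generator matrix (rows sum to zero).  The
    landscape is a plate-carree box in degrees with a linear MAP gradient
    from ``map_min`` to ``map_max`` (mm/yr) along latitude.
    """

    n_tips: int = 100
    birth_rate: float = 0.3
    death_rate: float = 0.1
    trait_sigma2: float = 40000.0  # (mm/yr)^2 per Ma: spans ~200-3000 mm over ~30 Ma
    lambda_true: float = 1.0
    mk_rates: np.ndarray = field(
        default_factory=lambda: np.array([[-0.05, 0.05], [0.05, -0.05]])
    )
    landscape_extent: tuple[float, float, float, float] = (-20.0, -30.0, 20.0, 30.0)
    n_occurrences_per_species: int = 50
    occurrence_noise_deg: float = 1.0
    map_min: float = 200.0
    map_max: float = 3000.0
    seasonal_amplitude: float = 0.9  # relative amplitude of the monthly profile
    resolution: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_tips < 2:
            raise ValueError("n_tips must be at least 2")
        if not (self.birth_rate > self.death_rate >= 0):
            raise ValueError("need birth_rate > death_rate >= 0")
        if self.trait_sigma2 < 0:
            raise ValueError("trait_sigma2 must be non-negative")
        if not (0.0 <= self.lambda_true <= 1.0):
            raise ValueError("lambda_true must lie in [0, 1]")
        q = np.asarray(self.mk_rates, dtype=float)
        if q.ndim != 2 or q.shape[0] != q.shape[1]:
            raise ValueError("mk_rates must be square")
        off = q - np.diag(np.diag(q))
        if (off < 0).any():
            raise ValueError("mk_rates off-diagonals must be non-negative")
        if not np.allclose(q.sum(axis=1), 0.0, atol=1e-10):
            raise ValueError("mk_rates rows must sum to zero")
        self.mk_rates = q
        x0, y0, x1, y1 = self.landscape_extent
        if not (x1 > x0 and y1 > y0):
            raise ValueError("landscape_extent is degenerate")
        if self.n_occurrences_per_species < 1:
            raise ValueError("n_occurrences_per_species must be positive")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class GroundTruth:
    """What the simulator knows and the estimators are asked to recover."""

    true_node_states: dict[str, float] = field(default_factory=dict)
    true_shift_branches: frozenset[str] = frozenset()
    true_range_history: dict[str, list[tuple[float, int]]] = field(default_factory=dict)
    true_cluster_of_cell: dict[int, int] = field(default_factory=dict)

    def validate_against(self, tree: TimeTree) -> None:
        names = {n.name for n in tree.preorder()}
        for key in list(self.true_node_states) + list(self.true_range_history):
            if key not in names:
                raise ValueError(f"ground truth references unknown node {key!r}")
        if not self.true_shift_branches <= names:
            raise ValueError("ground truth references unknown shift branches")


# --------------------------------------------------------------------- #
# birth--death trees
# --------------------------------------------------------------------- #
def simulate_tree(config: SimulationConfig, max_retries: int = 1000) -> TimeTree:
    """Simulate an ultrametric birth--death tree with exactly ``n_tips`` tips.

    Forward simulation from a crown pair of lineages; the process runs until
    the number of extant lineages first reaches ``n_tips`` (general sampling:
    grow until the target, prune the extinct), then extends the extant tips
    by a draw from the waiting time to the next event so tip branches are
    positive.  Replicates that go extinct first are retried; persistent
    failure raises :class:`SimulationError`.
    """
    rng = config.rng(_TREE_STREAM)
    b, d = config.birth_rate, config.death_rate
    n_target = config.n_tips

    for _ in range(max_retries):
        result = _grow_tree(rng, b, d, n_target)
        if result is not None:
            return result
    raise SimulationError(
        f"birth-death simulation failed to reach {n_target} tips "
        f"in {max_retries} attempts (b={b}, d={d})"
    )


def _grow_tree(rng, b: float, d: float, n_target: int) -> TimeTree | None:
    if n_target == 2:
        # smallest tree: one split, two equal tip branches
        t = rng.exponential(1.0 / (2 * (b + d))) if (b + d) > 0 else 1.0
        root = Node(None, 0.0)
        root.add_child(Node("sp001", t))
        root.add_child(Node("sp002", t))
        return TimeTree(root)

    root = Node(None, 0.0)
    left, right = Node(None, 0.0), Node(None, 0.0)
    root.add_child(left)
    root.add_child(right)
    extant = [left, right]
    t = 0.0
    birth_time = {id(left): 0.0, id(right): 0.0}
    while len(extant) < n_target:
        rate = len(extant) * (b + d)
        t += rng.exponential(1.0 / rate)
        k = rng.integers(len(extant))
        node = extant[k]
        if rng.random() < b / (b + d):
            c1, c2 = Node(None, 0.0), Node(None, 0.0)
            node.add_child(c1)
            node.add_child(c2)
            node.length = t - birth_time[id(node)]
            birth_time[id(c1)] = birth_time[id(c2)] = t
            extant[k] = c1
            extant.append(c2)
        else:
            node.length = t - birth_time[id(node)]
            node.name = "extinct"
            extant.pop(k)
            if not extant:
                return None
    # stop just before the next event would occur
    t += rng.exponential(1.0 / (len(extant) * (b + d)))
    for node in extant:
        node.length = t - birth_time[id(node)]
        node.name = "alive"

    tree = _prune_extinct(root)
    if tree is None or len(tree.tips()) != n_target:  # pragma: no cover
        return None
    for i, tip in enumerate(tree.tips(), start=1):
        tip.name = f"sp{i:03d}"
    return TimeTree(tree.root)


def _prune_extinct(root: Node) -> TimeTree | None:
    def build(n: Node) -> Node | None:
        if n.is_leaf:
            if n.name == "alive":
                return Node(None, n.length)
            return None
        kids = [k for k in (build(c) for c in n.children) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            kids[0].length += n.length
            return kids[0]
        m = Node(None, n.length)
        for k in kids:
            m.add_child(k)
        return m

    new_root = build(root)
    if new_root is None or new_root.is_leaf:
        return None
    new_root.length = 0.0
    return TimeTree(new_root)


# --------------------------------------------------------------------- #
# Brownian traits with a lambda transformation
# --------------------------------------------------------------------- #
def simulate_bm_trait(
    tree: TimeTree,
    sigma2: float,
    lambda_true: float = 1.0,
    root_state: float = 0.0,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Evolve a continuous trait by Brownian motion under Pagel's lambda.

    The lambda transformation multiplies internal branch lengths by lambda
    and stretches terminal branches to preserve each tip's root-to-tip
    depth, so tip values have covariance ``sigma2 * C(lambda)`` where the
    off-diagonal shared path lengths of C are scaled by lambda.  Values for
    every node (the transformed-tree realization) are returned keyed by node
    name; internal-node values serve as ground truth for ancestral-state
    recovery at lambda = 1.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    if not (0.0 <= lambda_true <= 1.0):
        raise ValueError("lambda_true must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng()

    depth = tree.depths()
    values: dict[str, float] = {tree.root.name: float(root_state)}
    for n in tree.preorder():
        if n.parent is None:
            continue
        if n.is_leaf:
            # terminal branch under the lambda stretch keeps total depth
            blen = lambda_true * n.length + (1.0 - lambda_true) * depth[n.name]
        else:
            blen = lambda_true * n.length
        step = rng.normal(0.0, np.sqrt(sigma2 * blen)) if blen > 0 else 0.0
        values[n.name] = values[n.parent.name] + step
    return values


def impose_niche_shifts(
    tree: TimeTree,
    states: dict[str, float],
    shift_spec: list[tuple[str, float]],
) -> tuple[dict[str, float], GroundTruth]:
    """Offset whole subtrees to create known niche shifts.

    ``shift_spec`` lists (branch id, delta); the branch id is the name of
    the child node of the shifted branch, and the delta is added to that
    node and all its descendants.  Returns the modified states and a
    :class:`GroundTruth` recording the shifted branches.
    """
    shifted = dict(states)
    for branch, delta in shift_spec:
        start = tree.find(branch)
        stack = [start]
        while stack:
            n = stack.pop()
            shifted[n.name] = shifted[n.name] + delta
            stack.extend(n.children)
    gt = GroundTruth(
        true_node_states=shifted,
        true_shift_branches=frozenset(b for b, _ in shift_spec),
    )
    gt.validate_against(tree)
    return shifted, gt


# --------------------------------------------------------------------- #
# Mk histories
# --------------------------------------------------------------------- #
def simulate_mk_history(
    tree: TimeTree,
    q_matrix: np.ndarray,
    root_state: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, int], GroundTruth]:
    """Simulate a continuous-time Markov (Mk) character down the tree.

    Returns tip states and a :class:`GroundTruth` whose
    ``true_range_history`` stores, per branch (keyed by child node name),
    the event sequence ``[(time offset from branch start, new state), ...]``
    and whose ``true_node_states`` stores the state at every node.
    """
    q = np.asarray(q_matrix, dtype=float)
    if not np.allclose(q.sum(axis=1), 0.0, atol=1e-10):
        raise ValueError("q_matrix rows must sum to zero")
    if rng is None:
        rng = np.random.default_rng()
    k = q.shape[0]

    node_state: dict[str, int] = {tree.root.name: int(root_state)}
    history: dict[str, list[tuple[float, int]]] = {}
    for n in tree.preorder():
        if n.parent is None:
            continue
        state = node_state[n.parent.name]
        events: list[tuple[float, int]] = []
        t = 0.0
        while True:
            rate = -q[state, state]
            if rate <= 0:
                break
            t += rng.exponential(1.0 / rate)
            if t >= n.length:
                break
            probs = q[state].copy()
            probs[state] = 0.0
            probs /= probs.sum()
            state = int(rng.choice(k, p=probs))
            events.append((t, state))
        node_state[n.name] = state
        history[n.name] = events

    tips = {t.name: node_state[t.name] for t in tree.tips()}
    gt = GroundTruth(
        true_node_states={k2: float(v) for k2, v in node_state.items()},
        true_range_history=history,
    )
    gt.validate_against(tree)
    return tips, gt


# --------------------------------------------------------------------- #
# landscape and occurrences
# --------------------------------------------------------------------- #
def monthly_profile(amplitude: float) -> np.ndarray:
    """Fixed seasonal weights: fraction of annual rain falling each month.

    A raised cosine with the wet peak in January; weights are non-negative
    and sum to 1, so monthly precipitation is ``MAP * weight``.
    """
    m = np.arange(12)
    w = np.maximum(0.0, 1.0 + amplitude * np.cos(2 * np.pi * m / 12.0))
    return w / w.sum()


def true_dry_season_length(map_value: float, amplitude: float) -> int:
    """Closed-form DSL implied by the seasonal profile at a given MAP."""
    monthly = map_value * monthly_profile(amplitude)
    dry = monthly < 100.0
    if dry.all():
        return 12
    doubled = np.concatenate([dry, dry])
    best = run = 0
    for flag in doubled:
        run = run + 1 if flag else 0
        best = max(best, run)
    return int(min(best, 12))


def simulate_landscape_and_occurrences(
    tree: TimeTree,
    states: dict[str, float],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, AsciiGrid], pd.DataFrame, GroundTruth]:
    """Build the climate landscape and draw occurrences around niche optima.

    The MAP raster increases linearly with latitude from ``map_min`` at the
    southern edge to ``map_max`` at the northern edge; twelve monthly layers
    are MAP times a fixed seasonal profile.  Each species' occurrences are
    placed at the latitude whose cell MAP is nearest its trait value, with
    Gaussian latitudinal noise, uniform longitude, and coordinates clipped
    to the landscape extent.  ``true_cluster_of_cell`` labels cells 0/1 by
    the landscape's median MAP (the two-band ground truth used by the
    regionalization recovery experiments).
    """
    if rng is None:
        rng = config.rng(_OCC_STREAM)
    x0, y0, x1, y1 = config.landscape_extent
    res = config.resolution
    ncols = int(round((x1 - x0) / res))
    nrows = int(round((y1 - y0) / res))
    if ncols < 1 or nrows < 1:
        raise ValueError("landscape_extent too small for the resolution")

    lat_centers = y0 + (np.arange(nrows) + 0.5) * res  # south to north
    frac = (lat_centers - y0) / (y1 - y0)
    map_by_row = config.map_min + frac * (config.map_max - config.map_min)

    # rasters are stored north-up (row 0 = northern edge)
    map_grid = np.tile(map_by_row[::-1, None], (1, ncols))
    layers = {"MAP": AsciiGrid(map_grid, x0, y0, res)}
    profile = monthly_profile(config.seasonal_amplitude)
    for m in range(12):
        layers[f"precip_{m + 1:02d}"] = AsciiGrid(map_grid * profile[m], x0, y0, res)

    # species occurrence clouds
    tip_names = tree.tip_labels()
    span = config.map_max - config.map_min
    records = []
    for sp in tip_names:
        trait = states[sp]
        target_frac = np.clip((trait - config.map_min) / span, 0.0, 1.0)
        target_lat = y0 + target_frac * (y1 - y0)
        lats = target_lat + rng.normal(0.0, config.occurrence_noise_deg,
                                       config.n_occurrences_per_species)
        eps = 1e-9
        lats = np.clip(lats, y0, y1 - eps)
        lons = rng.uniform(x0, x1 - eps, config.n_occurrences_per_species)
        for lon, lat in zip(lons, lats):
            records.append((sp, float(lon), float(lat)))
    occ = pd.DataFrame(records, columns=["taxon", "lon", "lat"])

    # two-band cluster ground truth by median MAP
    mid = 0.5 * (config.map_min + config.map_max)
    clusters: dict[int, int] = {}
    for r in range(nrows):
        for c in range(ncols):
            row_idx = int((y0 + (r + 0.5) * res + 90.0) / res)
            col_idx = int((x0 + (c + 0.5) * res + 180.0) / res)
            cell = cell_index(row_idx, col_idx, res)
            clusters[cell] = int(map_by_row[r] >= mid)
    gt = GroundTruth(true_cluster_of_cell=clusters)
    return layers, occ, gt


def config_as_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["mk_rates"] = np.asarray(config.mk_rates).tolist()
    return d
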