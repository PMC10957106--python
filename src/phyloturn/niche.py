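"""Continuous niche evolution on the tree.

Maximum-likelihood ancestral states under Brownian motion (BM) by linear
belief propagation (each internal node's estimate equals the ML root state
of the tree re-rooted at that node; the root estimate is the phylogenetic
GLS mean), Pagel's lambda by profile likelihood over a transformed
covariance, and the downstream niche bookkeeping: categorizing nodes into
precipitation regimes, detecting category shifts that also pass a
minimum-change rule, dating them at the branch midpoint, and expressing
shift counts per 5-Ma bin relative to phylogenetic splits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar

from .rasters import AsciiGrid
from .trees import TimeTree

logger = logging.getLogger(__name__)

__all__ = [
    "ancestral_states_bm",
    "pagels_lambda",
    "NicheCategorySpec",
    "MAP_CATEGORIES",
    "DSL_CATEGORIES",
    "NicheShift",
    "detect_niche_shifts",
    "shifts_per_time_bin",
    "classify_tropical",
    "phylo_covariance",
]

_MIN_BRANCH = 1e-8


def _effective_lengths(tree: TimeTree) -> dict[str, float]:
    out = {}
    warned = False
    for n in tree.preorder():
        if n.parent is None:
            continue
        length = n.length
        if length <= 0:
            if not warned:
                logger.warning("perturbing zero-length branches by %g", _MIN_BRANCH)
                warned = True
            length = _MIN_BRANCH
        out[n.name] = length
    return out


def ancestral_states_bm(
    tree: TimeTree,
    tip_values: dict[str, float],
    outgroup: list[str] | None = None,
) -> dict[str, tuple[float, float]]:
    """ML ancestral states under BM for every node.

    Returns ``{node name: (estimate, variance)}``; tip entries carry the
    observed value with zero variance.  Variances are conditional variances
    scaled by the ML rate estimate ``sigma2_hat = Q / n`` (Q the GLS
    quadratic form).  If ``outgroup`` tip labels are given, the whole tree
    is used for the optimization but only nodes inside the remaining
    (ingroup) clade are reported.
    """
    tips = tree.tip_labels()
    missing = set(tips) - set(tip_values)
    if missing:
        raise ValueError(f"missing tip values: {sorted(missing)}")
    lengths = _effective_lengths(tree)

    # up-pass: conditional (mean, variance) of each subtree
    up: dict[str, tuple[float, float]] = {}
    Q = 0.0
    n_tips = len(tips)
    for n in tree.postorder():
        if n.is_leaf:
            up[n.name] = (float(tip_values[n.name]), 0.0)
            continue
        msgs = [
            (up[c.name][0], up[c.name][1] + lengths[c.name]) for c in n.children
        ]
        m, v = msgs[0]
        for m2, v2 in msgs[1:]:
            Q += (m - m2) ** 2 / (v + v2)
            m, v = (m * v2 + m2 * v) / (v + v2), v * v2 / (v + v2)
        up[n.name] = (m, v)
    sigma2_hat = Q / n_tips if n_tips else 0.0

    # down-pass: message from the rest of the tree into each node
    down: dict[str, tuple[float, float] | None] = {tree.root.name: None}
    for n in tree.preorder():
        if n.is_leaf:
            continue
        for c in n.children:
            msgs = []
            if down[n.name] is not None:
                msgs.append(down[n.name])
            for s in n.children:
                if s is not c:
                    msgs.append((up[s.name][0], up[s.name][1] + lengths[s.name]))
            m, v = msgs[0]
            for m2, v2 in msgs[1:]:
                m, v = (m * v2 + m2 * v) / (v + v2), v * v2 / (v + v2)
            down[c.name] = (m, v + lengths[c.name])

    est: dict[str, tuple[float, float]] = {}
    for n in tree.preorder():
        if n.is_leaf:
            est[n.name] = (float(tip_values[n.name]), 0.0)
            continue
        msgs = [(up[c.name][0], up[c.name][1] + lengths[c.name]) for c in n.children]
        if down[n.name] is not None:
            msgs.append(down[n.name])
        m, v = msgs[0]
        for m2, v2 in msgs[1:]:
            m, v = (m * v2 + m2 * v) / (v + v2), v * v2 / (v + v2)
        est[n.name] = (m, v * sigma2_hat)

    if outgroup:
        ingroup = [t for t in tips if t not in set(outgroup)]
        keep_root = tree.mrca(ingroup)
        keep = set()
        stack = [keep_root]
        while stack:
            node = stack.pop()
            keep.add(node.name)
            stack.extend(node.children)
        est = {k: v for k, v in est.items() if k in keep and k not in set(outgroup)}
    return est


def phylo_covariance(tree: TimeTree, lam: float = 1.0) -> tuple[np.ndarray, list[str]]:
    """BM covariance (shared root-to-MRCA path lengths), off-diagonals
    scaled by lambda; returns the matrix and its tip order."""
    tips = tree.tip_labels()
    pos = {t: i for i, t in enumerate(tips)}
    depth = tree.depths()
    n = len(tips)
    C = np.zeros((n, n))
    tipsets = tree.tip_sets()
    for node in tree.preorder():
        if node.is_leaf:
            C[pos[node.name], pos[node.name]] = depth[node.name]
            continue
        d = depth[node.name]
        kids = [sorted(tipsets[c.name]) for c in node.children]
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                for ta in kids[a]:
                    for tb in kids[b]:
                        i, j = pos[ta], pos[tb]
                        C[i, j] = C[j, i] = d
    if lam != 1.0:
        diag = np.diag(C).copy()
        C = lam * C
        np.fill_diagonal(C, diag)
    return C, tips


def _gls_loglik(C: np.ndarray, x: np.ndarray) -> float:
    n = len(x)
    cf = cho_factor(C, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    ones = np.ones(n)
    Ci1 = cho_solve(cf, ones)
    Cix = cho_solve(cf, x)
    mu = float(ones @ Cix / (ones @ Ci1))
    r = x - mu
    q = float(r @ cho_solve(cf, r))
    sigma2 = max(q / n, 1e-300)
    return -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)


def pagels_lambda(
    tree: TimeTree,
    tip_values: dict[str, float],
    lambda_max: float = 1.0,
) -> tuple[float, float, float]:
    """ML Pagel's lambda with a likelihood-ratio test against lambda = 0.

    Profiles out the GLS mean and the BM rate analytically and maximizes
    over lambda in [0, lambda_max] (default 1, which keeps the covariance
    positive-definite on ultrametric trees).  Returns
    ``(lambda_hat, logL, p_value)`` with the p-value from a chi-square(1)
    likelihood-ratio test against lambda = 0 (no signal).
    """
    tips = tree.tip_labels()
    if len(tips) < 4:
        raise ValueError("need at least 4 tips")
    x = np.array([tip_values[t] for t in tips], dtype=float)
    C1, order = phylo_covariance(tree, 1.0)
    diag = np.diag(C1).copy()
    off = C1 - np.diag(diag)

    def loglik(lam: float) -> float:
        C = lam * off + np.diag(diag)
        return _gls_loglik(C, x)

    neg = lambda lam: -loglik(lam)  # noqa: E731
    res = minimize_scalar(neg, bounds=(0.0, lambda_max), method="bounded",
                          options={"xatol": 1e-8})
    candidates = [(0.0, loglik(0.0)), (lambda_max, loglik(lambda_max)),
                  (float(res.x), -float(res.fun))]
    lam_hat, logl = max(candidates, key=lambda t: t[1])
    lr = 2.0 * (logl - candidates[0][1])
    p = float(stats.chi2.sf(max(lr, 0.0), df=1))
    return float(lam_hat), float(logl), p


# --------------------------------------------------------------------- #
# niche categories and shifts
# --------------------------------------------------------------------- #
@dataclass(frozen=True)
class NicheCategorySpec:
    """Dry/intermediate/wet banding of a precipitation variable.

    For MAP the wet regime is the high end (dry < 1200, wet > 1800 mm/yr);
    for dry-season length it is the low end (wet < 4, dry > 8 months).
    ``min_change`` is the minimum absolute change along a branch for a
    category change to count as a shift.
    """

    variable: str
    lower: float
    upper: float
    min_change: float
    wet_is_high: bool = True

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError("boundaries must be ordered")
        if self.min_change <= 0:
            raise ValueError("min_change must be positive")

    def category(self, value: float) -> str:
        if value < self.lower:
            return "dry" if self.wet_is_high else "wet"
        if value > self.upper:
            return "wet" if self.wet_is_high else "dry"
        return "intermediate"


MAP_CATEGORIES = NicheCategorySpec("MAP", 1200.0, 1800.0, 250.0, wet_is_high=True)
DSL_CATEGORIES = NicheCategorySpec("DSL", 4.0, 8.0, 1.0, wet_is_high=False)


@dataclass(frozen=True)
class NicheShift:
    """A category change of at least ``min_change`` on a single branch."""

    branch: str
    parent_value: float
    child_value: float
    parent_category: str
    child_category: str
    parent_age: float
    child_age: float

    @property
    def age(self) -> float:
        """Shift age: midpoint of the parent and child node ages."""
        return 0.5 * (self.parent_age + self.child_age)

    @property
    def delta(self) -> float:
        return self.child_value - self.parent_value


def detect_niche_shifts(
    tree: TimeTree,
    node_states: dict[str, float],
    spec: NicheCategorySpec,
) -> list[NicheShift]:
    """Branches whose endpoint values change category by >= min_change.

    ``node_states`` maps every node (internal estimates plus observed tip
    values) to its reconstructed value; terminal branches use the observed
    tip value as the child state.  Both conditions are required: a category
    change alone, or a large change within a category, is not a shift.
    """
    ages = tree.ages()
    shifts = []
    for n in tree.preorder():
        if n.parent is None:
            continue
        pv = node_states[n.parent.name]
        cv = node_states[n.name]
        pc, cc = spec.category(pv), spec.category(cv)
        if pc != cc and abs(cv - pv) >= spec.min_change:
            shifts.append(
                NicheShift(n.name, pv, cv, pc, cc, ages[n.parent.name], ages[n.name])
            )
    return shifts


def shifts_per_time_bin(
    shifts,
    tree: TimeTree,
    bin_width: float = 5.0,
    denominator: str = "splits",
) -> pd.DataFrame:
    """Shift counts per time bin as a fraction of phylogenetic splits.

    Bins of ``bin_width`` Ma tile [0, root age]; ``n_splits`` counts
    internal-node ages per bin (or branch midpoints when ``denominator`` is
    ``"branches"``); fractions are NaN where the denominator is zero.
    Accepts any objects with an ``age`` attribute (niche shifts, dispersal
    events).
    """
    if denominator not in {"splits", "branches"}:
        raise ValueError("denominator must be 'splits' or 'branches'")
    ages = tree.ages()
    root_age = tree.root_age
    n_bins = max(1, int(np.ceil(root_age / bin_width - 1e-12)))
    edges = np.arange(n_bins + 1) * bin_width

    internal_ages = [ages[n.name] for n in tree.internal_nodes()]
    branch_mid_ages = [
        0.5 * (ages[n.parent.name] + ages[n.name])
        for n in tree.preorder() if n.parent is not None
    ]
    shift_ages = [s.age for s in shifts]

    def bin_of(a: float) -> int:
        return min(int(a // bin_width), n_bins - 1)

    n_splits = np.zeros(n_bins, dtype=int)
    denom_vals = internal_ages if denominator == "splits" else branch_mid_ages
    for a in denom_vals:
        n_splits[bin_of(a)] += 1
    n_shifts = np.zeros(n_bins, dtype=int)
    for a in shift_ages:
        n_shifts[bin_of(a)] += 1
    frac = np.where(n_splits > 0, n_shifts / np.maximum(n_splits, 1), np.nan)
    return pd.DataFrame({
        "bin_start_ma": edges[:-1],
        "bin_end_ma": edges[1:],
        "n_shifts": n_shifts,
        "n_splits": n_splits,
        "fraction": frac,
    })


def classify_tropical(
    records: pd.DataFrame,
    frost_raster: AsciiGrid,
) -> dict[str, str]:
    """Score each taxon tropical or temperate from its occurrences.

    The frost raster is 1 where temperatures drop below freezing in a
    typical year, 0 elsewhere.  A taxon is temperate iff strictly more than
    half of its occurrence points fall in frost cells; a tie stays
    tropical.
    """
    out = {}
    for sp, sub in records.groupby("taxon"):
        vals = frost_raster.value_at(sub["lon"].to_numpy(), sub["lat"].to_numpy())
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"taxon {sp!r} has no records with frost coverage")
        out[str(sp)] = "temperate" if (vals > 0).mean() > 0.5 else "tropical"
    return out
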