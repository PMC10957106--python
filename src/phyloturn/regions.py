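"""Phyloregionalization: clustering grid cells by phylogenetic turnover.

Cells are clustered agglomeratively from their pairwise dissimilarity
matrix (Ward by default, UPGMA as the candidate it is selected against via
cophenetic correlation), the dendrogram is cut into k = 2..8 phyloregions,
and the climatic distinctness of the resulting clusters is tested with
rank-based statistics (Wilcoxon rank-sum for two clusters, Kruskal-Wallis
followed by Dunn's test with Bonferroni adjustment for more).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "Phyloregionalization",
    "cluster_cells",
    "cophenetic_correlation",
    "select_algorithm",
    "ClimateTestReport",
    "cluster_climate_tests",
    "dunn_test",
]


@dataclass
class Phyloregionalization:
    """Dendrogram over cells plus nested cluster labels for k = 2..8."""

    linkage: np.ndarray
    labels: dict[int, np.ndarray]
    cells: list
    method: str
    cophenetic_r: float | None = None

    def labels_for(self, k: int) -> np.ndarray:
        return self.labels[k]

    def as_frame(self) -> pd.DataFrame:
        data = {f"label_k{k}": v for k, v in self.labels.items()}
        return pd.DataFrame(data, index=pd.Index(self.cells, name="cell"))


def _prepare_matrix(matrix: np.ndarray) -> np.ndarray:
    d = np.asarray(matrix, dtype=float).copy()
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(d, d.T, equal_nan=True):
        raise ValueError("dissimilarity matrix must be symmetric")
    np.fill_diagonal(d, 0.0)
    missing = ~np.isfinite(d)
    if missing.any():
        finite = d[np.isfinite(d)]
        if finite.size == 0:
            raise ValueError("matrix has no finite entries")
        n_missing = int(missing.sum() // 2)
        logger.warning("imputing %d undefined cell pairs with the matrix maximum", n_missing)
        d[missing] = finite.max()
        np.fill_diagonal(d, 0.0)
        bad = [i for i in range(d.shape[0]) if not np.isfinite(d[i]).all()]
        if bad:
            raise ValueError(f"cells with undefined pairs after imputation: {bad}")
    return d


def cluster_cells(
    matrix: np.ndarray,
    cells: list | None = None,
    method: str = "ward",
    k_range: range = range(2, 9),
    ward_variant: str = "D2",
) -> Phyloregionalization:
    """Agglomerative clustering of cells from a dissimilarity matrix.

    ``method`` is ``"ward"`` or ``"upgma"``.  Ward's default contract
    ("D2") applies the Lance-Williams recursion to squared dissimilarities;
    the "D" variant applies it to the raw dissimilarities (implemented by
    feeding sqrt-transformed distances to the same recursion and squaring
    the merge heights back).  Undefined pairs are imputed with the matrix
    maximum before clustering, with a logged count.
    """
    d = _prepare_matrix(matrix)
    if cells is None:
        cells = list(range(d.shape[0]))
    cond = squareform(d, checks=False)
    if method == "upgma":
        Z = hierarchy.linkage(cond, method="average")
    elif method == "ward":
        if ward_variant == "D2":
            Z = hierarchy.linkage(cond, method="ward")
        elif ward_variant == "D":
            Z = hierarchy.linkage(np.sqrt(cond), method="ward")
            Z = Z.copy()
            Z[:, 2] = Z[:, 2] ** 2
        else:
            raise ValueError(f"unknown ward_variant {ward_variant!r}")
    else:
        raise ValueError(f"unknown method {method!r}")

    labels = {}
    for k in k_range:
        if k > len(cells):
            break
        labels[k] = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return Phyloregionalization(Z, labels, list(cells), method)


def cophenetic_correlation(linkage: np.ndarray, matrix: np.ndarray) -> float:
    """Pearson correlation between cophenetic and input distances."""
    d = _prepare_matrix(matrix)
    coph = hierarchy.cophenet(linkage)
    r = np.corrcoef(coph, squareform(d, checks=False))[0, 1]
    return float(r)


def select_algorithm(
    matrix: np.ndarray,
    cells: list | None = None,
    candidates: tuple[str, ...] = ("upgma", "ward"),
) -> dict[str, Phyloregionalization]:
    """Fit candidate algorithms and attach their cophenetic correlations."""
    out = {}
    for method in candidates:
        reg = cluster_cells(matrix, cells, method=method)
        reg.cophenetic_r = cophenetic_correlation(reg.linkage, matrix)
        out[method] = reg
    return out


# --------------------------------------------------------------------- #
# climatic distinctness of clusters
# --------------------------------------------------------------------- #
@dataclass
class ClimateTestReport:
    """Rank-test summary of climatic differences between clusters."""

    variable: str
    n_clusters: int
    test: str
    p_value: float
    dunn: pd.DataFrame | None = None
    n_distinct: int | None = None
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return bool(self.p_value < self.alpha)


def _group_values(labels, values):
    labels = np.asarray(labels)
    values = np.asarray(values, dtype=float)
    groups = []
    uniq = np.unique(labels)
    for g in uniq:
        v = values[labels == g]
        if len(v) < 2:
            raise ValueError(f"cluster {g} has fewer than 2 cells")
        groups.append(v)
    return uniq, groups


def dunn_test(labels, values, adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's pairwise z-tests on ranks after a Kruskal-Wallis rejection.

    Mid-ranks with tie correction; two-sided normal p-values, Bonferroni
    multiplied by the number of comparisons (clipped at 1).
    """
    uniq, groups = _group_values(labels, values)
    all_vals = np.concatenate(groups)
    n_total = len(all_vals)
    ranks = stats.rankdata(all_vals)
    # tie correction term
    _, counts = np.unique(all_vals, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_total - 1))
    var_factor = n_total * (n_total + 1) / 12.0 - tie_term

    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start : start + len(g)].mean())
        start += len(g)

    rows = []
    m = len(uniq) * (len(uniq) - 1) // 2
    for i in range(len(uniq)):
        for j in range(i + 1, len(uniq)):
            se = np.sqrt(var_factor * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * stats.norm.sf(abs(z))
            p_adj = min(1.0, p * m) if adjust == "bonferroni" else p
            rows.append({
                "cluster_a": uniq[i], "cluster_b": uniq[j],
                "z": z, "p_raw": p, "p_adjusted": p_adj,
            })
    return pd.DataFrame(rows)


def cluster_climate_tests(
    labels,
    values,
    variable: str = "climate",
    alpha: float = 0.05,
) -> ClimateTestReport:
    """Test whether clusters differ in a climate variable.

    Two clusters: two-sided Wilcoxon rank-sum.  More: Kruskal-Wallis; if
    significant, Dunn's pairwise tests with Bonferroni adjustment, and the
    count of clusters that differ significantly from every other cluster.
    """
    uniq, groups = _group_values(labels, values)
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters")
    if len(uniq) == 2:
        stat = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
        return ClimateTestReport(variable, 2, "wilcoxon_rank_sum",
                                 float(stat.pvalue), alpha=alpha)
    kw = stats.kruskal(*groups)
    report = ClimateTestReport(variable, len(uniq), "kruskal_wallis",
                               float(kw.pvalue), alpha=alpha)
    if report.significant:
        dunn = dunn_test(labels, values)
        report.dunn = dunn
        distinct = 0
        for g in uniq:
            mask = (dunn["cluster_a"] == g) | (dunn["cluster_b"] == g)
            if (dunn.loc[mask, "p_adjusted"] < alpha).all():
                distinct += 1
        report.n_distinct = distinct
    return report
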