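"""Ordination and group structure: PCA, 5x1 self-organizing map, Ward
clustering, productive-trajectory regression and Tukey-Kramer contrasts.

PCA is column-centered with no unit-variance scaling, on (40 - dCt) levels
(undetected entries filled per the configured policy). A one-dimensional,
five-unit SOM on the first two PC scores partitions cells into the groups
seen along the reprogramming trajectory; units are relabeled Fib / Early /
Late / Pluri by the mean progression of their members, with the unit most
enriched for off-trajectory cells labeled Alt.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = [
    "OrdinationResult",
    "run_pca",
    "som_partition",
    "ward_cluster",
    "linkage_to_newick",
    "productive_regression",
    "tukey_kramer",
    "top_correlation_edges",
]

PRODUCTIVE_LABELS = ("Fib", "Early", "Late", "Pluri")


@dataclasses.dataclass
class OrdinationResult:
    scores: pd.DataFrame  # cells x PCs
    variance_fractions: np.ndarray  # non-increasing, sums to <= 1
    loadings: pd.DataFrame  # genes x PCs

    def pc12_variance(self) -> float:
        return float(self.variance_fractions[:2].sum())


def run_pca(levels: pd.DataFrame, n_components: int | None = None,
            scale: bool = False) -> OrdinationResult:
    """Centering-only PCA on expression levels (scaling optional)."""
    if levels.shape[0] < 3 or levels.shape[1] < 2:
        raise ValueError("PCA needs at least 3 cells and 2 genes")
    x = levels.to_numpy(dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("degenerate input: constant expression matrix")
    if scale:
        sd = x.std(axis=0, ddof=1)
        x = x / np.where(sd > 0, sd, 1.0)
    n_components = n_components or min(x.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(x)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return OrdinationResult(
        scores=pd.DataFrame(scores, index=levels.index, columns=cols),
        variance_fractions=pca.explained_variance_ratio_,
        loadings=pd.DataFrame(pca.components_.T, index=levels.columns,
                              columns=cols),
    )


def _batch_som_1d(x: np.ndarray, n_units: int, epochs: int,
                  init: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic batch-trained 1-D SOM; returns (weights, assignments)."""
    w = init.copy()
    unit_pos = np.arange(n_units, dtype=float)
    r0 = n_units / 2.0
    for e in range(epochs):
        radius = max(r0 * (1.0 - e / epochs), 0.25)  # linear decay
        d = ((x[:, None, :] - w[None, :, :]) ** 2).sum(axis=2)
        bmu = d.argmin(axis=1)
        h = np.exp(-((unit_pos[None, :] - unit_pos[bmu][:, None]) ** 2)
                   / (2.0 * radius ** 2))
        denom = h.sum(axis=0)
        ok = denom > 0
        w[ok] = (h.T @ x)[ok] / denom[ok, None]
    d = ((x[:, None, :] - w[None, :, :]) ** 2).sum(axis=2)
    return w, d.argmin(axis=1)


def som_partition(scores: pd.DataFrame, progression: pd.Series,
                  off_distance: pd.Series, *, n_units: int = 5,
                  epochs: int = 500, seed: int = 0,
                  method: str = "som") -> pd.Series:
    """Partition cells into Fib / Early / Late / Pluri / Alt.

    A 5-unit, 1-D SOM (or, with ``method="kmeans"``, a seeded k-means with
    the same unit count) is trained on (PC1, PC2). The unit whose members
    have the largest mean off-trajectory distance is labeled Alt; the
    remaining units are labeled Fib, Early, Late, Pluri in order of their
    members' mean progression. Deterministic for fixed seed.
    """
    if len(scores) < n_units:
        raise ValueError("fewer cells than SOM units")
    x = scores.iloc[:, :2].to_numpy(dtype=float)

    if method == "som":
        # seeded init from evenly spaced PC1 quantiles
        qs = np.linspace(0.1, 0.9, n_units)
        order = np.argsort(x[:, 0], kind="stable")
        init = np.empty((n_units, 2))
        for i, q in enumerate(qs):
            lo = x[:, 0] <= np.quantile(x[:, 0], min(q + 0.1, 1.0))
            hi = x[:, 0] >= np.quantile(x[:, 0], max(q - 0.1, 0.0))
            sel = lo & hi
            init[i] = x[sel].mean(axis=0) if sel.any() else x[order[
                int(q * (len(x) - 1))]]
        _, unit = _batch_som_1d(x, n_units, epochs, init)
    elif method == "kmeans":
        km = KMeans(n_clusters=n_units, n_init=10, random_state=seed)
        unit = km.fit_predict(x)
    else:
        raise ValueError(f"unknown method {method!r}")

    unit = pd.Series(unit, index=scores.index)
    present = sorted(unit.unique())
    if len(present) < n_units:
        warnings.warn(f"{n_units - len(present)} empty SOM unit(s)")
    mean_off = {u: off_distance[unit == u].mean() for u in present}
    alt_unit = max(mean_off, key=mean_off.get)
    rest = [u for u in present if u != alt_unit]
    rest.sort(key=lambda u: progression[unit == u].mean())
    label_of = {alt_unit: "Alt"}
    for lab, u in zip(PRODUCTIVE_LABELS, rest):
        label_of[u] = lab
    labels = unit.map(label_of)
    labels.name = "group"
    return labels


def ward_cluster(levels: pd.DataFrame):
    """Ward-linkage agglomerative dendrogram on unscaled levels.

    Returns the scipy linkage matrix (merge heights are the Ward distances).
    """
    if len(levels) < 2:
        raise ValueError("need at least 2 cells to cluster")
    return hierarchy.linkage(levels.to_numpy(dtype=float), method="ward")


def linkage_to_newick(Z: np.ndarray, leaf_names) -> str:
    """Render a scipy linkage matrix as a Newick string (heights as branch
    lengths)."""
    tree = hierarchy.to_tree(Z)
    names = list(leaf_names)

    def rec(node, parent_height):
        bl = parent_height - node.dist
        if node.is_leaf():
            return f"{names[node.id]}:{bl:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{bl:.6g}"

    return rec(tree, tree.dist) + ";"


def productive_regression(scores: pd.DataFrame, productive_ids) -> tuple:
    """OLS of PC2 on PC1 over productive-trajectory cells.

    Returns (slope, intercept, r_squared).
    """
    import statsmodels.api as sm

    sub = scores.loc[list(productive_ids)]
    if len(sub) < 3:
        raise ValueError("need at least 3 productive cells")
    x = sm.add_constant(sub["PC1"].to_numpy())
    fit = sm.OLS(sub["PC2"].to_numpy(), x).fit()
    return float(fit.params[1]), float(fit.params[0]), float(fit.rsquared)


def tukey_kramer(levels: pd.DataFrame, groups: pd.Series, gene: str,
                 alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise group contrasts of one gene's level, Tukey-Kramer
    (unequal-n honest-significant-difference) adjusted.

    Groups with fewer than 2 cells are skipped with a warning. Returns a
    DataFrame (group1, group2, meandiff, p_adj, significant).
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    y = levels[gene]
    g = groups.reindex(y.index)
    sizes = g.value_counts()
    small = sizes[sizes < 2].index.tolist()
    if small:
        warnings.warn(f"{gene}: groups skipped (n < 2): {small}")
        keep = ~g.isin(small)
        y, g = y[keep], g[keep]
    if g.nunique() < 2:
        raise ValueError("need at least 2 comparable groups")
    res = pairwise_tukeyhsd(y.to_numpy(dtype=float), g.to_numpy(), alpha=alpha)
    frame = pd.DataFrame(res.summary().data[1:],
                         columns=[c.strip() for c in res.summary().data[0]])
    return pd.DataFrame({
        "group1": frame["group1"], "group2": frame["group2"],
        "meandiff": frame["meandiff"].astype(float),
        "p_adj": frame["p-adj"].astype(float),
        "significant": frame["reject"].astype(bool),
    })


def tukey_gene_ranking(levels: pd.DataFrame, groups: pd.Series,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Rank genes by their most significant pairwise group contrast."""
    rows = []
    for gene in levels.columns:
        try:
            t = tukey_kramer(levels, groups, gene, alpha=alpha)
        except ValueError:
            continue
        rows.append({"gene": gene, "min_p_adj": float(t["p_adj"].min()),
                     "n_significant_pairs": int(t["significant"].sum())})
    return (pd.DataFrame(rows).set_index("gene")
            .sort_values("min_p_adj"))


def top_correlation_edges(levels: pd.DataFrame, n_edges: int = 100) -> pd.DataFrame:
    """Edge list of the strongest cell-cell Pearson correlations (the
    force-directed network is reduced to this export)."""
    x = levels.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    np.nan_to_num(r, copy=False)  # constant cells carry no usable edges
    cells = list(levels.index)
    iu = np.triu_indices(len(cells), k=1)
    vals = r[iu]
    order = np.argsort(-vals, kind="stable")[:n_edges]
    return pd.DataFrame({
        "cell_a": [cells[iu[0][i]] for i in order],
        "cell_b": [cells[iu[1][i]] for i in order],
        "r": vals[order],
    })
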