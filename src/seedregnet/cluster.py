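"""K-means co-clustering of temporal profiles, PCA/HCA summaries, and
cross-omics cluster matching.

Clustering operates on z-scored *group-mean* profiles (one value per
stage), so replicate noise is averaged out before pattern matching.
Lloyd's algorithm with k-means++ seeding is run `n_init` times and the
restart with the lowest total within-cluster sum of squares wins; ties
in seeding and assignment break toward the lowest row index so results
are fully reproducible for a given seed.

Cluster labels follow the stage-peak convention: cluster 1 has the
latest-peaking centroid, cluster k the earliest (for k=3 this maps
1 -> T4, 2 -> mid stages, 3 -> T1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist, squareform

from .errors import ParameterError


@dataclass
class ClusterAssignment:
    """Result of k-means over feature profiles."""

    feature_ids: list[str]
    labels: pd.Series  # feature -> cluster index in 1..k
    centroids: pd.DataFrame  # k x n_groups, index 1..k
    k: int
    total_wss: float
    rng_seed: int
    wss_trace: list[float] = field(default_factory=list)

    def members(self, cluster: int) -> list[str]:
        return list(self.labels.index[self.labels == cluster])


def _kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    centers = [int(rng.integers(n))]
    d2 = ((X - X[centers[0]]) ** 2).sum(axis=1)
    for _ in range(1, k):
        total = d2.sum()
        if total <= 0:
            # all remaining mass at distance zero: take the lowest unused index
            unused = [i for i in range(n) if i not in centers]
            centers.append(unused[0])
        else:
            r = rng.random() * total
            idx = int(np.searchsorted(np.cumsum(d2), r, side="right"))
            idx = min(idx, n - 1)
            centers.append(idx)
        d2 = np.minimum(d2, ((X - X[centers[-1]]) ** 2).sum(axis=1))
    return X[centers].copy()


def _lloyd(
    X: np.ndarray, centers: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    trace: list[float] = []
    labels = np.zeros(X.shape[0], dtype=int)
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)  # argmin ties -> lowest cluster index
        wss = float(d2[np.arange(X.shape[0]), labels].sum())
        trace.append(wss)
        new_centers = centers.copy()
        for c in range(centers.shape[0]):
            mask = labels == c
            if mask.any():
                new_centers[c] = X[mask].mean(axis=0)
            else:  # empty cluster: seize the point farthest from its centroid
                far = int(d2[np.arange(X.shape[0]), labels].argmax())
                new_centers[c] = X[far]
        if len(trace) > 1 and trace[-2] - trace[-1] <= tol:
            centers = new_centers
            break
        centers = new_centers
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    wss = float(d2[np.arange(X.shape[0]), labels].sum())
    trace.append(wss)
    return labels, centers, wss, trace


def kmeans_profiles(
    m: pd.DataFrame,
    k: int,
    rng_seed: int,
    n_init: int = 10,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> ClusterAssignment:
    """Cluster z-scored feature x group profiles into k temporal clusters."""
    X = m.to_numpy(dtype=float)
    n_distinct = np.unique(X, axis=0).shape[0]
    if k < 1 or k > n_distinct:
        raise ParameterError(
            f"k={k} must lie in 1..{n_distinct} (number of distinct profiles)"
        )
    rng = np.random.default_rng(rng_seed)
    best = None
    for _ in range(n_init):
        centers0 = _kmeanspp_init(X, k, rng)
        labels, centers, wss, trace = _lloyd(X, centers0, max_iter, tol)
        if best is None or wss < best[2]:
            best = (labels, centers, wss, trace)
    labels, centers, wss, trace = best

    # renumber so cluster 1 peaks latest, cluster k earliest
    peaks = centers.argmax(axis=1)
    order = sorted(range(k), key=lambda c: (-peaks[c], c))
    relabel = {old: new + 1 for new, old in enumerate(order)}
    new_labels = pd.Series(
        [relabel[c] for c in labels], index=m.index, name="cluster"
    )
    centroids = pd.DataFrame(
        centers[order], index=range(1, k + 1), columns=m.columns
    )
    return ClusterAssignment(
        list(m.index), new_labels, centroids, k, wss, rng_seed, trace
    )


def pca_summary(m: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples over centered features.

    Parameters
    ----------
    m : DataFrame
        Feature x sample table.

    Returns
    -------
    scores : DataFrame
        Sample x component coordinates.
    fractions : ndarray
        Variance-explained fractions, descending, summing to 1.
    """
    if m.shape[1] < 2:
        raise ParameterError("PCA needs at least 2 samples")
    X = m.to_numpy(dtype=float).T  # samples x features
    X = X - X.mean(axis=0, keepdims=True)
    _u, s, vt = np.linalg.svd(X, full_matrices=False)
    n_comp = min(X.shape[0] - 1, X.shape[1])
    s = s[:n_comp]
    scores = X @ vt[:n_comp].T
    var = s**2
    total = var.sum()
    fractions = var / total if total > 0 else np.full(n_comp, 1.0 / max(n_comp, 1))
    cols = [f"PC{i + 1}" for i in range(n_comp)]
    return pd.DataFrame(scores[:, :n_comp], index=m.columns, columns=cols), fractions


def _linkage_to_newick(node, labels: list[str]) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _linkage_to_newick(node.left, labels)
    right = _linkage_to_newick(node.right, labels)
    h = node.dist / 2.0
    bl_left = h - (node.left.dist / 2.0)
    bl_right = h - (node.right.dist / 2.0)
    return f"({left}:{bl_left:.6g},{right}:{bl_right:.6g})"


def hca_dendrogram(
    m: pd.DataFrame, linkage: str = "complete", metric: str = "euclidean"
) -> str:
    """Hierarchical clustering of samples; returns the merge tree as newick.

    Parameters
    ----------
    m : DataFrame
        Sample x feature table (one row per sample).
    linkage : {"complete", "average"}
    metric : {"euclidean", "1-pearson"}
    """
    if linkage not in ("complete", "average"):
        raise ParameterError(f"unknown linkage {linkage!r}")
    if m.shape[0] < 2:
        raise ParameterError("HCA needs at least 2 samples")
    X = m.to_numpy(dtype=float)
    if metric == "euclidean":
        dist = pdist(X)
    elif metric == "1-pearson":
        dist = pdist(X, metric="correlation")
    else:
        raise ParameterError(f"unknown metric {metric!r}")
    Z = hierarchy.linkage(dist, method=linkage)
    tree = hierarchy.to_tree(Z)
    return _linkage_to_newick(tree, list(m.index)) + ";"


def match_clusters(
    gene_ca: ClusterAssignment, metab_ca: ClusterAssignment
) -> dict[int, tuple[int, float]]:
    """Optimal one-to-one pairing of gene and metabolite clusters.

    Maximises total Pearson correlation of matched centroid pairs
    (Hungarian assignment).  Returns gene-cluster -> (metabolite-cluster,
    centroid correlation).
    """
    if gene_ca.k != metab_ca.k:
        raise ParameterError("cluster counts differ between the two assignments")
    if list(gene_ca.centroids.columns) != list(metab_ca.centroids.columns):
        raise ParameterError("centroid group axes differ")
    k = gene_ca.k
    G = gene_ca.centroids.to_numpy(dtype=float)
    M = metab_ca.centroids.to_numpy(dtype=float)
    corr = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            gi, mj = G[i], M[j]
            if gi.std() == 0 or mj.std() == 0:
                corr[i, j] = 0.0
            else:
                corr[i, j] = np.corrcoef(gi, mj)[0, 1]
    rows, cols = linear_sum_assignment(-corr)
    return {
        int(gene_ca.centroids.index[r]): (int(metab_ca.centroids.index[c]), float(corr[r, c]))
        for r, c in zip(rows, cols)
    }
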