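"""Gene-mask fitness: K-means clustering quality traded against mask size.

A candidate gene subset ``S`` out of ``D`` highly variable genes is scored

    fitness(S) = w * SC(labels) + (1 - w) * (1 - |S| / D)

where ``SC`` is the mean silhouette coefficient of the K-means labels
computed on the cells x selected-genes submatrix and ``w`` (default 0.9)
weights clustering quality against parsimony.  An empty mask is
inadmissible and scores ``-inf``; a clustering that collapses to a single
cluster scores ``SC = -1`` so the mask is penalized rather than crashing
the search.

When the number of clusters K is unknown, :func:`estimate_k_louvain` infers
it by Louvain community detection on a k-nearest-neighbor graph.
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass

import igraph as ig
import numpy as np
from sklearn.metrics import silhouette_score
from sklearn.cluster import KMeans
from sklearn.neighbors import kneighbors_graph

from .io import ExpressionMatrix

__all__ = [
    "FitnessValue",
    "kmeans_cluster",
    "silhouette",
    "fitness",
    "combine_fitness",
    "estimate_k_louvain",
]

# K-means settings used for every mask evaluation: greedy k-means++ seeding,
# 5 restarts, 100 Lloyd iterations.
KMEANS_N_INIT = 5
KMEANS_MAX_ITER = 100


@dataclass(frozen=True)
class FitnessValue:
    """Score of one gene mask together with its clustering by-products."""

    value: float
    sc: float
    n_selected: int
    labels: np.ndarray | None


def _masked(expr: ExpressionMatrix, mask) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.size != expr.n_genes:
        raise ValueError(f"mask length {mask.size} != n_genes {expr.n_genes}")
    return expr.values[:, mask]


def kmeans_cluster(
    expr: ExpressionMatrix, mask, K: int, rng: np.random.Generator
) -> np.ndarray:
    """K-means labels on the masked expression submatrix."""
    x = _masked(expr, mask)
    if x.shape[1] == 0:
        raise ValueError("empty gene mask; nothing to cluster on")
    if K > expr.n_cells:
        raise ValueError(f"K={K} exceeds number of cells {expr.n_cells}")
    if K < 1:
        raise ValueError("K must be positive")
    seed = int(rng.integers(2**31 - 1))
    km = KMeans(
        n_clusters=K,
        n_init=KMEANS_N_INIT,
        max_iter=KMEANS_MAX_ITER,
        init="k-means++",
        random_state=seed,
    )
    return km.fit_predict(x)


def silhouette(x: np.ndarray, labels) -> float:
    """Mean silhouette coefficient over cells (Euclidean distances).

    Each cell scores (b - a)/max(a, b) with a the mean distance to its own
    cluster and b the smallest mean distance to another cluster; singleton
    clusters contribute 0.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette requires at least 2 distinct clusters")
    return float(silhouette_score(np.asarray(x, dtype=float), labels))


def combine_fitness(sc: float, n_selected: int, D: int, w: float) -> float:
    """The weighted quality/parsimony combination for an admissible mask."""
    return w * sc + (1.0 - w) * (1.0 - n_selected / D)


def fitness(
    expr: ExpressionMatrix,
    mask,
    K: int,
    w: float,
    rng: np.random.Generator,
) -> FitnessValue:
    """Score one gene mask; empty masks get the ``-inf`` sentinel."""
    mask = np.asarray(mask, dtype=bool)
    n_selected = int(mask.sum())
    if n_selected == 0:
        return FitnessValue(value=-np.inf, sc=np.nan, n_selected=0, labels=None)
    labels = kmeans_cluster(expr, mask, K, rng)
    if len(np.unique(labels)) < 2:
        sc = -1.0  # collapsed clustering: worst possible cohesion score
    else:
        sc = silhouette(_masked(expr, mask), labels)
    value = combine_fitness(sc, n_selected, expr.n_genes, w)
    return FitnessValue(value=value, sc=sc, n_selected=n_selected, labels=labels)


def estimate_k_louvain(
    expr: ExpressionMatrix,
    mask=None,
    n_neighbors: int = 15,
    seed: int = 0,
    resolution: float = 1.0,
) -> tuple[int, np.ndarray]:
    """Estimate the cluster count by Louvain on a kNN graph.

    Builds an unweighted symmetric Euclidean k-nearest-neighbor graph on the
    masked expression and maximizes modularity with the Louvain (multilevel)
    algorithm.  Returns the community count and per-cell labels.  If all
    cells are identical on the selected genes the graph carries no structure
    and a single community is returned.
    """
    if mask is None:
        mask = np.ones(expr.n_genes, dtype=bool)
    x = _masked(expr, mask)
    if x.shape[1] == 0:
        raise ValueError("empty gene mask")
    n = x.shape[0]
    if n_neighbors >= n:
        raise ValueError(f"n_neighbors={n_neighbors} must be < n_cells={n}")
    if np.all(x == x[0]):
        return 1, np.zeros(n, dtype=int)
    adj = kneighbors_graph(x, n_neighbors=n_neighbors, mode="connectivity")
    adj = adj.maximum(adj.T).tocoo()
    edges = [(int(i), int(j)) for i, j in zip(adj.row, adj.col) if i < j]
    graph = ig.Graph(n=n, edges=edges)
    ig.set_random_number_generator(_pyrandom.Random(seed))
    try:
        part = graph.community_multilevel(resolution=resolution)
    finally:
        ig.set_random_number_generator(_pyrandom)
    labels = np.asarray(part.membership, dtype=int)
    return int(labels.max()) + 1, labels
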