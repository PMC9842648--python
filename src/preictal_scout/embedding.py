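"""3-D embedding over a hyperparameter grid, multi-method clustering, and
Dunn's-Index model selection.

Each prepared feature matrix is reduced to 3-D with UMAP over a grid of
(n_neighbors, min_dist) pairs — ten equally spaced neighbour values in
[10, 100] and nine minimum distances 0.1..0.9 by default, 90 embeddings.
On every embedding ten clustering solutions are computed (k-means,
Ward-linkage agglomerative and full-covariance Gaussian mixtures for
k = 2, 3, 4, plus HDBSCAN), each scored with the classical Dunn's Index
(minimum single-linkage inter-cluster distance over maximum intra-cluster
diameter, density-method noise points excluded).  The grid-wide maximum
DI selects the final (embedding, solution); if no solution has a defined
DI a DBSCAN sweep over an epsilon grid is tried, and failing that a
single-cluster solution flagged ``unclustered`` is returned.

All stochastic steps (UMAP, k-means, GMM) derive from one seed, making
``select_best`` a pure function of (matrix, config, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import (DBSCAN, HDBSCAN, AgglomerativeClustering,
                             KMeans)
from sklearn.mixture import GaussianMixture
from sklearn.neighbors import NearestNeighbors


@dataclass
class EmbeddingConfig:
    """Hyperparameters of the embedding/clustering sweep."""

    n_neighbors_grid: tuple = tuple(range(10, 101, 10))
    min_dist_grid: tuple = tuple(np.round(np.arange(0.1, 0.95, 0.1), 1))
    output_dim: int = 3
    n_epochs: int = 200
    k_values: tuple = (2, 3, 4)
    hdbscan_min_cluster_size: int = 30
    dbscan_min_samples: int = 4
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_neighbors_grid or not self.min_dist_grid:
            raise ValueError("grids must be non-empty")
        if self.output_dim != 3:
            raise ValueError("output_dim is fixed at 3")


@dataclass
class ClusterSolution:
    """Labels (-1 = noise for density methods) with provenance and score."""

    labels: np.ndarray | None
    method: str
    embedding_params: tuple        # (n_neighbors, min_dist)
    dunn_index: float = np.nan     # NaN = undefined
    unclustered: bool = False

    @property
    def n_clusters(self) -> int:
        if self.labels is None:
            return 0
        return np.unique(self.labels[self.labels >= 0]).size


def dunn_index(points: np.ndarray, labels: np.ndarray,
               distances: np.ndarray | None = None) -> float:
    """Classical Dunn (1974) index.

    DI = (min over cluster pairs of the single-linkage inter-cluster
    Euclidean distance) / (max over clusters of the intra-cluster
    diameter).  Noise points (label -1) are excluded.  Undefined (NaN)
    unless there are >= 2 non-noise clusters each of size >= 2.

    ``distances`` may carry a precomputed square distance matrix for the
    full point set to avoid recomputation across solutions.
    """
    labels = np.asarray(labels)
    ids = [c for c in np.unique(labels) if c >= 0]
    sizes = [(labels == c).sum() for c in ids]
    if len(ids) < 2 or min(sizes) < 2:
        return np.nan
    if distances is None:
        distances = squareform(pdist(np.asarray(points, dtype=np.float64)))
    masks = [labels == c for c in ids]
    diam = max(distances[np.ix_(m, m)].max() for m in masks)
    inter = min(distances[np.ix_(mi, mj)].min()
                for a, mi in enumerate(masks) for mj in masks[a + 1:])
    if inter == 0:
        return 0.0
    if diam == 0:
        return np.inf
    return float(inter / diam)


def embed_grid(values: np.ndarray, config: EmbeddingConfig) -> list:
    """One 3-D embedding per (n_neighbors, min_dist) grid pair.

    Returns a list of ``((n_neighbors, min_dist), embedding)`` in grid
    order (neighbours outer, min_dist inner).  If the matrix has too few
    rows for the largest neighbour counts the neighbour grid is clipped,
    with a warning.
    """
    import umap

    x = np.asarray(values, dtype=np.float32)
    n = x.shape[0]
    nn_grid = [k for k in config.n_neighbors_grid if k <= n - 1]
    if len(nn_grid) < len(config.n_neighbors_grid):
        clipped = max(2, n - 1)
        if not nn_grid or nn_grid[-1] != clipped:
            nn_grid.append(clipped)
        warnings.warn(f"n_neighbors grid clipped to {nn_grid} for n={n}")
    out = []
    for nn in nn_grid:
        for md in config.min_dist_grid:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                emb = umap.UMAP(
                    n_components=config.output_dim, n_neighbors=nn,
                    min_dist=float(md), n_epochs=config.n_epochs,
                    random_state=config.rng_seed, n_jobs=1,
                ).fit_transform(x)
            out.append(((nn, float(md)), np.asarray(emb, dtype=np.float64)))
    return out


METHOD_ORDER = tuple(
    [f"kmeans_k{k}" for k in (2, 3, 4)]
    + [f"agglomerative_k{k}" for k in (2, 3, 4)]
    + [f"gmm_k{k}" for k in (2, 3, 4)]
    + ["hdbscan"]
)


def cluster_all(embedding: np.ndarray, params: tuple,
                config: EmbeddingConfig,
                distances: np.ndarray | None = None) -> list:
    """The ten clustering solutions for one embedding, each DI-scored.

    A method failure (non-convergence) is recorded as a solution with
    ``labels = None`` and undefined DI rather than aborting the sweep.
    """
    if distances is None:
        distances = squareform(pdist(embedding))
    seed = config.rng_seed
    solutions = []

    def run(method: str, fn):
        try:
            labels = np.asarray(fn())
            di = dunn_index(embedding, labels, distances)
        except Exception:
            labels, di = None, np.nan
        solutions.append(ClusterSolution(labels=labels, method=method,
                                         embedding_params=params,
                                         dunn_index=di))

    for k in config.k_values:
        run(f"kmeans_k{k}",
            lambda k=k: KMeans(n_clusters=k, n_init=10, random_state=seed
                               ).fit_predict(embedding))
    for k in config.k_values:
        run(f"agglomerative_k{k}",
            lambda k=k: AgglomerativeClustering(n_clusters=k, linkage="ward"
                                                ).fit_predict(embedding))
    for k in config.k_values:
        run(f"gmm_k{k}",
            lambda k=k: GaussianMixture(n_components=k,
                                        covariance_type="full",
                                        random_state=seed
                                        ).fit(embedding).predict(embedding))
    msize = min(config.hdbscan_min_cluster_size, max(embedding.shape[0] - 1, 2))
    run("hdbscan", lambda: HDBSCAN(min_cluster_size=msize
                                   ).fit_predict(embedding))
    return solutions


def _dbscan_fallback(embeddings: list, config: EmbeddingConfig) -> list:
    """DBSCAN sweep used when no primary solution has a defined DI: for
    each embedding, 10 epsilon values between the 1st and 50th percentile
    of 4-nearest-neighbour distances."""
    out = []
    for params, emb in embeddings:
        nn = NearestNeighbors(n_neighbors=config.dbscan_min_samples + 1
                              ).fit(emb)
        d4 = nn.kneighbors(emb)[0][:, -1]
        eps_grid = np.percentile(d4, np.linspace(1, 50, 10))
        distances = squareform(pdist(emb))
        for eps in eps_grid:
            if eps <= 0:
                continue
            labels = DBSCAN(eps=float(eps),
                            min_samples=config.dbscan_min_samples
                            ).fit_predict(emb)
            out.append((params, emb, ClusterSolution(
                labels=labels, method=f"dbscan_eps{eps:.4g}",
                embedding_params=params,
                dunn_index=dunn_index(emb, labels, distances))))
    return out


def select_best(grid_results: list, config: EmbeddingConfig,
                embeddings: list | None = None) -> tuple:
    """Pick the (embedding, solution) with maximal Dunn's Index.

    ``grid_results`` is a list of ``(params, embedding, [solutions])`` in
    grid order; ties keep the first in (grid order, method order).  When
    no solution has a defined DI, a DBSCAN epsilon sweep re-selects; if
    that also fails, the first embedding is returned with a single-cluster
    solution flagged ``unclustered``.
    """
    best = None
    for params, emb, sols in grid_results:
        for sol in sols:
            if np.isnan(sol.dunn_index):
                continue
            if best is None or sol.dunn_index > best[2].dunn_index:
                best = (params, emb, sol)
    if best is not None:
        return best[1], best[2]

    if embeddings is None:
        embeddings = [(params, emb) for params, emb, _ in grid_results]
    fb = _dbscan_fallback(embeddings, config)
    for params, emb, sol in fb:
        if np.isnan(sol.dunn_index):
            continue
        if best is None or sol.dunn_index > best[2].dunn_index:
            best = (params, emb, sol)
    if best is not None:
        return best[1], best[2]

    params, emb = embeddings[0]
    n = emb.shape[0]
    return emb, ClusterSolution(labels=np.zeros(n, dtype=int),
                                method="unclustered",
                                embedding_params=params,
                                dunn_index=np.nan, unclustered=True)


def embed_and_select(values: np.ndarray, config: EmbeddingConfig) -> tuple:
    """Full sweep: embed over the grid, cluster each embedding, select by
    maximum DI.  Returns ``(embedding, ClusterSolution)``."""
    embeddings = embed_grid(values, config)
    results = []
    for params, emb in embeddings:
        distances = squareform(pdist(emb))
        results.append((params, emb,
                        cluster_all(emb, params, config, distances)))
    return select_best(results, config, embeddings)
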