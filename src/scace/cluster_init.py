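"""Initial clustering of the latent embedding.

De novo initialization runs Leiden (or Louvain) community detection on a
k-nearest-neighbour graph of the embedding at a deliberately high resolution,
producing many small, high-purity clusters that the adaptive merge loop later
collapses.  Enhancement mode instead refines externally supplied labels by
recursive bi-partitioning of clusters that are too spread out.

Note: the recursive 2-means splitting rule used by ``split_clusters`` is a
reconstruction (the criterion is only characterized as being driven by
intra-cluster distances); it is isolated here so it can be swapped out.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from sklearn.neighbors import NearestNeighbors

from .zinb_vae import Embedding


@dataclass
class ClusterState:
    """Labels in 0..K-1, centroids (latent_dim x K) and cluster count K."""

    labels: np.ndarray
    centroids: np.ndarray
    K: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.centroids = np.asarray(self.centroids, dtype=np.float64)
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.centroids.shape[1] != self.K:
            raise ValueError("centroids must have K columns")
        counts = np.bincount(self.labels, minlength=self.K)
        if self.labels.min(initial=0) < 0 or self.labels.max(initial=0) >= self.K:
            raise ValueError("labels out of range 0..K-1")
        if np.any(counts == 0):
            raise ValueError("every cluster id in 0..K-1 must have >= 1 member")


def _z_of(emb) -> np.ndarray:
    """Accept an Embedding or a latent_dim x n array; return cells x d."""
    z = emb.z if isinstance(emb, Embedding) else np.asarray(emb, dtype=np.float64)
    return np.ascontiguousarray(z.T)


def canonicalize_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel cluster ids by first occurrence order to 0..K-1."""
    labels = np.asarray(labels)
    mapping: dict[int, int] = {}
    out = np.empty(labels.shape, dtype=np.int64)
    for j, v in enumerate(labels):
        out[j] = mapping.setdefault(int(v), len(mapping))
    return out


def compute_centroids(emb, labels: np.ndarray) -> np.ndarray:
    """Per-cluster Euclidean centers of the embedding, latent_dim x K."""
    zc = _z_of(emb)
    labels = np.asarray(labels, dtype=np.int64)
    K = int(labels.max()) + 1
    counts = np.bincount(labels, minlength=K)
    if np.any(counts == 0):
        raise ValueError("empty cluster id in labels")
    sums = np.zeros((K, zc.shape[1]))
    np.add.at(sums, labels, zc)
    return (sums / counts[:, None]).T


def _state_from_labels(emb, labels: np.ndarray) -> ClusterState:
    labels = canonicalize_labels(labels)
    cents = compute_centroids(emb, labels)
    return ClusterState(labels=labels, centroids=cents, K=cents.shape[1])


def knn_graph(z_cells: np.ndarray, n_neighbors: int):
    """Undirected kNN graph (Euclidean) as an igraph Graph."""
    import igraph

    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(z_cells)
    _, idx = nn.kneighbors(z_cells)
    edges = set()
    for i in range(z_cells.shape[0]):
        for j in idx[i, 1:]:
            edges.add((min(i, int(j)), max(i, int(j))))
    g = igraph.Graph(n=z_cells.shape[0], edges=sorted(edges))
    return g


def leiden_init(
    emb,
    resolution: float = 2.0,
    n_neighbors: int = 15,
    seed: int = 0,
    flavor: str = "leiden",
) -> ClusterState:
    """Community detection on the kNN graph of the embedding.

    ``flavor`` may be ``"leiden"`` (default) or ``"louvain"`` (drop-in
    alternative, run via igraph multilevel on the same graph).
    """
    zc = _z_of(emb)
    n = zc.shape[0]
    if n < n_neighbors + 1:
        raise ValueError("need at least n_neighbors + 1 cells")
    if np.allclose(zc, zc[0]):
        warnings.warn("degenerate embedding (all cells identical): single cluster")
        return _state_from_labels(emb, np.zeros(n, dtype=np.int64))
    g = knn_graph(zc, n_neighbors)
    if flavor == "leiden":
        import leidenalg

        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=resolution,
            seed=seed,
            n_iterations=2,
        )
        labels = np.asarray(part.membership)
    elif flavor == "louvain":
        rng = np.random.default_rng(seed)
        import igraph

        igraph.set_random_number_generator(_IgraphRNG(rng))
        part = g.community_multilevel(resolution=resolution)
        labels = np.asarray(part.membership)
    else:
        raise ValueError(f"unknown flavor {flavor!r}")
    return _state_from_labels(emb, labels)


class _IgraphRNG:
    """Adapter exposing a numpy Generator to igraph's RNG interface."""

    def __init__(self, rng: np.random.Generator):
        self._rng = rng

    def random(self):
        return float(self._rng.random())

    def randint(self, a, b=None):
        if b is None:
            a, b = 0, a
        return int(self._rng.integers(a, b))

    def gauss(self, mu, sigma):
        return float(self._rng.normal(mu, sigma))


def kmeans_init(emb, k_min: int = 15, k_max: int = 30, seed: int = 0) -> ClusterState:
    """K-means over a range of K; keep the K maximizing the silhouette."""
    if k_min < 2 or k_max < k_min:
        raise ValueError("need 2 <= k_min <= k_max")
    zc = _z_of(emb)
    if zc.shape[0] <= k_max:
        raise ValueError("need more cells than k_max")
    best = None
    for k in range(k_min, k_max + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(zc)
        labels = km.labels_
        if len(np.unique(labels)) < 2:
            continue
        try:
            score = silhouette_score(zc, labels)
        except ValueError:
            continue
        if best is None or score > best[0]:
            best = (score, labels)
    if best is None:
        raise ValueError("silhouette undefined for every candidate K")
    return _state_from_labels(emb, best[1])


def intra_cluster_distance(z_cells: np.ndarray, member_idx: np.ndarray) -> float:
    """Mean Euclidean distance of members to their centroid."""
    pts = z_cells[member_idx]
    c = pts.mean(axis=0)
    return float(np.linalg.norm(pts - c, axis=1).mean())


def split_clusters(
    emb,
    external_labels: np.ndarray,
    seed: int = 0,
    min_split_size: int = 20,
) -> ClusterState:
    """Refine external labels by recursively bi-partitioning loose clusters.

    A cluster whose intra-cluster distance exceeds the mean intra-cluster
    distance across the input clusters is split by 2-means on the embedding;
    splitting recurses until every leaf is at or below that threshold or
    smaller than ``min_split_size``.  A split that would shave off a tiny
    fragment (fewer than ``min_split_size // 2`` cells, at least 2) is
    rejected: degenerate near-singleton clusters have near-zero intra
    distance, which would skew the merge criterion's weights downstream.
    Output labels always refine the input (each output cluster is a subset
    of one input cluster).
    """
    zc = _z_of(emb)
    labels = canonicalize_labels(external_labels)
    if labels.shape[0] != zc.shape[0]:
        raise ValueError("external_labels must cover all cells")
    K_in = int(labels.max()) + 1
    intra = np.array(
        [intra_cluster_distance(zc, np.flatnonzero(labels == k)) for k in range(K_in)]
    )
    # tiny relative slack so clusters exactly at the mean never split on
    # floating-point noise
    threshold = float(intra.mean()) * (1.0 + 1e-9)

    rng = np.random.default_rng(seed)
    out = np.full(labels.shape[0], -1, dtype=np.int64)
    next_id = 0
    for k in range(K_in):
        stack = [np.flatnonzero(labels == k)]
        while stack:
            idx = stack.pop()
            if (
                idx.size < max(min_split_size, 2)
                or intra_cluster_distance(zc, idx) <= threshold
            ):
                out[idx] = next_id
                next_id += 1
                continue
            km = KMeans(n_clusters=2, n_init=5, random_state=int(rng.integers(2**31))).fit(
                zc[idx]
            )
            part = km.labels_
            min_leaf = max(2, min_split_size // 2)
            sizes = np.bincount(part, minlength=2)
            if sizes.min() < min_leaf:  # degenerate or shaving split: keep leaf
                out[idx] = next_id
                next_id += 1
                continue
            stack.append(idx[part == 1])
            stack.append(idx[part == 0])
    return _state_from_labels(emb, out)
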