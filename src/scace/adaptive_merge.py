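"""Alternating network update and data-adaptive cluster merging.

The merge loop compares, for every cluster pair, a size-corrected
inter-centroid distance ``w_ij * d_ij_inter`` against half the weighted mean
pairwise distance ``d_bar / 2``; qualifying pairs are merged smallest first,
distances are recomputed after every merge, and the outer loop alternates
merge passes with DEC-style network updates until a merge pass performs no
merge.  From a two-cluster state no merge can ever fire: with a single pair
``d_bar`` equals that pair's weighted distance, which cannot be below half of
itself, so the method never collapses to K = 1 from K = 2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .cluster_init import (
    ClusterState,
    canonicalize_labels,
    compute_centroids,
    leiden_init,
    split_clusters,
    _z_of,
)
from .data_io import CountMatrix, NormalizedMatrix, preprocess, read_counts, read_labels
from .zinb_vae import (
    Adam,
    Embedding,
    TrainingDivergedError,
    VAEModel,
    _forward_backward,
    encode,
    pretrain,
)

logger = logging.getLogger("scace")


def soft_assign(emb, centroids: np.ndarray) -> np.ndarray:
    """Student-t kernel soft assignment of cells to centroids, n x K.

    ``q[i, j] = (1 + ||z_i - c_j||^2)^-1`` normalized over ``j``.
    """
    zc = _z_of(emb)  # (n, d)
    C = np.asarray(centroids, dtype=np.float64).T  # (K, d)
    if not np.all(np.isfinite(zc)):
        raise ValueError("non-finite embedding")
    d2 = ((zc[:, None, :] - C[None, :, :]) ** 2).sum(-1)
    q = 1.0 / (1.0 + d2)
    return q / q.sum(1, keepdims=True)


def target_distribution(q: np.ndarray) -> np.ndarray:
    """Sharpened auxiliary target: square q and correct for cluster frequency."""
    q = np.asarray(q, dtype=np.float64)
    f = q.sum(0)
    if np.any(f == 0):
        raise ValueError("cluster with zero total soft mass")
    num = q * q / f
    return num / num.sum(1, keepdims=True)


def clustering_kl_loss(p: np.ndarray, q: np.ndarray) -> float:
    """KL(p || q) summed over cells, with 0 * log 0 == 0."""
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if p.shape != q.shape:
        raise ValueError("p and q must have matching shapes")
    mask = p > 0
    return float(np.sum(p[mask] * (np.log(p[mask]) - np.log(q[mask]))))


@dataclass
class MergePlan:
    """Distances, weights and the selected pair for one merge decision."""

    d_intra: np.ndarray
    d_inter: np.ndarray
    w: np.ndarray
    d_bar: float
    candidate_pairs: list[tuple[int, int, float]]
    selected_pair: Optional[tuple[int, int]]


def build_merge_plan(emb, state: ClusterState) -> MergePlan:
    """Evaluate the adaptive merge criterion on fresh centroids.

    ``d_intra[i]`` is the mean member-to-centroid distance of cluster ``i``;
    ``d_inter[i, j]`` the centroid-to-centroid distance; the weight
    ``w[i, j] = mean(d_intra) / (0.5 * (d_intra[i] + d_intra[j]))`` corrects
    for cluster spread; ``d_bar`` is the mean of ``w * d_inter`` over pairs.
    Candidates satisfy ``w_ij * d_inter_ij < d_bar / 2``; the pair with the
    smallest weighted distance is selected (lexicographic tie-break).
    """
    if state.K < 2:
        raise ValueError("need K >= 2 to evaluate merges")
    zc = _z_of(emb)
    labels = state.labels
    K = state.K
    cents = compute_centroids(emb, labels)  # (d, K), fresh per contract
    C = cents.T
    d_intra = np.empty(K)
    for k in range(K):
        pts = zc[labels == k]
        d_intra[k] = np.linalg.norm(pts - C[k], axis=1).mean()
    d_inter = np.sqrt(((C[:, None, :] - C[None, :, :]) ** 2).sum(-1))
    mean_intra = d_intra.mean()
    with np.errstate(divide="ignore"):
        w = mean_intra / (0.5 * (d_intra[:, None] + d_intra[None, :]))
    np.fill_diagonal(w, 0.0)
    iu, ju = np.triu_indices(K, k=1)
    weighted = w[iu, ju] * d_inter[iu, ju]
    d_bar = float(weighted.mean())
    cand_mask = weighted < d_bar / 2.0
    candidate_pairs = [
        (int(i), int(j), float(wd)) for i, j, wd in zip(iu[cand_mask], ju[cand_mask], weighted[cand_mask])
    ]
    selected = None
    if candidate_pairs:
        selected = min(candidate_pairs, key=lambda t: (t[2], t[0], t[1]))[:2]
    return MergePlan(
        d_intra=d_intra,
        d_inter=d_inter,
        w=w,
        d_bar=d_bar,
        candidate_pairs=candidate_pairs,
        selected_pair=selected,
    )


def apply_merge(emb, state: ClusterState, pair: tuple[int, int]) -> ClusterState:
    """Union two clusters; the merged centroid is the member mean; relabel."""
    i, j = pair
    if not (0 <= i < state.K and 0 <= j < state.K and i != j):
        raise ValueError(f"invalid merge pair {pair}")
    labels = state.labels.copy()
    labels[labels == j] = i
    labels = canonicalize_labels(labels)
    cents = compute_centroids(emb, labels)
    return ClusterState(labels=labels, centroids=cents, K=cents.shape[1])


def assign_to_nearest_centroid(emb, state: ClusterState) -> ClusterState:
    """Reassign every cell to its closest centroid; drop emptied clusters."""
    zc = _z_of(emb)
    C = state.centroids.T
    d2 = ((zc[:, None, :] - C[None, :, :]) ** 2).sum(-1)
    labels = d2.argmin(1)
    if len(np.unique(labels)) < state.K:
        logger.info("dropping %d emptied cluster(s) after reassignment",
                    state.K - len(np.unique(labels)))
    labels = canonicalize_labels(labels)
    cents = compute_centroids(emb, labels)
    return ClusterState(labels=labels, centroids=cents, K=cents.shape[1])


def merge_until_stable(emb, state: ClusterState) -> tuple[ClusterState, int]:
    """Nearest-centroid reassignment, then merge until no pair qualifies.

    Returns the stable state and the number of merges performed.  Terminates
    after at most ``K0 - 2`` merges since the criterion is unsatisfiable at
    K = 2.
    """
    state = assign_to_nearest_centroid(emb, state)
    n_merges = 0
    while state.K >= 2:
        plan = build_merge_plan(emb, state)
        if plan.selected_pair is None:
            break
        state = apply_merge(emb, state, plan.selected_pair)
        n_merges += 1
    return state, n_merges


@dataclass
class ScaceConfig:
    """Hyperparameters of the full pipeline; defaults follow the method."""

    latent_dim: int = 32
    encoder_hidden_width: int = 512
    decoder_hidden_width: int = 512
    resolution: float = 2.0
    n_neighbors: int = 15
    init_flavor: str = "leiden"  # leiden | louvain | kmeans
    kmeans_k_range: tuple[int, int] = (15, 30)
    lambda_: float = 1.0
    tol_fraction: float = 0.05
    pretrain_epochs: int = 30
    pretrain_lr: float = 1e-3
    merge_lr: float = 1e-4
    batch_size: int = 256
    beta_pretrain_scale: float = 0.001  # beta = scale * n_genes
    beta_merge_scale: float = 0.01
    min_cells_per_gene: int = 1
    target_sum: float = 1e4
    n_top_genes: Optional[int] = None
    min_split_size: int = 20
    max_iterations: int = 10
    max_update_repeats: int = 10
    seed: int = 0


def network_update(
    model: VAEModel,
    counts: CountMatrix,
    x_norm: NormalizedMatrix,
    state: ClusterState,
    lambda_: float = 1.0,
    tol_fraction: float = 0.05,
    beta: Optional[float] = None,
    lr: float = 1e-4,
    batch_size: int = 256,
    max_repeats: int = 10,
    seed: int = 0,
) -> tuple[VAEModel, Embedding, ClusterState, list[dict]]:
    """DEC-style refinement of network weights, centroids and labels.

    Each repeat freezes the target distribution ``p``, runs one epoch of
    gradient updates on ``L_VAE + lambda * L_C`` (centroids trainable), then
    reassigns labels to the argmax of the recomputed soft assignment;
    repeats stop once fewer than ``tol_fraction`` of cells change label.
    Centroids are re-centered on cluster means at repeat boundaries.
    """
    m = counts.n_genes
    beta = 0.01 * m if beta is None else beta
    rng = np.random.default_rng(seed)
    Xc = np.ascontiguousarray(counts.counts.T, dtype=np.float64)
    Xn = np.ascontiguousarray(x_norm.values.T, dtype=np.float32)
    sf = x_norm.size_factors
    n = Xc.shape[0]
    d = model.latent_dim

    labels = state.labels.copy()
    # model.params is the live dict: Adam rebinds its entries in place, so
    # the encoder/decoder weights actually train alongside the centroids
    trainables = model.params
    trainables["centroids"] = state.centroids.T.copy()  # (K, d)
    opt = Adam(trainables, lr=lr)

    history: list[dict] = []
    emb = encode(model, x_norm)
    for repeat in range(max_repeats):
        C = trainables["centroids"]
        q = soft_assign(emb, C.T)
        p = target_distribution(q)

        order = rng.permutation(n)
        tot = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            eps = rng.standard_normal((idx.size, d))
            total, nll, kl, lc, grads = _forward_backward(
                model.params,
                Xc[idx],
                Xn[idx],
                sf[idx],
                eps,
                beta,
                P=p[idx],
                centroids=trainables["centroids"],
                lambda_=lambda_,
            )
            if not math.isfinite(total):
                raise TrainingDivergedError(
                    f"network update diverged at repeat {repeat}: loss={total}"
                )
            grads["centroids"] = grads.pop("centroids")
            opt.step(trainables, grads)
            tot += total * idx.size / n

        emb = encode(model, x_norm)
        q = soft_assign(emb, trainables["centroids"].T)
        new_labels = q.argmax(1)
        changed = float(np.mean(new_labels != labels))
        labels = new_labels

        # drop emptied clusters, re-canonicalize, re-center on cluster means
        present = np.unique(labels)
        if present.size < trainables["centroids"].shape[0]:
            logger.info("dropping %d emptied cluster(s) during network update",
                        trainables["centroids"].shape[0] - present.size)
        labels = canonicalize_labels(labels)
        cents = compute_centroids(emb, labels)
        trainables["centroids"] = cents.T.copy()
        # optimizer state persists across repeats; only the (possibly resized,
        # re-centered) centroid slot is reinitialized
        opt.reset_slot("centroids", trainables["centroids"])

        history.append(dict(repeat=repeat, loss=tot, label_change=changed))
        if changed < tol_fraction:
            break

    model.params.pop("centroids", None)
    cents = compute_centroids(emb, labels)
    new_state = ClusterState(labels=labels, centroids=cents, K=cents.shape[1])
    return model, emb, new_state, history


@dataclass
class ScaceResult:
    labels: np.ndarray
    embedding: np.ndarray  # latent_dim x n
    history: list[dict]
    cell_ids: list[str] = field(default_factory=list)
    model: Optional[VAEModel] = None
    state: Optional[ClusterState] = None


def run_scace(
    counts: Union[str, CountMatrix],
    mode: str = "de_novo",
    external_labels: Optional[Union[str, np.ndarray]] = None,
    config: Optional[ScaceConfig] = None,
) -> ScaceResult:
    """Full pipeline: preprocess, pretrain, initialize, alternate
    network updates with adaptive merging until a merge pass is empty.

    ``counts`` may be a file path or an in-memory :class:`CountMatrix`;
    ``external_labels`` (enhancement mode) a path to a two-column file or a
    label vector aligned with the cells.
    """
    cfg = config or ScaceConfig()
    if mode not in ("de_novo", "enhance"):
        raise ValueError(f"unknown mode {mode!r}")

    stage = "read_counts"
    try:
        raw = read_counts(counts) if isinstance(counts, str) else counts

        stage = "preprocess"
        filtered, x_norm = preprocess(
            raw,
            min_cells_per_gene=cfg.min_cells_per_gene,
            target_sum=cfg.target_sum,
            n_top_genes=cfg.n_top_genes,
        )

        stage = "pretrain"
        model = VAEModel(
            n_genes=filtered.n_genes,
            encoder_hidden_width=cfg.encoder_hidden_width,
            latent_dim=cfg.latent_dim,
            decoder_hidden_width=cfg.decoder_hidden_width,
            seed=cfg.seed,
        )
        pretrain(
            model,
            filtered,
            x_norm,
            epochs=cfg.pretrain_epochs,
            seed=cfg.seed,
            lr=cfg.pretrain_lr,
            batch_size=cfg.batch_size,
            beta=cfg.beta_pretrain_scale * filtered.n_genes,
        )
        emb = encode(model, x_norm)

        stage = "cluster_init"
        if mode == "enhance":
            if external_labels is None:
                raise ValueError("enhance mode requires external labels")
            if isinstance(external_labels, str):
                ext = read_labels(external_labels, filtered.cell_ids)
            else:
                ext = np.asarray(external_labels)
            state = split_clusters(emb, ext, seed=cfg.seed, min_split_size=cfg.min_split_size)
        elif cfg.init_flavor == "kmeans":
            from .cluster_init import kmeans_init

            state = kmeans_init(emb, *cfg.kmeans_k_range, seed=cfg.seed)
        else:
            state = leiden_init(
                emb,
                resolution=cfg.resolution,
                n_neighbors=cfg.n_neighbors,
                seed=cfg.seed,
                flavor=cfg.init_flavor,
            )

        history: list[dict] = [
            dict(iteration=0, event="init", K=state.K, n_merges=None, label_change=None)
        ]
        logger.info("initial clustering: K=%d", state.K)

        beta_merge = cfg.beta_merge_scale * filtered.n_genes
        stage = "adaptive_merge"
        for it in range(1, cfg.max_iterations + 1):
            model, emb, state, upd_hist = network_update(
                model,
                filtered,
                x_norm,
                state,
                lambda_=cfg.lambda_,
                tol_fraction=cfg.tol_fraction,
                beta=beta_merge,
                lr=cfg.merge_lr,
                batch_size=cfg.batch_size,
                max_repeats=cfg.max_update_repeats,
                seed=cfg.seed + it,
            )
            state, n_merges = merge_until_stable(emb, state)
            history.append(
                dict(
                    iteration=it,
                    event="update+merge",
                    K=state.K,
                    n_merges=n_merges,
                    label_change=upd_hist[-1]["label_change"] if upd_hist else None,
                    loss=upd_hist[-1]["loss"] if upd_hist else None,
                )
            )
            logger.info("iteration %d: K=%d after %d merge(s)", it, state.K, n_merges)
            if n_merges == 0:
                break

        return ScaceResult(
            labels=state.labels.copy(),
            embedding=emb.z.copy(),
            history=history,
            cell_ids=list(filtered.cell_ids),
            model=model,
            state=state,
        )
    except Exception as exc:
        exc.add_note(f"[scace stage: {stage}]")
        raise
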