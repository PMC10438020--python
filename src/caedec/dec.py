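"""Deep embedded clustering layer and joint training loop.

The clustering layer measures similarity between an embedded point
z_k and a centroid c_m with a Student-t kernel,

    q_km = (1 + ||z_k - c_m||^2 / alpha)^(-(alpha+1)/2) / (normalizer),

sharpens Q into a frequency-normalized target distribution

    p_km = (q_km^2 / f_m) / sum_i (q_ki^2 / f_i),   f_m = sum_k q_km,

and minimizes KL(P || Q) jointly with the autoencoder's reconstruction
loss, L_t = L_r + C * L_c.  Centroids are initialized by spectral
clustering of the pretrained latent space (cluster means as centroid
estimators) and are themselves trainable parameters.  Reconstruction
gradients flow through encoder and decoder; clustering gradients flow
through encoder and centroids only (the decoder never sees Q).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import SpectralClustering

from .nn import Adam, CAEModel, DivergenceError, reconstruction_loss

__all__ = [
    "ClusterState",
    "TrainConfig",
    "TrainResult",
    "soft_assign",
    "target_distribution",
    "clustering_loss",
    "total_loss",
    "clustering_grads",
    "spectral_init",
    "assign_labels",
    "train_caedec",
]


# ---------------------------------------------------------------------------
# the clustering-layer math


def soft_assign(z: np.ndarray, centroids: np.ndarray, alpha: float = 1.0) -> np.ndarray:
    """Student-t soft assignment of embedded points to centroids.

    Rows sum to 1; all entries lie in (0, 1].  With alpha=1 each
    unnormalized weight reduces to 1 / (1 + ||z_k - c_m||^2).
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    c = np.atleast_2d(np.asarray(centroids, dtype=float))
    if c.shape[0] == 0:
        raise ValueError("need at least one centroid")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    d2 = np.sum((z[:, None, :] - c[None, :, :]) ** 2, axis=2)
    w = (1.0 + d2 / alpha) ** (-(alpha + 1.0) / 2.0)
    return w / w.sum(axis=1, keepdims=True)


def target_distribution(q: np.ndarray) -> np.ndarray:
    """Sharpened, cluster-frequency-normalized target distribution P."""
    q = np.atleast_2d(np.asarray(q, dtype=float))
    if q.size == 0:
        raise ValueError("empty assignment matrix")
    f = q.sum(axis=0)
    num = q**2 / f
    return num / num.sum(axis=1, keepdims=True)


def clustering_loss(p: np.ndarray, q: np.ndarray, reduction: str = "sum") -> float:
    """KL(P || Q) with natural logs; 0*log(0/q) = 0.

    ``reduction='sum'`` is the plain double sum over records and
    clusters; ``'mean'`` divides by the number of records (the scale
    used during training so the balance coefficient is n-free).
    """
    p = np.atleast_2d(np.asarray(p, dtype=float))
    q = np.atleast_2d(np.asarray(q, dtype=float))
    if p.shape != q.shape:
        raise ValueError("P and Q must share a shape")
    mask = p > 0
    if np.any(q[mask] == 0):
        raise ValueError("q is zero where p is positive: KL divergence is infinite")
    val = float(np.sum(p[mask] * np.log(p[mask] / q[mask])))
    val = max(val, 0.0)  # clip the tiny negative round-off at P ~= Q
    if reduction == "mean":
        val /= p.shape[0]
    return val


def total_loss(l_r: float, l_c: float, c: float) -> float:
    """Joint objective L_t = L_r + C * L_c."""
    if c < 0:
        raise ValueError("balance coefficient must be non-negative")
    return l_r + c * l_c


def clustering_grads(
    z: np.ndarray,
    centroids: np.ndarray,
    p: np.ndarray,
    alpha: float = 1.0,
    reduction: str = "mean",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Analytic gradients of KL(P || Q) wrt embeddings and centroids.

    dL/dz_k =  (alpha+1)/alpha * sum_m (p_km - q_km) u_km^-1 (z_k - c_m)
    dL/dc_m = -(alpha+1)/alpha * sum_k (p_km - q_km) u_km^-1 (z_k - c_m)

    with u_km = 1 + ||z_k - c_m||^2 / alpha.  Returns (dZ, dC, Q).
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    c = np.atleast_2d(np.asarray(centroids, dtype=float))
    diff = z[:, None, :] - c[None, :, :]
    u = 1.0 + np.sum(diff**2, axis=2) / alpha
    w = u ** (-(alpha + 1.0) / 2.0)
    q = w / w.sum(axis=1, keepdims=True)
    coef = (alpha + 1.0) / alpha * (p - q) / u  # (n, m)
    gz = np.einsum("km,kmd->kd", coef, diff)
    gc = -np.einsum("km,kmd->md", coef, diff)
    if reduction == "mean":
        gz /= len(z)
        gc /= len(z)
    return gz, gc, q


def assign_labels(q: np.ndarray) -> np.ndarray:
    """Hard labels: argmax over clusters, ties to the lowest index."""
    return np.argmax(np.atleast_2d(q), axis=1)


# ---------------------------------------------------------------------------
# centroid initialization


def spectral_init(
    z: np.ndarray,
    n_clusters: int,
    sample_size: int = 5000,
    seed: int = 0,
    n_neighbors: int = 30,
) -> np.ndarray:
    """Spectral-clustering centroid initialization.

    Runs spectral clustering (k-nearest-neighbour affinity, normalized
    Laplacian) on a random subsample of the latent space and returns
    the mean latent vector of each spectral cluster.  Categorical
    records embed to exactly coincident latent points, which fragments
    a nearest-neighbour graph, so the subsample is deduplicated first
    and each distinct point carries its multiplicity into the centroid
    mean.  Reproducible for a fixed seed.
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    if n_clusters < 1:
        raise ValueError("need at least one cluster")
    distinct = np.unique(z, axis=0)
    if n_clusters > len(distinct):
        raise ValueError(
            f"{n_clusters} clusters requested but only {len(distinct)} distinct points"
        )
    if n_clusters == 1:
        return z.mean(axis=0, keepdims=True)

    rng = np.random.default_rng(seed)
    if len(z) > sample_size:
        sub = z[rng.choice(len(z), size=sample_size, replace=False)]
    else:
        sub = z
    uniq, counts = np.unique(sub, axis=0, return_counts=True)
    if len(uniq) <= n_clusters:
        # degenerate subsample: the distinct points are the clusters
        return uniq[:n_clusters]

    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # kNN graph connectivity warnings
        sc = SpectralClustering(
            n_clusters=n_clusters,
            affinity="nearest_neighbors",
            n_neighbors=min(n_neighbors, len(uniq) - 1),
            assign_labels="kmeans",
            random_state=seed,
        )
        labels = sc.fit_predict(uniq)
    return np.stack([
        np.average(uniq[labels == m], axis=0, weights=counts[labels == m])
        for m in range(n_clusters)
    ])


# ---------------------------------------------------------------------------
# joint training


@dataclass(frozen=True)
class TrainConfig:
    """Joint-training hyperparameters.

    ``max_iter`` (the iteration cap) and ``p_update_interval`` (epochs
    between target-distribution refreshes) default to 3000 and 5, the
    values found stable in practice; ``balance`` is the coefficient C
    weighting the clustering loss; ``tol`` stops training once the
    fraction of records changing hard label between consecutive target
    updates falls below it.
    """

    n_clusters: int
    balance: float = 0.1
    max_iter: int = 3000
    p_update_interval: int = 5
    tol: float = 0.001
    alpha: float = 1.0
    learning_rate: float = 1e-3
    batch_size: int = 256
    init_sample_size: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iter < 1 or self.p_update_interval < 1:
            raise ValueError("max_iter and p_update_interval must be >= 1")
        if self.balance < 0:
            raise ValueError("balance coefficient C must be >= 0")
        if self.n_clusters < 1:
            raise ValueError("need at least one cluster")


@dataclass
class ClusterState:
    """Centroids, soft assignment Q, target P and hard labels."""

    centroids: np.ndarray
    q: np.ndarray
    p: np.ndarray
    labels: np.ndarray
    alpha: float = 1.0


@dataclass
class TrainResult:
    latent: np.ndarray
    labels: np.ndarray
    state: ClusterState
    loss_total: np.ndarray
    loss_recon: np.ndarray
    loss_cluster: np.ndarray
    n_epochs: int
    initial_centroids: np.ndarray
    initial_labels: np.ndarray
    empty_clusters: tuple[int, ...]
    stopped_early: bool


def train_caedec(
    x: np.ndarray, pretrained: CAEModel, cfg: TrainConfig
) -> TrainResult:
    """Joint optimization of reconstruction and clustering losses.

    Builds the initial latent space with the pretrained autoencoder,
    initializes centroids by spectral clustering, then iterates up to
    ``cfg.max_iter`` epochs: the target distribution P is recomputed
    every ``cfg.p_update_interval`` epochs (and held fixed in between)
    while every epoch updates weights, biases and centroids by a
    gradient step on L_t = L_r + C*L_c.  Training stops early once the
    hard labelling stabilizes; final labels are the argmax of the last
    optimized Q.  An empty cluster at termination is reported in the
    result, not raised.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    model = pretrained

    z0 = model.encode(x)
    centroids = spectral_init(
        z0, cfg.n_clusters, sample_size=cfg.init_sample_size, seed=cfg.seed
    ).copy()
    init_centroids = centroids.copy()
    q = soft_assign(z0, centroids, cfg.alpha)
    p = target_distribution(q)
    init_labels = assign_labels(q)
    prev_labels = init_labels

    opt = Adam([*model.params(), centroids], lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 17)

    lt_trace, lr_trace, lc_trace = [], [], []
    stopped = False
    epoch = 0
    for epoch in range(cfg.max_iter):
        if epoch % cfg.p_update_interval == 0 and epoch > 0:
            z = model.encode(x)
            q = soft_assign(z, centroids, cfg.alpha)
            p = target_distribution(q)
            labels = assign_labels(q)
            changed = float(np.mean(labels != prev_labels))
            prev_labels = labels
            if changed < cfg.tol:
                stopped = True
                break

        order = rng.permutation(n)
        ep_lt, ep_lr, ep_lc, ep_w = [], [], [], []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb = x[idx]
            zb = model.encode(xb)
            xhat = model.decode(zb)
            l_r = reconstruction_loss(xb, xhat)

            g_xhat = 2.0 * (xhat - xb) / len(xb)
            gz_recon = model.backward_decoder(g_xhat)

            gz_clu, gc, qb = clustering_grads(zb, centroids, p[idx], cfg.alpha)
            l_c = clustering_loss(p[idx], qb, reduction="mean")

            # reconstruction trains encoder+decoder; the clustering term
            # reaches the encoder and centroids only (the decoder never
            # sees Q)
            model.backward_encoder(gz_recon + cfg.balance * gz_clu)
            grads = [*model.grads(), cfg.balance * gc]

            l_t = total_loss(l_r, l_c, cfg.balance)
            if not np.isfinite(l_t):
                raise DivergenceError(f"non-finite total loss at epoch {epoch}")
            opt.step(grads)
            ep_lt.append(l_t)
            ep_lr.append(l_r)
            ep_lc.append(l_c)
            ep_w.append(len(xb))

        lt_trace.append(np.average(ep_lt, weights=ep_w))
        lr_trace.append(np.average(ep_lr, weights=ep_w))
        lc_trace.append(np.average(ep_lc, weights=ep_w))

    z = model.encode(x)
    q = soft_assign(z, centroids, cfg.alpha)
    p_final = target_distribution(q)
    labels = assign_labels(q)
    counts = np.bincount(labels, minlength=cfg.n_clusters)
    empty = tuple(int(m) for m in np.where(counts == 0)[0])

    state = ClusterState(centroids=centroids, q=q, p=p_final, labels=labels,
                         alpha=cfg.alpha)
    return TrainResult(
        latent=z,
        labels=labels,
        state=state,
        loss_total=np.asarray(lt_trace),
        loss_recon=np.asarray(lr_trace),
        loss_cluster=np.asarray(lc_trace),
        n_epochs=len(lt_trace),
        initial_centroids=init_centroids,
        initial_labels=init_labels,
        empty_clusters=empty,
        stopped_early=stopped,
    )
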