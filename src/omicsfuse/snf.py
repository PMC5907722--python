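"""Similarity Network Fusion (SNF) and the rSNF feature ranking.

SNF turns each omics layer into a patient-similarity network (a scaled
exponential kernel on Euclidean distances with a locally adaptive
bandwidth) and fuses the two networks by iterative cross-diffusion: each
layer's full similarity is propagated through the other layer's k-nearest-
neighbor graph, which reinforces structure supported by both layers and
washes out layer-specific noise. The fused network is the average of the
diffused layer networks.

The rSNF ranking scores every feature of the juxtaposed matrix by how well
the patient partition induced by that feature alone agrees (normalized
mutual information) with the spectral-clustering partition of the fused
network: features that individually reproduce the fused multi-omics
structure rank first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.metrics import normalized_mutual_info_score

from ._utils import DataError, rank_order, stage_seed
from .io import OmicsLayer, RankedFeatureList

__all__ = [
    "AffinityNetwork",
    "FusedNetwork",
    "build_affinity",
    "snf_fuse",
    "cluster_fused",
    "rsnf_rank",
]


@dataclass
class AffinityNetwork:
    """Sample-similarity network of one omics layer over the TR samples."""

    matrix: np.ndarray
    sample_ids: list[str]
    k_neighbors: int
    mu: float


@dataclass
class FusedNetwork:
    """SNF-fused sample network plus its spectral-cluster assignment."""

    matrix: np.ndarray
    sample_ids: list[str]
    iterations: int
    cluster_labels: np.ndarray | None = None
    n_clusters: int | None = None


# ---------------------------------------------------------------------------
# affinity construction


def _affinity_from_distances(d2: np.ndarray, k: int, mu: float) -> np.ndarray:
    """Scaled exponential kernel with locally adaptive bandwidth.

    ``d2`` is a squared-distance matrix. The bandwidth for pair (i, j) is
    the average of the mean squared distance of i and of j to their k
    nearest neighbors, blended with the pair distance itself, scaled by
    ``mu``. Identical samples (zero distance, possibly zero bandwidth) get
    the maximal similarity 1.
    """
    n = d2.shape[0]
    d2 = (d2 + d2.T) / 2.0
    np.fill_diagonal(d2, 0.0)
    sorted_d2 = np.sort(d2, axis=1)
    # columns 1..k: k nearest neighbors excluding self
    means = sorted_d2[:, 1 : k + 1].mean(axis=1)
    eps = (means[:, None] + means[None, :] + d2) / 3.0
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.exp(-d2 / (mu * eps))
    w[~np.isfinite(w)] = 1.0  # zero distance and zero bandwidth
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return w


def build_affinity(layer: OmicsLayer, k: int = 20, mu: float = 0.5) -> AffinityNetwork:
    """Patient-similarity network of one layer (TR samples only).

    ``k`` is capped at ``n - 1``. Defaults (k=20, mu=0.5) follow the SNF
    method's recommended ranges.
    """
    x = np.asarray(layer.values, dtype=float)
    if not np.isfinite(x).all():
        raise DataError("affinity construction requires a finite matrix")
    n = x.shape[0]
    if n < 3:
        raise DataError("need at least 3 samples to build an affinity network")
    k = min(int(k), n - 1)
    if k < 1:
        raise DataError(f"n={n} samples leave no neighbors for k-NN affinity")
    d2 = cdist(x, x, metric="sqeuclidean")
    w = _affinity_from_distances(d2, k, mu)
    return AffinityNetwork(matrix=w, sample_ids=list(layer.sample_ids), k_neighbors=k, mu=mu)


# ---------------------------------------------------------------------------
# fusion


def _full_normalize(w: np.ndarray) -> np.ndarray:
    """Row normalization with a protected half diagonal.

    ``P[i, j] = W[i, j] / (2 * sum_{k != i} W[i, k])`` off the diagonal and
    ``P[i, i] = 1/2``; every row sums to 1 while self-similarity stays
    dominant, which keeps the cross-diffusion numerically stable.
    """
    w = w.copy().astype(float)
    np.fill_diagonal(w, 0.0)
    row = w.sum(axis=1, keepdims=True)
    row[row == 0] = 1.0
    p = w / (2.0 * row)
    np.fill_diagonal(p, 0.5)
    return p


def _local_normalize(w: np.ndarray, k: int) -> np.ndarray:
    """Row-stochastic k-nearest-neighbor kernel (zero outside the k-NN)."""
    n = w.shape[0]
    w = w.copy().astype(float)
    np.fill_diagonal(w, 0.0)
    s = np.zeros_like(w)
    for i in range(n):
        nn = np.argsort(w[i])[::-1][:k]
        denom = w[i, nn].sum()
        if denom == 0:
            s[i, i] = 1.0
            continue
        s[i, nn] = w[i, nn] / denom
    return s


def snf_fuse(
    nets: tuple[AffinityNetwork, AffinityNetwork] | list,
    k: int = 20,
    t: int = 20,
) -> FusedNetwork:
    """Fuse two affinity networks by iterative cross-diffusion.

    Each step updates layer m's status matrix as ``S_m @ P_other @ S_m.T``
    (S = local k-NN kernel, P = full normalized similarity), renormalizes
    and symmetrizes. The fused network is the average of the layer matrices
    after ``t`` steps; ``t = 0`` returns the average of the normalized
    inputs.
    """
    nets = list(nets)
    if len(nets) != 2:
        raise DataError("fusion is defined for exactly two layers")
    ids = nets[0].sample_ids
    if nets[1].sample_ids != ids:
        raise DataError("affinity networks cover different sample sets")
    n = len(ids)
    k = min(int(k), n - 1)
    p = [_full_normalize(net.matrix) for net in nets]
    s = [_local_normalize(net.matrix, k) for net in nets]
    for _ in range(int(t)):
        p_new = []
        for m in (0, 1):
            other = p[1 - m]
            upd = s[m] @ other @ s[m].T
            upd = _full_normalize(upd)
            p_new.append((upd + upd.T) / 2.0)
        p = p_new
    fused = (p[0] + p[1]) / 2.0
    fused = (fused + fused.T) / 2.0
    return FusedNetwork(matrix=fused, sample_ids=list(ids), iterations=int(t))


# ---------------------------------------------------------------------------
# spectral clustering


def _spectral_embedding(w: np.ndarray, n_vectors: int):
    """Eigen-decomposition of the symmetric normalized Laplacian.

    Returns ascending eigenvalues and the first ``n_vectors`` eigenvectors.
    """
    w = (np.asarray(w, dtype=float) + np.asarray(w, dtype=float).T) / 2.0
    deg = w.sum(axis=1)
    deg[deg == 0] = 1.0
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    lap = np.eye(w.shape[0]) - d_inv_sqrt[:, None] * w * d_inv_sqrt[None, :]
    vals, vecs = eigh(lap)
    return vals, vecs[:, :n_vectors]


def spectral_labels(w: np.ndarray, n_clusters: int, seed: int = 0) -> np.ndarray:
    """Normalized spectral clustering of a similarity matrix."""
    n = w.shape[0]
    if n_clusters >= n:
        raise DataError(f"n_clusters={n_clusters} must be < n={n}")
    if n_clusters < 2:
        raise DataError("need at least 2 clusters")
    _, vecs = _spectral_embedding(w, n_clusters)
    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    emb = vecs / norms
    km = KMeans(n_clusters=n_clusters, n_init=20, random_state=seed)
    return km.fit_predict(emb)


def eigengap_n_clusters(w: np.ndarray, candidates=range(2, 6)) -> int:
    """Eigen-gap heuristic on the normalized Laplacian spectrum."""
    candidates = list(candidates)
    vals, _ = _spectral_embedding(w, max(candidates) + 1)
    gaps = {c: vals[c] - vals[c - 1] for c in candidates if c < len(vals)}
    return max(gaps, key=lambda c: (gaps[c], -c))


def cluster_fused(f: FusedNetwork, n_clusters="auto", seed: int = 0) -> FusedNetwork:
    """Spectral clustering of the fused network; fills the label fields.

    ``n_clusters="auto"`` chooses the cluster count in 2..5 by the
    eigen-gap heuristic.
    """
    if n_clusters == "auto":
        n_clusters = eigengap_n_clusters(f.matrix, range(2, 6))
    n_clusters = int(n_clusters)
    f.cluster_labels = spectral_labels(f.matrix, n_clusters, seed=seed)
    f.n_clusters = n_clusters
    return f


# ---------------------------------------------------------------------------
# rSNF ranking


def rsnf_rank(
    juxt: OmicsLayer,
    cluster_labels,
    k: int = 20,
    mu: float = 0.5,
    seed: int = 0,
) -> RankedFeatureList:
    """Score each feature by agreement with the fused-network partition.

    For every feature of the juxtaposed TR matrix, a one-dimensional
    affinity network is built with the same kernel, spectrally clustered at
    the same number of clusters, and compared to the fused-network labels
    by normalized mutual information. Features are ranked by decreasing
    NMI. The per-feature clustering step replaces any histogram
    discretization: continuous features are partitioned by their own
    similarity structure.
    """
    labels = np.asarray(cluster_labels)
    n_clusters = int(np.unique(labels).size)
    if n_clusters < 2:
        raise DataError("rSNF ranking needs at least 2 fused clusters")
    x = juxt.values
    if labels.shape[0] != x.shape[0]:
        raise DataError("cluster labels must cover the juxtaposed TR samples")
    n = x.shape[0]
    k = min(int(k), n - 1)
    scores = np.zeros(x.shape[1])
    for j in range(x.shape[1]):
        col = x[:, j][:, None]
        d2 = (col - col.T) ** 2
        w = _affinity_from_distances(d2, k, mu)
        feat_labels = spectral_labels(w, n_clusters, seed=stage_seed(seed, f"rsnf{j}"))
        scores[j] = normalized_mutual_info_score(labels, feat_labels)
    order = rank_order(juxt.feature_ids, scores)
    return RankedFeatureList(
        [juxt.feature_ids[i] for i in order], scores[order], ranker_tag="rsnf"
    )
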