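"""Base-clustering ensemble generation.

The workhorse is an ultra-scalable spectral clustering: p representatives
are drawn from the n cells (a mix of k-means centers and random cells), a
sparse Gaussian affinity between cells and representatives is built with K
nonzeros per cell, and the resulting bipartite graph is partitioned through
the small-side (transfer-cut) eigenproblem. Louvain/Leiden community
detection on a kNN graph is available as an alternative base clusterer when
a resolution parameter is wanted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import svds
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors

from .latent import LatentSpaces, _child_seed

__all__ = [
    "BasePartition",
    "ClusterEnsemble",
    "RepresentativeSet",
    "select_representatives",
    "sparse_affinity",
    "bipartite_spectral",
    "community_partition",
    "generate_ensemble",
    "write_ensemble",
    "read_ensemble",
]


@dataclass
class BasePartition:
    labels: np.ndarray
    k: int
    subspace_index: int = 0
    run_index: int = 0
    method: str = "uspec"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= self.k):
            raise ValueError("labels must lie in [0, k)")


@dataclass
class ClusterEnsemble:
    partitions: list[BasePartition]
    D: int
    T: int
    corrupted: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return len(self.partitions[0].labels)

    def by_subspace(self) -> dict[int, list[BasePartition]]:
        groups: dict[int, list[BasePartition]] = {}
        for p in self.partitions:
            groups.setdefault(p.subspace_index, []).append(p)
        return groups


@dataclass
class RepresentativeSet:
    points: np.ndarray
    source_flags: list[str]  # "kmeans_center" or "random_cell"


def select_representatives(
    z: np.ndarray, p: int, mix_frac: float = 0.5, seed: int = 0
) -> RepresentativeSet:
    """Pick p landmark points: round(mix_frac*p) k-means centers fitted on a
    random sub-sample, the rest distinct randomly chosen cells."""
    z = np.asarray(z, dtype=float)
    n = z.shape[0]
    if not 1 <= p <= n:
        raise ValueError(f"p={p} must be in [1, {n}]")
    rng = np.random.default_rng(seed)
    n_km = int(round(mix_frac * p))
    n_rand = p - n_km
    points, flags = [], []
    if n_km > 0:
        sub = z[rng.choice(n, size=min(n, max(10 * n_km, 100)), replace=False)]
        km = KMeans(n_clusters=n_km, n_init=3, random_state=int(rng.integers(2**31)))
        km.fit(sub)
        points.append(km.cluster_centers_)
        flags += ["kmeans_center"] * n_km
    if n_rand > 0:
        idx = rng.choice(n, size=n_rand, replace=False)
        points.append(z[idx])
        flags += ["random_cell"] * n_rand
    return RepresentativeSet(np.vstack(points), flags)


def sparse_affinity(
    z: np.ndarray,
    reps: RepresentativeSet,
    K: int = 5,
    sigma: float | str = "auto",
) -> sp.csr_matrix:
    """Sparse n x p Gaussian affinity to the K nearest representatives.

    s_ij = exp(-||x_i - r_j||^2 / (2 sigma^2)) when r_j is among the K
    nearest representatives of x_i, else 0. ``sigma="auto"`` uses the mean
    of the retained cell-to-representative distances. Exact distance ties at
    the K-th position are trimmed toward the lower representative index.
    """
    z = np.asarray(z, dtype=float)
    R = reps.points
    p = R.shape[0]
    if K > p:
        raise ValueError(f"K={K} exceeds number of representatives {p}")
    d2 = np.maximum(
        (z**2).sum(1)[:, None] + (R**2).sum(1)[None, :] - 2.0 * z @ R.T, 0.0
    )
    # stable sort -> ties resolved toward lower index
    nearest = np.argsort(d2, axis=1, kind="stable")[:, :K]
    rows = np.repeat(np.arange(z.shape[0]), K)
    cols = nearest.ravel()
    kept_d2 = d2[rows, cols]
    if sigma == "auto":
        sigma_val = float(np.mean(np.sqrt(kept_d2)))
        if sigma_val == 0:
            sigma_val = 1.0  # all points coincide with reps
    else:
        sigma_val = float(sigma)
        if sigma_val <= 0:
            raise ValueError("sigma must be positive")
    vals = np.exp(-kept_d2 / (2.0 * sigma_val**2))
    return sp.csr_matrix((vals, (rows, cols)), shape=(z.shape[0], p))


def bipartite_spectral(S: sp.spmatrix, k: int, seed: int = 0) -> BasePartition:
    """Transfer-cut partition of the cell-representative bipartite graph.

    Solves the normalized eigenproblem through the SVD of
    D_r^{-1/2} S D_c^{-1/2}, stacks the (n+p) x k scaled singular-vector
    matrix, row-normalizes it and runs seeded k-means on the cell rows.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    S = sp.csr_matrix(S, dtype=float)
    n, p = S.shape
    d1 = np.asarray(S.sum(axis=1)).ravel()
    d2 = np.asarray(S.sum(axis=0)).ravel()
    if (d1 <= 0).any():
        raise ValueError("affinity has a zero row sum")
    d2 = np.maximum(d2, 1e-300)
    D1 = sp.diags(1.0 / np.sqrt(d1))
    D2 = sp.diags(1.0 / np.sqrt(d2))
    Shat = D1 @ S @ D2
    m = k
    if m >= min(n, p):
        U, s, Vt = np.linalg.svd(Shat.toarray(), full_matrices=False)
        U, Vt = U[:, :m], Vt[:m]
    else:
        U, s, Vt = svds(Shat, k=m, random_state=seed)
        order = np.argsort(-s)
        U, Vt = U[:, order], Vt[order]
    stacked = np.vstack([D1 @ U, D2 @ Vt.T])
    norms = np.linalg.norm(stacked, axis=1, keepdims=True)
    stacked = stacked / np.maximum(norms, 1e-12)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(stacked[:n])
    return BasePartition(labels, k=k, method="uspec")


def community_partition(
    z: np.ndarray,
    method: str = "leiden",
    resolution: float = 1.0,
    knn: int = 15,
    seed: int = 0,
) -> BasePartition:
    """Louvain or Leiden community detection on a kNN graph of the embedding.

    The graph is unweighted and symmetrized (edge if either endpoint lists
    the other as a neighbor). The number of clusters is whatever the
    community method returns at the given resolution.
    """
    import igraph as ig

    if resolution <= 0:
        raise ValueError("resolution must be positive")
    z = np.asarray(z, dtype=float)
    n = z.shape[0]
    if knn >= n:
        raise ValueError("knn must be smaller than the number of cells")
    nn = NearestNeighbors(n_neighbors=knn + 1).fit(z)
    _, idx = nn.kneighbors(z)
    edges = {(min(i, j), max(i, j)) for i, row in enumerate(idx) for j in row[1:]}
    g = ig.Graph(n=n, edges=sorted(edges))
    if method == "louvain":
        import random as _random

        ig.set_random_number_generator(_random.Random(seed))
        part = g.community_multilevel(resolution=resolution)
        membership = part.membership
    elif method == "leiden":
        import leidenalg

        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=resolution,
            seed=seed,
            n_iterations=2,
        )
        membership = part.membership
    else:
        raise ValueError(f"unknown community method {method!r}")
    labels = np.asarray(membership, dtype=int)
    return BasePartition(labels, k=int(labels.max()) + 1, method=method)


def generate_ensemble(
    Z: LatentSpaces,
    k: int,
    T: int = 10,
    method: str = "uspec",
    seed: int = 0,
    p: int | None = None,
    K: int = 5,
    mix_frac: float = 0.5,
    sigma: float | str = "auto",
    resolution: float = 1.0,
    knn: int = 15,
) -> ClusterEnsemble:
    """Run the base clusterer T times in each of the D latent spaces.

    Each run gets a seed derived from the master seed and its
    (subspace_index, run_index) pair, so representative sets and k-means
    initializations differ across runs while the whole ensemble stays
    reproducible.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    partitions = []
    for d_idx, z in enumerate(Z.spaces):
        n = z.shape[0]
        p_eff = min(n, 1000) if p is None else min(p, n)
        for t in range(T):
            run_seed = _child_seed(seed, d_idx, t)
            if method == "uspec":
                reps = select_representatives(z, p_eff, mix_frac, seed=run_seed)
                S = sparse_affinity(z, reps, K=min(K, p_eff), sigma=sigma)
                part = bipartite_spectral(S, k=k, seed=run_seed)
            else:
                part = community_partition(
                    z, method=method, resolution=resolution, knn=knn, seed=run_seed
                )
            part.subspace_index = d_idx
            part.run_index = t
            partitions.append(part)
    return ClusterEnsemble(partitions, D=Z.d, T=T)


def write_ensemble(ensemble: ClusterEnsemble, labels_path: str, meta_path: str) -> None:
    """Export as a labels CSV (cells x partitions) plus a JSON sidecar."""
    cols = {
        f"p{i}": p.labels for i, p in enumerate(ensemble.partitions)
    }
    pd.DataFrame(cols).to_csv(labels_path, index=False)
    meta = {
        "D": ensemble.D,
        "T": ensemble.T,
        "columns": [
            {"subspace_index": p.subspace_index, "run_index": p.run_index,
             "method": p.method, "k": p.k}
            for p in ensemble.partitions
        ],
    }
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=1)


def read_ensemble(labels_path: str, meta_path: str) -> ClusterEnsemble:
    df = pd.read_csv(labels_path)
    with open(meta_path) as fh:
        meta = json.load(fh)
    partitions = [
        BasePartition(df.iloc[:, i].to_numpy(), k=c["k"],
                      subspace_index=c["subspace_index"],
                      run_index=c["run_index"], method=c["method"])
        for i, c in enumerate(meta["columns"])
    ]
    return ClusterEnsemble(partitions, D=meta["D"], T=meta["T"])
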