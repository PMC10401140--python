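"""Locally weighted co-association consensus.

Each cluster of each base partition is scored by its cross-ensemble
uncertainty U (the summed entropy of how the cluster is split by every
other partition) and converted to a reliability weight
ECI = exp(-U / (theta * D * N)). The co-association matrix then accumulates
ECI, rather than a plain count, whenever two cells are co-clustered, so
unstable clusters contribute less. The final partition is an average-linkage
agglomerative cut of the resulting similarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .ensemble import BasePartition, ClusterEnsemble

__all__ = [
    "CoAssociationMatrix",
    "ConsensusPartition",
    "cluster_uncertainty",
    "eci",
    "lwca_matrix",
    "agglomerative_consensus",
    "consensus",
]


@dataclass
class CoAssociationMatrix:
    values: np.ndarray
    weighting: str = "eci"


@dataclass
class ConsensusPartition:
    labels: np.ndarray
    k: int
    coassociation: CoAssociationMatrix | None = None
    cluster_eci: dict[tuple[int, int], float] = field(default_factory=dict)


def cluster_uncertainty(cluster: np.ndarray, ensemble: ClusterEnsemble) -> float:
    """Entropy (bits) of how ``cluster`` (cell indices) is fragmented by
    every base partition of the ensemble.

    U(c) = -sum_partitions sum_j (|c ∩ c_j| / |c|) log2(|c ∩ c_j| / |c|),
    zero exactly when the cluster sits inside one cluster of every partition.
    """
    cluster = np.asarray(cluster, dtype=int)
    if cluster.size == 0:
        raise ValueError("empty cluster")
    u = 0.0
    for part in ensemble.partitions:
        sub = part.labels[cluster]
        counts = np.bincount(sub)
        frac = counts[counts > 0] / cluster.size
        u -= float(np.sum(frac * np.log2(frac)))
    return u


def eci(U: float, theta: float, D: int, N: float) -> float:
    """Reliability weight exp(-U / (theta * D * N)) in (0, 1]."""
    if theta <= 0 or D <= 0 or N <= 0:
        raise ValueError("theta, D and N must be positive")
    return float(np.exp(-U / (theta * D * N)))


def _partition_entropies(labels_matrix: np.ndarray) -> np.ndarray:
    """U for every cluster of every partition, vectorized over cells.

    labels_matrix is (n_partitions, n_cells); returns a list aligned with
    partitions of per-cluster U arrays.
    """
    nP, n = labels_matrix.shape
    out = []
    for p in range(nP):
        lab = labels_matrix[p]
        k = lab.max() + 1
        U = np.zeros(k)
        sizes = np.bincount(lab, minlength=k).astype(float)
        for q in range(nP):
            other = labels_matrix[q]
            kq = other.max() + 1
            joint = np.zeros((k, kq))
            np.add.at(joint, (lab, other), 1.0)
            frac = joint / np.maximum(sizes[:, None], 1.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                term = np.where(frac > 0, frac * np.log2(frac), 0.0)
            U -= term.sum(axis=1)
        out.append(U)
    return out


def lwca_matrix(
    ensemble: ClusterEnsemble, theta: float = 0.4, weighting: str = "eci"
) -> CoAssociationMatrix:
    """Locally weighted co-association matrix.

    Entry (i, j) averages, over base partitions, the ECI of the cluster
    containing both i and j (0 when they are separated). ``weighting=
    "uniform"`` reduces to the classic co-cluster frequency. The ECI
    normalizer theta*D*N is taken as theta times the total number of base
    partitions, which equals theta*D*N for balanced ensembles and
    generalizes to pruned, unbalanced ones.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    parts = ensemble.partitions
    if not parts:
        raise ValueError("empty ensemble")
    n = ensemble.n_cells
    labels_matrix = np.vstack([p.labels for p in parts])
    nP = len(parts)
    C = np.zeros((n, n))
    if weighting == "eci":
        Us = _partition_entropies(labels_matrix)
    for p_idx, part in enumerate(parts):
        lab = labels_matrix[p_idx]
        k = lab.max() + 1
        if weighting == "eci":
            w = np.exp(-Us[p_idx] / (theta * nP))
        else:
            w = np.ones(k)
        H = np.zeros((n, k))
        H[np.arange(n), lab] = 1.0
        C += (H * w[lab][:, None]) @ H.T
    C /= nP
    np.fill_diagonal(C, C.max(initial=1.0))
    return CoAssociationMatrix(C, weighting=weighting)


def agglomerative_consensus(caM: CoAssociationMatrix, k: int) -> ConsensusPartition:
    """Average-linkage agglomerative cut of the co-association similarity."""
    C = caM.values
    n = C.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"k={k} out of range [2, {n}]")
    cmax = C.max()
    Dmat = 1.0 - C / (cmax if cmax > 0 else 1.0)
    np.fill_diagonal(Dmat, 0.0)
    Dmat = np.maximum((Dmat + Dmat.T) / 2.0, 0.0)
    Zl = linkage(squareform(Dmat, checks=False), method="average")
    labels = fcluster(Zl, t=k, criterion="maxclust") - 1
    # compact, order-of-appearance relabeling
    _, labels = np.unique(labels, return_inverse=True)
    return ConsensusPartition(labels, k=int(labels.max()) + 1, coassociation=caM)


def consensus(
    ensemble: ClusterEnsemble, k: int, theta: float = 0.4, weighting: str = "eci"
) -> ConsensusPartition:
    """Full consensus: uncertainty -> ECI -> weighted co-association ->
    agglomerative cut at k clusters."""
    caM = lwca_matrix(ensemble, theta=theta, weighting=weighting)
    return agglomerative_consensus(caM, k)
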