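"""Internal cluster-quality objectives and optimization direction.

Compactness (Cp) averages within-cluster pairwise distances, Deviation
(Dev) sums cell-to-centroid distances; both are "smaller is better" when
clusters are genuinely compact. Because real data can invert that
association, a silhouette-based indicator fixes the optimization direction
once, from the initial consensus: if any cell's silhouette falls below a
threshold eps (default -0.6), the signs of both objectives are flipped so
the pruner maximizes them instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.metrics import silhouette_samples

__all__ = [
    "ObjectivePair",
    "SilhouetteReport",
    "compactness",
    "deviation",
    "silhouette",
    "decide_direction",
    "evaluate_mask",
    "estimate_k",
]


@dataclass(frozen=True)
class ObjectivePair:
    dev: float
    cp: float
    direction: int = 1

    def __post_init__(self) -> None:
        if self.direction not in (1, -1):
            raise ValueError("direction must be +1 or -1")

    @property
    def signed(self) -> tuple[float, float]:
        return (self.direction * self.dev, self.direction * self.cp)


@dataclass
class SilhouetteReport:
    per_cell: np.ndarray

    @property
    def msc(self) -> float:
        return float(np.mean(self.per_cell))

    @property
    def min_sc(self) -> float:
        return float(np.min(self.per_cell))


def _check_labels(labels: np.ndarray, coords: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if labels.shape[0] != coords.shape[0]:
        raise ValueError("labels and coordinates disagree on cell count")
    present = np.unique(labels)
    if not np.array_equal(present, np.arange(present.size)):
        # accept any label ids, but every id must be populated
        pass
    return labels


def compactness(labels: np.ndarray, coords: np.ndarray) -> float:
    """Cp: size-weighted mean within-cluster pairwise Euclidean distance.

    Cp = (1/N) * sum_k m_k * mean_{pairs in c_k} ||x_i - x_j||.
    Singleton clusters have no pairs and contribute zero.
    """
    coords = np.asarray(coords, dtype=float)
    labels = _check_labels(labels, coords)
    N = labels.size
    total = 0.0
    for c in np.unique(labels):
        members = coords[labels == c]
        m = members.shape[0]
        if m < 2:
            continue
        total += m * pdist(members).sum() / (m * (m - 1) / 2)
    return total / N


def deviation(labels: np.ndarray, coords: np.ndarray) -> float:
    """Dev: summed Euclidean distance of every cell to its cluster centroid."""
    coords = np.asarray(coords, dtype=float)
    labels = _check_labels(labels, coords)
    total = 0.0
    for c in np.unique(labels):
        members = coords[labels == c]
        centroid = members.mean(axis=0)
        total += float(np.linalg.norm(members - centroid, axis=1).sum())
    return total


def silhouette(labels: np.ndarray, coords: np.ndarray) -> SilhouetteReport:
    """Per-cell silhouette coefficients.

    SC = 1 - a/b when a < b, 0 when a = b, b/a - 1 when a > b, where a is
    the mean distance to own-cluster co-members and b the mean distance to
    the nearest other cluster. Cells in singleton clusters score 0.
    """
    coords = np.asarray(coords, dtype=float)
    labels = _check_labels(labels, coords)
    if np.unique(labels).size < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    return SilhouetteReport(silhouette_samples(coords, labels))


def decide_direction(report: SilhouetteReport, eps: float = -0.6) -> int:
    """+1 (minimize Dev, Cp) if every silhouette lies in [eps, 1];
    -1 (maximize both) as soon as any cell falls below eps."""
    return 1 if report.min_sc >= eps else -1


def member_objectives(
    subspace_partitions: list, coords: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-partition (Dev, Cp) of each base clustering on its subspace."""
    devs = np.array([deviation(p.labels, coords) for p in subspace_partitions])
    cps = np.array([compactness(p.labels, coords) for p in subspace_partitions])
    return devs, cps


def evaluate_mask(
    mask: np.ndarray,
    subspace_partitions: list,
    coords: np.ndarray,
    direction: int = 1,
    precomputed: tuple[np.ndarray, np.ndarray] | None = None,
) -> ObjectivePair:
    """Score a pruning mask over one subspace's base partitions.

    The selected base clusterings are each evaluated against the subspace
    coordinates, and the mask's objective pair is the mean (Dev, Cp) over
    the selection — a junk member with inflated Dev/Cp therefore raises the
    pair of every mask that keeps it, which is what gives the pruner its
    selection pressure. ``precomputed`` accepts the output of
    :func:`member_objectives` to avoid rescoring members.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.size != len(subspace_partitions):
        raise ValueError("mask length must equal the number of partitions")
    if not mask.any():
        raise ValueError("all-zero mask reached evaluation; repair upstream")
    devs, cps = precomputed if precomputed is not None else member_objectives(
        subspace_partitions, coords
    )
    return ObjectivePair(
        dev=float(devs[mask].mean()),
        cp=float(cps[mask].mean()),
        direction=direction,
    )


def estimate_k(
    Z,
    k_range: tuple[int, int] = (2, 15),
    T: int = 10,
    seed: int = 0,
    theta: float = 0.4,
    eps_direction: float = -0.6,
    max_fes: int = 5,
    flies: int = 9,
    alpha: float = 13.0,
    p: int | None = None,
) -> tuple[int, dict[int, float]]:
    """Scan candidate cluster numbers and score each by mean silhouette.

    One search swarm is devoted to each k in ``k_range`` (inclusive): the
    ensemble -> prune -> consensus chain runs with a reduced pruning budget
    (default 5 iterations) and the final partition's mean silhouette (MSC)
    in the concatenated latent space is recorded. Returns the argmax k and
    the full MSC curve.
    """
    from .ensemble import generate_ensemble
    from .pruning import prune

    lo, hi = k_range
    coords = Z.concatenated()
    curve: dict[int, float] = {}
    for k in range(lo, hi + 1):
        ens = generate_ensemble(Z, k=k, T=T, seed=seed, p=p)
        init = _initial_consensus(ens, k, theta)
        rep = silhouette(init.labels, coords)
        direction = decide_direction(rep, eps=eps_direction)
        result = prune(
            ens, Z, direction=direction, max_fes=max_fes, flies=flies,
            alpha=alpha, seed=seed,
        )
        from .consensus import consensus as _consensus

        final = _consensus(result.pruned_ensemble, k=k, theta=theta)
        curve[k] = silhouette(final.labels, coords).msc
    k_best = max(curve, key=lambda kk: (curve[kk], -kk))
    return k_best, curve


def _initial_consensus(ens, k, theta):
    from .consensus import consensus as _consensus

    return _consensus(ens, k=k, theta=theta)
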