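"""Seeded synthetic data: scRNA-seq-like counts, latent blobs, corrupted
ensembles.

``simulate_counts`` produces an overdispersed count matrix with K planted
cell populations: log-normal baseline gene means, a fraction of genes
differentially expressed per cluster (shifted up or down by a log-fold
change), negative-binomial sampling, and optional logistic dropout whose
probability decreases with a gene's mean expression. It captures the
stylized facts the clustering pipeline cares about — overdispersion,
cluster-specific markers, zero inflation — but not batch effects, doublets,
or continuous trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .ensemble import BasePartition, ClusterEnsemble
from .io import ExpressionMatrix
from .latent import _child_seed

__all__ = [
    "SimulationSpec",
    "simulate_counts",
    "simulate_latent_blobs",
    "corrupt_ensemble",
]


@dataclass
class SimulationSpec:
    """Parameters of the planted-population count simulator.

    lfc is the log-fold-change magnitude of differentially expressed genes
    (natural log); dispersion is the negative-binomial size parameter r
    (variance = mu + mu^2 / r, so smaller r means more overdispersion);
    dropout_mid is the log1p-mean at which the logistic dropout probability
    crosses 1/2 (None disables dropout).
    """

    n_cells: int = 1000
    n_genes: int = 2000
    k: int = 4
    de_frac: float = 0.1
    lfc: float = 1.0
    dispersion: float = 2.0
    dropout_mid: float | None = 1.0
    dropout_slope: float = 1.0
    proportions: list[float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k > self.n_cells:
            raise ValueError("more clusters than cells")
        if self.proportions is None:
            self.proportions = [1.0 / self.k] * self.k
        if abs(sum(self.proportions) - 1.0) > 1e-8 or len(self.proportions) != self.k:
            raise ValueError("proportions must have length k and sum to 1")
        if min(self.n_cells, self.n_genes, self.k) < 1 or self.dispersion <= 0:
            raise ValueError("size and dispersion parameters must be positive")


def simulate_counts(spec: SimulationSpec) -> tuple[ExpressionMatrix, np.ndarray]:
    """Draw a (cells x genes) count matrix with planted populations.

    Returns the matrix and the planted integer labels.
    """
    rng = np.random.default_rng(spec.seed)
    base = rng.lognormal(mean=1.0, sigma=0.6, size=spec.n_genes)
    n_de = int(round(spec.de_frac * spec.n_genes))
    cluster_means = np.tile(base, (spec.k, 1))
    for c in range(spec.k):
        de_genes = rng.choice(spec.n_genes, size=n_de, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_de)
        cluster_means[c, de_genes] *= np.exp(signs * spec.lfc)
    labels = rng.choice(spec.k, size=spec.n_cells, p=spec.proportions)
    mu = cluster_means[labels]
    r = spec.dispersion
    counts = rng.negative_binomial(r, r / (r + mu)).astype(float)
    if spec.dropout_mid is not None:
        logit = spec.dropout_slope * (np.log1p(mu) - spec.dropout_mid)
        p_drop = 1.0 / (1.0 + np.exp(logit))
        counts *= rng.random(counts.shape) >= p_drop
    X = ExpressionMatrix(
        sp.csr_matrix(counts),
        [f"cell{i}" for i in range(spec.n_cells)],
        [f"gene{j}" for j in range(spec.n_genes)],
    )
    return X, labels


def simulate_latent_blobs(
    n: int, dim: int = 10, k: int = 3, separation: float = 6.0, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Isotropic Gaussian clusters with centroid spacing ``separation``
    times the unit within-cluster standard deviation."""
    if k > n:
        raise ValueError("more clusters than points")
    rng = np.random.default_rng(seed)
    centers = rng.standard_normal((k, dim))
    if k > 1:
        # rescale so the minimum pairwise center distance equals `separation`
        from scipy.spatial.distance import pdist

        dmin = pdist(centers).min()
        if dmin > 0 and separation > 0:
            centers *= separation / dmin
        elif separation == 0:
            centers[:] = 0.0
    labels = rng.integers(0, k, size=n)
    coords = centers[labels] + rng.standard_normal((n, dim))
    return coords, labels


def corrupt_ensemble(
    ensemble: ClusterEnsemble,
    n_bad_per_subspace: int,
    mode: str = "shuffle",
    seed: int = 0,
) -> ClusterEnsemble:
    """Replace members of each subspace with junk partitions.

    ``shuffle`` permutes an existing member's labels; ``random_k`` draws
    uniform labels with the same k. The (subspace, run) pairs of replaced
    members are recorded in ``corrupted`` so tests know the ground truth.
    """
    if mode not in ("shuffle", "random_k"):
        raise ValueError(f"unknown corruption mode {mode!r}")
    groups = ensemble.by_subspace()
    new_parts: list[BasePartition] = []
    flagged: list[tuple[int, int]] = []
    for d_idx in sorted(groups):
        parts = groups[d_idx]
        if n_bad_per_subspace > len(parts):
            raise ValueError("cannot corrupt more members than exist")
        rng = np.random.default_rng(_child_seed(seed, 31, d_idx))
        bad = set(rng.choice(len(parts), size=n_bad_per_subspace, replace=False).tolist())
        for i, p in enumerate(parts):
            if i in bad:
                if mode == "shuffle":
                    labels = rng.permutation(p.labels)
                else:
                    labels = rng.integers(0, p.k, size=p.labels.size)
                new_parts.append(
                    BasePartition(labels, k=p.k, subspace_index=p.subspace_index,
                                  run_index=p.run_index, method=p.method)
                )
                flagged.append((p.subspace_index, p.run_index))
            else:
                new_parts.append(p)
    return ClusterEnsemble(new_parts, D=ensemble.D, T=ensemble.T, corrupted=flagged)
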