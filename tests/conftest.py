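import numpy as np
import pytest

from depf.ensemble import BasePartition, ClusterEnsemble, generate_ensemble
from depf.latent import LatentSpaces
from depf.simulate import simulate_latent_blobs


def make_latent_spaces(n=150, dim=6, k=3, separation=6.0, d=3, noise=0.2, seed=0):
    """Planted blob coordinates replicated into d noisy latent spaces."""
    X, labels = simulate_latent_blobs(n, dim=dim, k=k, separation=separation, seed=seed)
    rngs = [np.random.default_rng(10_000 + seed * 100 + i) for i in range(d)]
    Z = LatentSpaces([X + noise * r.standard_normal(X.shape) for r in rngs],
                     seed_record=list(range(d)))
    return Z, labels


@pytest.fixture(scope="session")
def blob_latent():
    return make_latent_spaces(seed=1)


@pytest.fixture(scope="session")
def blob_ensemble(blob_latent):
    Z, labels = blob_latent
    ens = generate_ensemble(Z, k=3, T=4, seed=2, p=80)
    return ens, Z, labels


def random_partition_ensemble(n=30, n_parts=5, k=3, seed=0):
    """Ensemble of random label vectors (for oracle comparisons)."""
    rng = np.random.default_rng(seed)
    parts = [
        BasePartition(rng.integers(0, k, size=n), k=k,
                      subspace_index=0, run_index=t)
        for t in range(n_parts)
    ]
    return ClusterEnsemble(parts, D=1, T=n_parts)
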