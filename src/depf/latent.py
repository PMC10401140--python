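"""Hierarchical autoencoder embeddings.

Two stages mirror the hierarchical-autoencoder idea used for single-cell
dimension reduction:

1. A *non-negative kernel autoencoder* (NNKAE) — a single-hidden-layer
   autoencoder whose weights and biases are projected onto the non-negative
   orthant after every optimizer step. Because all parameters are
   non-negative, a gene can only contribute additively to the reconstruction,
   and the row-sums of the encoder weight matrix rank genes by how much the
   part-based representation uses them. Low-weight genes are dropped.

2. A *stacked Bayesian autoencoder* — a variational autoencoder whose
   encoder produces a per-cell Gaussian N(mu, sigma^2) in latent space; the
   sigma head is stacked on the mu head. Sampling the posterior several
   times yields multiple distinct latent spaces of the same data, which is
   the source of ensemble diversity downstream.

Both networks are implemented directly in numpy (hand-derived gradients,
Adam updates); the matrices involved are small enough that this trains in
seconds on a single core. A deterministic truncated-SVD embedding is
available as a cheap alternative (``embedding_mode="svd_fallback"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import NormalizedMatrix

__all__ = [
    "NNKAEModel",
    "BayesianEncoder",
    "LatentSpaces",
    "fit_nnkae",
    "select_informative_genes",
    "fit_stacked_bayesian_ae",
    "sample_latent_spaces",
    "svd_embedding",
    "fit_latent_spaces",
]


def _child_seed(master: int, *key: int) -> int:
    ss = np.random.SeedSequence([int(master) & 0x7FFFFFFF, *[int(k) for k in key]])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.params = params
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)


@dataclass
class NNKAEModel:
    W_E: np.ndarray
    b_E: np.ndarray
    W_D: np.ndarray
    b_D: np.ndarray
    loss_trace: list[float] = field(default_factory=list)

    @property
    def gene_scores(self) -> np.ndarray:
        return self.W_E.sum(axis=1)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -40, 40)))


def fit_nnkae(
    M: NormalizedMatrix | np.ndarray,
    hidden_dim: int = 64,
    epochs: int = 30,
    seed: int = 0,
    lr: float = 1e-2,
    batch_size: int = 256,
    weight_decay: float = 1e-4,
) -> NNKAEModel:
    """Train the non-negative kernel autoencoder on a [0,1] matrix.

    Sigmoid encoder, linear decoder, mean-squared reconstruction loss; every
    parameter is clamped at zero after each Adam step so the learned
    representation stays part-based. A small L2 penalty on the encoder
    weights lets the weight rows of uninformative genes decay to zero, so
    the row-sums of W_E rank genes by their contribution.
    """
    X = M.values if isinstance(M, NormalizedMatrix) else np.asarray(M, dtype=float)
    n, m = X.shape
    if hidden_dim < 1:
        raise ValueError("hidden_dim must be >= 1")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(2.0 / (m + hidden_dim))
    W_E = np.abs(rng.normal(0, scale, (m, hidden_dim)))
    b_E = np.zeros(hidden_dim)
    W_D = np.abs(rng.normal(0, scale, (hidden_dim, m)))
    b_D = np.zeros(m)
    params = [W_E, b_E, W_D, b_D]
    opt = _Adam(params, lr)
    trace: list[float] = []
    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            Xb = X[idx]
            e = _sigmoid(Xb @ W_E + b_E)
            R = e @ W_D + b_D
            diff = R - Xb
            loss = float(np.mean(diff**2))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    "NNKAE training diverged (non-finite loss); lower the learning rate"
                )
            epoch_loss += loss * len(idx)
            dR = 2.0 * diff / diff.size
            gW_D = e.T @ dR
            gb_D = dR.sum(axis=0)
            de = dR @ W_D.T
            dpre = de * e * (1 - e)
            gW_E = Xb.T @ dpre + weight_decay * W_E
            gb_E = dpre.sum(axis=0)
            opt.step([gW_E, gb_E, gW_D, gb_D])
            for p in params:  # non-negativity projection
                np.maximum(p, 0.0, out=p)
        trace.append(epoch_loss / n)
    return NNKAEModel(W_E, b_E, W_D, b_D, trace)


def select_informative_genes(model: NNKAEModel, n_keep: int) -> np.ndarray:
    """Indices of the ``n_keep`` genes with the largest encoder weight mass.

    Ties broken toward the lower gene index; result sorted ascending.
    """
    scores = model.gene_scores
    if not 1 <= n_keep <= scores.size:
        raise ValueError(f"n_keep={n_keep} out of range [1, {scores.size}]")
    # stable sort on (-score, index) keeps lower indices on ties
    order = np.lexsort((np.arange(scores.size), -scores))
    return np.sort(order[:n_keep])


@dataclass
class BayesianEncoder:
    """Variational autoencoder parameters (tanh hidden layers)."""

    W1: np.ndarray
    b1: np.ndarray
    Wm: np.ndarray
    bm: np.ndarray
    Ws: np.ndarray
    bs: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    W3: np.ndarray
    b3: np.ndarray
    latent_dim: int
    loss_trace: list[float] = field(default_factory=list)

    def encode(self, A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Posterior parameters (mu, sigma) for each cell; sigma > 0."""
        h1 = np.tanh(A @ self.W1 + self.b1)
        mu = h1 @ self.Wm + self.bm
        s_pre = mu @ self.Ws + self.bs
        sigma = _softplus(s_pre)
        return mu, sigma

    def decode(self, z: np.ndarray) -> np.ndarray:
        h2 = np.tanh(z @ self.W2 + self.b2)
        return h2 @ self.W3 + self.b3


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x) + 1e-8


def fit_stacked_bayesian_ae(
    A: NormalizedMatrix | np.ndarray,
    latent_dim: int = 15,
    epochs: int = 50,
    seed: int = 0,
    hidden_dim: int = 128,
    beta_kl: float = 0.005,
    lr: float = 1e-3,
    batch_size: int = 256,
) -> BayesianEncoder:
    """Train the stacked Bayesian (variational) autoencoder.

    Encoder A -> tanh(hidden) -> mu; sigma head stacked on mu through a
    softplus so it is strictly positive. The loss is the usual evidence
    bound with Gaussian likelihood: squared reconstruction error from a
    reparameterized draw z = mu + sigma * eps, summed over genes and
    averaged over the batch, plus the KL term against N(0, I) weighted by
    ``beta_kl``.
    """
    X = A.values if isinstance(A, NormalizedMatrix) else np.asarray(A, dtype=float)
    n, m = X.shape
    if n == 0 or m == 0:
        raise ValueError("empty input matrix")
    if latent_dim >= m:
        raise ValueError(f"latent_dim={latent_dim} must compress below {m} genes")
    rng = np.random.default_rng(seed)

    def glorot(fan_in, fan_out):
        return rng.normal(0, np.sqrt(2.0 / (fan_in + fan_out)), (fan_in, fan_out))

    enc = BayesianEncoder(
        W1=glorot(m, hidden_dim), b1=np.zeros(hidden_dim),
        Wm=glorot(hidden_dim, latent_dim), bm=np.zeros(latent_dim),
        Ws=glorot(latent_dim, latent_dim) * 0.1, bs=np.full(latent_dim, -2.0),
        W2=glorot(latent_dim, hidden_dim), b2=np.zeros(hidden_dim),
        W3=glorot(hidden_dim, m), b3=np.zeros(m),
        latent_dim=latent_dim,
    )
    params = [enc.W1, enc.b1, enc.Wm, enc.bm, enc.Ws, enc.bs,
              enc.W2, enc.b2, enc.W3, enc.b3]
    opt = _Adam(params, lr)
    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            Xb = X[idx]
            nb = len(idx)
            h1 = np.tanh(Xb @ enc.W1 + enc.b1)
            mu = h1 @ enc.Wm + enc.bm
            s_pre = mu @ enc.Ws + enc.bs
            sigma = _softplus(s_pre)
            eps = rng.standard_normal(mu.shape)
            z = mu + sigma * eps
            h2 = np.tanh(z @ enc.W2 + enc.b2)
            Ahat = h2 @ enc.W3 + enc.b3
            diff = Ahat - Xb
            recon = float(np.sum(diff**2)) / nb
            kl = 0.5 * float(np.sum(mu**2 + sigma**2 - 1.0 - 2.0 * np.log(sigma))) / nb
            loss = recon + beta_kl * kl
            if not np.isfinite(loss):
                raise FloatingPointError(
                    "VAE training diverged (non-finite loss); lower the learning rate"
                )
            epoch_loss += loss * nb

            dAhat = 2.0 * diff / nb
            gW3 = h2.T @ dAhat
            gb3 = dAhat.sum(axis=0)
            dh2 = dAhat @ enc.W3.T
            dz2 = dh2 * (1 - h2**2)
            gW2 = z.T @ dz2
            gb2 = dz2.sum(axis=0)
            dz = dz2 @ enc.W2.T
            dmu = dz.copy()
            dsigma = dz * eps
            dmu += beta_kl * mu / nb
            dsigma += beta_kl * (sigma - 1.0 / sigma) / nb
            ds_pre = dsigma * _sigmoid(s_pre)
            gWs = mu.T @ ds_pre
            gbs = ds_pre.sum(axis=0)
            dmu += ds_pre @ enc.Ws.T
            gWm = h1.T @ dmu
            gbm = dmu.sum(axis=0)
            dh1 = dmu @ enc.Wm.T
            dh1p = dh1 * (1 - h1**2)
            gW1 = Xb.T @ dh1p
            gb1 = dh1p.sum(axis=0)
            opt.step([gW1, gb1, gWm, gbm, gWs, gbs, gW2, gb2, gW3, gb3])
        enc.loss_trace.append(epoch_loss / n)
    return enc


@dataclass
class LatentSpaces:
    """A set of d stochastic low-dimensional embeddings of the same cells."""

    spaces: list[np.ndarray]
    seed_record: list[int]
    mode: str = "autoencoder"

    def __post_init__(self) -> None:
        if not self.spaces:
            raise ValueError("need at least one latent space")
        shape = self.spaces[0].shape
        if any(s.shape != shape for s in self.spaces):
            raise ValueError("latent spaces must share (n, latent_dim)")

    @property
    def d(self) -> int:
        return len(self.spaces)

    @property
    def n_cells(self) -> int:
        return self.spaces[0].shape[0]

    def concatenated(self) -> np.ndarray:
        return np.hstack(self.spaces)


def sample_latent_spaces(
    enc: BayesianEncoder,
    A: NormalizedMatrix | np.ndarray,
    d: int = 3,
    seed: int = 0,
    sigma_scale: float = 1.0,
) -> LatentSpaces:
    """Draw ``d`` latent spaces z ~ N(mu, sigma^2) from a trained encoder."""
    if d < 1:
        raise ValueError("d must be >= 1")
    X = A.values if isinstance(A, NormalizedMatrix) else np.asarray(A, dtype=float)
    mu, sigma = enc.encode(X)
    spaces, seeds = [], []
    for i in range(d):
        s = _child_seed(seed, 101, i)
        rng = np.random.default_rng(s)
        spaces.append(mu + sigma_scale * sigma * rng.standard_normal(mu.shape))
        seeds.append(s)
    return LatentSpaces(spaces, seeds, mode="autoencoder")


def svd_embedding(
    M: NormalizedMatrix | np.ndarray,
    latent_dim: int = 15,
    d: int = 3,
    seed: int = 0,
    noise_scale: float = 1e-3,
) -> LatentSpaces:
    """Deterministic truncated-SVD embedding, replicated d times with a
    small seeded Gaussian perturbation per copy."""
    from sklearn.decomposition import TruncatedSVD

    X = M.values if isinstance(M, NormalizedMatrix) else np.asarray(M, dtype=float)
    k = min(latent_dim, min(X.shape) - 1)
    base = TruncatedSVD(n_components=k, random_state=seed).fit_transform(X)
    spaces, seeds = [], []
    for i in range(d):
        s = _child_seed(seed, 202, i)
        rng = np.random.default_rng(s)
        spaces.append(base + noise_scale * rng.standard_normal(base.shape))
        seeds.append(s)
    return LatentSpaces(spaces, seeds, mode="svd_fallback")


def fit_latent_spaces(
    M: NormalizedMatrix,
    n_keep: int = 5000,
    hidden_dim: int = 64,
    latent_dim: int = 15,
    d: int = 3,
    epochs_nnkae: int = 30,
    epochs_vae: int = 50,
    beta_kl: float = 0.005,
    seed: int = 0,
    embedding_mode: str = "autoencoder",
) -> LatentSpaces:
    """Full latent stage: gene filtering by NNKAE, then VAE sampling.

    With ``embedding_mode="svd_fallback"`` the autoencoders are skipped in
    favor of the truncated-SVD embedding.
    """
    if embedding_mode == "svd_fallback":
        return svd_embedding(M, latent_dim=latent_dim, d=d, seed=seed)
    n_keep = min(n_keep, len(M.gene_ids))
    model = fit_nnkae(M, hidden_dim=hidden_dim, epochs=epochs_nnkae,
                      seed=_child_seed(seed, 1))
    kept = select_informative_genes(model, n_keep)
    A = M.values[:, kept]
    enc = fit_stacked_bayesian_ae(
        A, latent_dim=min(latent_dim, A.shape[1] - 1), epochs=epochs_vae,
        beta_kl=beta_kl, seed=_child_seed(seed, 2),
    )
    return sample_latent_spaces(enc, A, d=d, seed=_child_seed(seed, 3))
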