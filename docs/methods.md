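# Methods

## Pipeline overview

`depf` turns a cells × genes expression matrix into a single consensus
partition in five stages: preprocessing, latent embedding, base-clustering
ensemble generation, bi-objective ensemble pruning, and locally weighted
consensus. A single master seed drives every stochastic stage through
`numpy.random.SeedSequence` children keyed by stage and run indices, so the
whole run is reproducible bit-for-bit and individual stages remain
independently reseedable.

## Preprocessing

Quality control follows the Seurat convention: genes expressed in fewer
than `min_cells` (default 3) cells are removed first, then cells with fewer
than `min_features` (default 200) expressed genes and cells whose
mitochondrial count fraction (genes matching the case-insensitive prefix
`MT-`) exceeds `max_mito_frac` (default 0.05). Counts are then log(1+x)
transformed and each cell is min-max rescaled to [0, 1]:

    M[i, j] = (X[i, j] − min_j X[i, j]) / (max_j X[i, j] − min_j X[i, j]).

A cell whose values are all equal has zero range; it is mapped to a zero
row (it carries no contrast, and any constant would do). The order — log
first, rescale second — is a design choice: the rescaled matrix is the
autoencoder input, and log-compression first keeps the rescaling from being
dominated by a handful of very high counts. Both steps can be switched off
in the config.

## Latent embedding

Two numpy-implemented networks (hand-derived gradients, Adam, minibatch
size 256):

* **Non-negative kernel autoencoder (NNKAE)** — one sigmoid hidden layer
  (default 64 units), linear decoder, mean-squared loss, every parameter
  projected onto [0, ∞) after each step. Because contributions are purely
  additive, the row-sums of the encoder weight matrix score each gene's
  share of the representation; the top `n_keep` (default 5000, or all)
  genes are retained. A small L2 penalty (1e-4) on the encoder weights
  makes the rows of genes that carry no signal decay to zero, so dead genes
  rank last rather than floating at their random initialization.
* **Stacked Bayesian autoencoder** — a variational autoencoder with a tanh
  hidden layer (128 units), a linear mu head, and a sigma head stacked on
  mu through a softplus (so sigma > 0 always). The loss is squared
  reconstruction error summed over genes and averaged over cells plus
  β·KL(N(mu, sigma²) ‖ N(0, I)) with β = 0.005. The reconstruction term is
  summed (not averaged) over genes deliberately: averaging would let the KL
  term dominate per-gene gradients and push sigma toward 1, washing out the
  structure in the sampled spaces.

Sampling z ~ N(mu, sigma²) d times (default d = 3) yields d distinct latent
spaces of the same cells — the source of ensemble diversity. Defaults:
latent_dim 15, 30 NNKAE epochs, 50 VAE epochs. We sample one trained model
rather than retraining per space (cheaper; retraining is available by
re-seeding). A deterministic truncated-SVD embedding (d copies plus 1e-3
seeded jitter) is provided for fast runs and tests
(`embedding_mode="svd_fallback"`); its provenance is recorded on the
`LatentSpaces` object.

## Base-clustering ensemble

The default base clusterer is landmark (ultra-scalable) bipartite spectral
clustering: p representatives (default min(n, 1000)) are drawn as a
half/half mix of k-means centers over a random sub-sample and distinct
random cells; the sparse affinity keeps, per cell, the K = 5 nearest
representatives with Gaussian weights exp(−d²/2σ²), σ defaulting to the
mean retained distance (scale-free); ties at the K-th neighbor are trimmed
toward the lower representative index for determinism. The bipartite graph
is partitioned through the SVD of D_r^{-1/2} S D_c^{-1/2}: the top m = k
left/right singular vectors are rescaled, stacked into an (n+p) × k matrix,
row-normalized, and the cell rows are k-means clustered. With p = n and
K = p this coincides with dense spectral clustering — a property the tests
exercise against an independently coded dense oracle.

Each of the d latent spaces is clustered T = 10 times with per-run derived
seeds (fresh representative sets and k-means starts), giving a D×T
ensemble. Louvain and Leiden on a symmetrized unweighted kNN graph (default
knn 15) are available where a resolution parameter is needed; cluster count
is then whatever the community method returns.

## Objectives and optimization direction

For a partition of coordinates X:

* Dev = Σ_clusters Σ_members ‖x − centroid‖ (cell-to-center tightness),
* Cp = (1/N) Σ_clusters m_k · mean within-cluster pairwise distance.

Singleton clusters contribute zero to Cp (the pair term is 0/0; zero is the
continuous completion) and their cells score zero silhouette. Smaller is
better for both — when cluster structure and geometry agree. Because real
data sometimes invert that association, the direction is set once from the
initial full-ensemble consensus: per-cell silhouettes are computed in the
concatenation of all d latent spaces, and if any cell falls below
ε = −0.6 the signs of both objectives are flipped (the optimizer always
minimizes the signed pair, so "−" means maximize). The boundary ε itself
keeps the positive direction.

## Ensemble pruning (BOFOA)

Each subspace owns a subswarm of G = FD/D flies (total FD = 9; sizes differ
by at most one when D ∤ FD). A fly's position is 2M coordinates — an (X, Y)
pair per base partition of its subspace, bounded to [0, 2] (chosen so the
smell of a coordinate pair spans both sides of the 0.5 threshold; positions
are clamped after every move). The smell S^m = 1/(√(X²+Y²)+ε_s) with
ε_s = 1e-6 guarding the pole (an alternative 1/(X²+Y²+ε_s) grouping is
switchable), and the pruning code selects member m iff S^m > 0.5 (exactly
0.5 maps to off); an all-zero mask is repaired to all-ones. The first fly
of every subswarm starts at the origin, i.e. with the full ensemble
selected.

A mask is scored by the mean (Dev, Cp) of its **selected base partitions**
on the subspace coordinates. Scoring the members directly — rather than a
consensus of them — is what gives pruning its selection pressure: a
co-association consensus is deliberately robust to junk members (that is
its job), so any consensus-mediated objective is flat in exactly the bits
the pruner needs to feel; the per-member mean makes every junk member raise
the score of every mask that keeps it. Member scores are computed once per
subspace and mask evaluations are memoized, so the search costs O(M)
arithmetic per new mask.

Iterations alternate: an olfactory step draws one offspring per fly around
the subswarm's best with step scale ω = α^((FEs−1)/MaxFEs) (α = 13,
MaxFEs = 20 — ω grows 1 → 13, widening the search late, exactly as the
update rule prescribes); a vision step replaces a fly by its offspring only
under Pareto dominance of the signed pair, and updates the subswarm best
the same way (ties broken by smaller signed Dev, then Cp, then fly index,
so elitism is strict: the tracked best never worsens componentwise); a ring
exchange then sends a copy of each subswarm's best to the next subswarm,
where its mask is re-scored against the new subspace — the incomer replaces
the last fly and takes over the best slot only if it dominates. Final
selection takes each subswarm's best mask (one per subspace); the archive
reports the non-dominated set across subswarm bests. Independent optimizer
restarts are exposed via `restarts` (default 1) with mean/sd metric
reporting.

## Consensus

For each cluster c of each base partition, the uncertainty
U(c) = −Σ_partitions Σ_j (|c∩c_j|/|c|) log₂(|c∩c_j|/|c|) measures how the
rest of the ensemble fragments it; the reliability weight is
ECI = exp(−U/(θ·D·N)) with θ = 0.4 and θ·D·N taken as θ times the total
number of partitions in the ensemble at hand (identical for balanced
ensembles, well-defined after pruning leaves subspaces unequal). The
co-association entry (i, j) averages the ECI of the shared cluster over
partitions (0 when separated); uniform weighting (classic co-cluster
frequency) is available as a mode. The diagonal is set to the matrix
maximum, the matrix normalized by its maximum, converted to a distance
1 − s, and cut at k clusters by scipy average-linkage agglomeration (its
deterministic merge order provides the tie-break). The initial
(pre-pruning) and final consensus share one θ.

## Cluster-number estimation

`estimate_k` devotes one search swarm to each k in the scan range (default
2–15): ensemble → direction → pruning with a reduced budget (5 iterations
by default; full budget by flag) → consensus, scoring each final partition
by its mean silhouette (MSC) in the concatenated latent space, and returns
the argmax with the full curve (ties toward smaller k).

## Synthetic data

`simulate_counts` draws per-gene log-normal baseline means (log-mean 1.0,
log-sd 0.6), shifts a `de_frac` = 0.1 fraction of genes per cluster by a
random sign times `lfc` (natural-log fold change), samples counts from a
negative binomial with size r = `dispersion` = 2 (variance μ + μ²/r), and
optionally zeroes entries with logistic dropout whose probability falls
with log1p mean expression (midpoint `dropout_mid` = 1.0). Default scale:
1000 cells × 2000 genes, k = 4 equal populations. It reproduces the
stylized facts the clustering pipeline is sensitive to — overdispersion,
cluster-specific markers, zero inflation — but not batch effects, doublets,
ambient RNA, library-size gradients, or continuous trajectories; passing
tests therefore certify the machinery on well-specified population
structure, not robustness to those real-data complications.
`simulate_latent_blobs` provides isotropic Gaussian clusters (unit
within-cluster sd, minimum centroid spacing = `separation`) for testing the
clustering core without training an autoencoder, and `corrupt_ensemble`
replaces chosen members with label-shuffled or uniform-random partitions,
recording which, as ground truth for pruning experiments.

## Problem sizes and numerical choices

The validation suite runs at desk scale, chosen to finish in minutes on one
core: oracle comparisons at n ≤ 60, the spectral-reduction check at n = 30
over 10 seeds, the pruning-efficacy experiment at n = 600 (D = 3, T = 10,
separation 8, latent jitter 0.3, 3 of 10 members shuffled per subspace, 20
repeats), and end-to-end recovery at n = 1000 with the cluster-number scan
over 2–10. Tolerances: analytic quantities match brute-force oracles to
1e-9; elitism and determinism are exact. Degenerate inputs are defined
explicitly: constant cells rescale to zero rows, singleton clusters score
zero (Cp and silhouette), equal a = b silhouette is zero, smell exactly 0.5
deselects, an all-zero mask repairs to the full ensemble, and a
single-cluster partition is rejected where silhouettes are required.

## Known limitations

* The per-member objective means the pruner favors small, high-quality
  member subsets; it does not explicitly reward diversity, which the
  ECI-weighted consensus then has to supply from the survivors.
* Internal objectives (Dev, Cp) track external quality only when geometry
  and class structure agree; the direction indicator mitigates but cannot
  remove this on heavily manifold-shaped data.
* The numpy autoencoders are single-hidden-layer CPU trainers intended for
  datasets up to tens of thousands of cells; there is no GPU path.
* ZINB-likelihood embeddings, batch correction, doublet handling, and
  downstream functional annotation are out of scope.
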