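# Methods

This note records the statistical procedures the package implements, the
defaults and the numerical choices, and what the synthetic benchmarks do and
do not demonstrate.

## Consensus clustering

Given a dataset of N observations, H perturbed datasets are drawn by
subsampling observations and/or features without replacement (defaults:
H = 1000 runs, 80% of the observations, all features; tests and examples use
H = 30–100 for speed).  Each perturbed dataset is clustered into K groups by
a pluggable base clusterer; the default is k-means with k-means++ seeding,
10 restarts, 300 iterations and Euclidean distance.  PAM (partitioning
around medoids, BUILD + SWAP, arbitrary precomputed distances) and
average/complete-linkage hierarchical clustering are also provided; PAM is
implemented in-package because no installed library supplies it.

Run h contributes a binary co-clustering matrix C⁽ʰ⁾ (entry 1 when both
observations were sampled and co-clustered).  The consensus matrix divides,
pair by pair, the number of runs co-clustering a pair by the number of runs
co-sampling it; pairs never sampled together get 0.  The per-pair
denominators mean that under observation subsampling the consensus matrix is
*not* an exact nonnegative combination of co-clustering matrices, so the PSD
guarantee below holds only approximately; empirically the smallest
eigenvalue can reach ≈ −0.3 at 80% subsampling.  All consensus matrices are
therefore passed through the spectral-shift repair before kernel use.

**Choosing K (stability heuristic).**  `select_k_monti` scores each
candidate by the proportion of off-diagonal consensus entries strictly
inside an ambiguity band, default (0.1, 0.9) — the band is a package choice,
as is breaking ties toward the smallest K (parsimony).  A known failure mode
under this package's own benchmark geometry: the synthetic cluster means lie
equally spaced on a line, so merging adjacent clusters is itself a stable
k-means optimum and the heuristic prefers K = 2–3 regardless of the true K.
The heuristic is faithful to its definition; it is simply not a reliable
K-recovery tool for such geometries, which is why the pipelines also offer
silhouette-based selection.

## COCA

Per-dataset partitions (each with its own K_m) are stacked into the binary
K̄ × N matrix of clusters, K̄ = Σ K_m; observations missing from a dataset
get all-zero columns in that dataset's rows.  The MOC columns are consensus-
clustered (inner clusterer: k-means on the binary profiles, Euclidean), and
the global partition is extracted by average-linkage hierarchical clustering
on the dissimilarity 1 − Δ, cut at K.  Converting similarity to distance by
1 − Δ is a package choice.

**Choosing the global K.**  `coca_select_k` runs COCA for every candidate K
and picks the one maximising the average silhouette width of the final
labels against a *shared, K-independent* distance.  The default shared
distance is Euclidean between MOC columns; when the raw datasets are
available (e.g. in simulations) the caller may pass the data-space distance
instead, which is more robust to a second failure mode: observations
misclassified in one dataset form small coherent profile groups that a
per-candidate or MOC-space silhouette likes to split off, inflating the
selected K.  Silhouette of a singleton cluster is 0 (the common convention).

## Kernel machinery

* **PSD check / repair.**  `check_psd` reports the smallest eigenvalue
  (symmetry required within 1e−8); `spectral_shift` adds (−λ_min)·I when
  λ_min < −tol, which changes no eigenvector and hence no spectral
  clustering, only the feature-space scale.
* **Kernel k-means.**  The N × K relaxation is solved by kernel PCA: the K
  leading eigenvectors (descending eigenvalue, sign fixed so the first
  nonzero component is positive) are row-normalised to unit length (zero
  rows stay zero) and discretised with seeded Euclidean k-means.  Each of
  the 10 spectral starts plus 9 random starts is then refined by exact
  kernel-space Lloyd sweeps followed by Hartigan-style single-point moves
  whose objective deltas account for the cluster means shifting; the best
  within-cluster sum of squares tr(K) − tr(HᵀKH) wins.  The Hartigan phase
  matters: minima that isolate small clusters are unreachable by batch
  Lloyd updates but are found exactly on exhaustive 8-point benchmarks.
* **Weight QP.**  At fixed assignments the weight objective decomposes as
  Σ_m θ_m ᵀ Q_m θ_m with Q_m = K_m ∘ (I − HHᵀ), a Schur product of PSD
  matrices (asserted ≥ −1e−8 before solving).  The constraint set is the
  product of per-observation simplexes over observed datasets.  The problem
  is solved by FISTA with exact per-row simplex projection, step 1/L with
  L = 2·max_m λ_max(Q_m), momentum restart on objective increase, and a
  gradient-mapping stopping rule (max-norm ≤ 1e−7, ≤ 3000 iterations).  A
  1e−10 ridge keeps the solution unique (minimal-norm) when Q_m is
  singular.  An interior-point QP library would do the same job; the
  projected-gradient solver keeps the dependency footprint to numpy and is
  verified against an exhaustive simplex grid search.
* **Alternating loop.**  Weights start uniform over each observation's
  observed datasets; the loop alternates kernel k-means on the combined
  kernel and the QP, both optimising the same objective
  tr(Δ_Θ) − tr(HᵀΔ_ΘH).  Because the assignment step discretises a
  relaxation the trace need not be monotone; convergence is declared when
  the relative objective change is within tol (default 1e−5, ≤ 100
  iterations) and the best-objective iterate is returned.

## KLIC pipeline

Datasets are aligned by observation ID (union, order of first appearance);
every observation must appear in at least one dataset.  Consensus matrices
are built once per dataset at `consensus_k` clusters, spectral-shifted,
embedded into the N × N union frame with zero rows/columns for missing
observations, and combined by localized MKL k-means with the observation ×
dataset presence mask; missing pairs get weight exactly 0 and each row of Θ
sums to 1 over the observed datasets.

When a range of global K values is supplied, the kernels are held fixed and
the full MKL optimisation runs per candidate (no warm starts, for
reproducibility); each candidate is scored by the average silhouette width
on the feature-space distance induced by its own combined kernel,
d_ij = √(K_ii + K_jj − 2K_ij), ties to the smallest K.  Holding the kernels
fixed while K varies is essential: rebuilding consensus matrices at each
candidate K makes the silhouette degenerate, because a stably merged
coarse clustering yields an exactly binary consensus matrix and a perfect
silhouette of 1.  `consensus_k` defaults to the single requested K; with a
K range it defaults to the stability heuristic per dataset, but in studies
where per-dataset cluster counts are known they should be passed explicitly
(the real-data workflow this mirrors chooses them externally).

## Synthetic benchmarks

`simdata` draws K equal-size clusters (defaults: 6 clusters × 50
observations) in which an observation of cluster k is N(mean, I) with mean
k·s in each of 2 relevant variables and 0 in any of the optional irrelevant
N(0, 1) variables (13 of them reproduce the 15-variable setting).
Separability defaults used across tests and studies are s ∈ {0, 1, 2, 3},
spanning unrecoverable to cleanly separated regimes; adjacent cluster means
are s·√2 apart against unit noise.  Means are placed at k·s without
centring — all clusterers and metrics used are translation-invariant.
Collections share one true partition with independent noise, either at one
s ("similar datasets") or one dataset per s level ("heterogeneous").

What the generator does *not* emulate: non-Gaussian or heavy-tailed
measurement noise, correlated features, unequal cluster sizes, batch
effects, and datasets with genuinely different (nested or conflicting)
partitions.  Passing benchmarks therefore demonstrates correctness of the
machinery and the weighting behaviour under clean Gaussian structure, not
performance on real omics data.

**Study scales.**  The test-suite and `scripts/acceptance.py` run the
studies at desk scale: N = 300 observations, H = 100 consensus resamplings
(H = 30 for the K-selection study), 5–10 seeded repetitions per setting.
These sizes give stable medians for the qualitative claims (equal datasets
get ≈ 25% weight each; the cleanest dataset in a heterogeneous collection
gets the largest weight; combining never loses more than 0.05 ARI against
the best single dataset; silhouette selection recovers K = 6).

## Known limitations

* The two K-selection heuristics disagree and both have documented failure
  modes (stability: stable coarse merges; silhouette: splitting of
  boundary-noise groups).  Neither should be used blindly.
* PAM is exact BUILD + SWAP, a local search: on small random instances it
  occasionally ends one swap from the exhaustive-medoid optimum.
* The weight QP scales as O(M·N²) per iteration and the kernel step as
  O(N³); the pipeline is intended for N up to a few thousand.
* Consensus matrices under observation subsampling are only approximately
  PSD; the spectral shift inflates the diagonal and is logged, but large
  shifts signal an unstable base clustering rather than a numerical issue.
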