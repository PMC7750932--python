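# klic — kernel learning integrative clustering

`klic` is a Python library for **integrative clustering**: finding one global
partition of a set of observations (tumour samples, patients, genes) that are
measured in several different datasets — for example expression, methylation
and copy-number profiles of the same tumours.  It implements two two-step
strategies built on resampled consensus clustering:

* **COCA** (Cluster Of Clusters Analysis).  Each dataset is clustered on its
  own; the per-dataset labels are stacked into a binary *matrix of clusters*
  (MOC) with one row per (dataset, cluster) pair, and consensus clustering of
  the MOC columns yields the global partition.  COCA is *unweighted*: every
  cluster found in step one has the same influence on the result.
* **KLIC** (Kernel Learning Integrative Clustering).  Consensus clustering of
  dataset *m* produces a consensus matrix Δ<sub>m</sub> whose (i, j) entry is
  the fraction of resampled runs co-clustering observations i and j.  Every
  co-clustering matrix is block-diagonal with all-ones blocks, hence positive
  semi-definite, and nonnegative combinations of PSD matrices are PSD — so
  Δ<sub>m</sub> is a valid **kernel matrix**.  KLIC feeds these kernels to
  *localized multiple-kernel k-means*, which alternates

  1. kernel k-means on the combined kernel
     Δ<sub>Θ</sub>(i, j) = Σ<sub>m</sub> θ<sub>im</sub> θ<sub>jm</sub> Δ<sub>m</sub>(i, j),
  2. a convex QP that updates the weights Θ at fixed assignments, with each
     observation's weights constrained to the simplex over the datasets that
     observe it,

  so noisy datasets (and noisy observations within a dataset) are
  down-weighted instead of diluting the result.  Observations missing from a
  dataset simply get weight zero there.

Supporting modules provide the resampled consensus-clustering engine
(`klic.consensus`), kernel machinery with PSD verification and spectral-shift
repair (`klic.mkl`), synthetic Gaussian-cluster benchmarks (`klic.simdata`),
evaluation metrics and CSV I/O (`klic.evalio`), and a thin `klic` command-line
interface (`simulate`, `consensus`, `coca`, `run`, `evaluate`).

## Worked example

`examples/klic_weights.py` integrates three synthetic datasets that share one
true 6-cluster partition but differ in cluster separability *s* (cluster k has
mean k·s in each informative variable, unit variance):

```
per-dataset results (consensus matrix clustered alone vs weight):
  s=0: single-dataset ARI -0.003   mean weight  10.8%
  s=1: single-dataset ARI  0.294   mean weight  14.3%
  s=3: single-dataset ARI  0.906   mean weight  74.9%
combined (KLIC) ARI: 0.906
```

The adjusted Rand index (ARI) is 1 for a perfect match with the true
partition and ~0 at chance level.  The pure-noise dataset (s=0) is
uninformative on its own and receives ~11% of the weight; the clearly
structured dataset (s=3) receives ~75%, and the integrated clustering matches
the best single dataset instead of being dragged down by the noisy ones.
The other scripts in `examples/` show consensus clustering of a single
dataset, COCA, and KLIC on precomputed RBF kernels.

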