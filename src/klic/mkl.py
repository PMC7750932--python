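"""Kernel machinery for integrative clustering.

Contains the pieces of localized multiple-kernel k-means:

* PSD verification and spectral-shift repair of near-kernel matrices,
* RBF kernels,
* kernel k-means via the standard spectral relaxation (kernel PCA +
  row-normalised eigenvectors + k-means discretisation),
* the convex per-sample kernel combination
  ``K_theta(i, j) = sum_m theta_im * theta_jm * K_m(i, j)``,
* the convex QP that updates the per-sample, per-dataset weights at fixed
  cluster assignments, and
* the alternating two-step optimisation that ties them together.

The QP decomposes into M quadratic forms ``theta_m' (K_m o P) theta_m`` with
``P = I - H H'`` the projection complementary to the normalised cluster
indicator H, coupled only by per-row simplex constraints (each observation's
weights sum to one over the datasets observing it).  Since each ``K_m o P``
is a Schur product of PSD matrices it is PSD, and the problem is solved
exactly by an accelerated projected-gradient method with per-row simplex
projection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from collections.abc import Sequence

import numpy as np
from sklearn.cluster import KMeans

from .consensus import ConsensusMatrix, DatasetMatrix, Partition

__all__ = [
    "KernelMatrix",
    "WeightMatrix",
    "MKLState",
    "check_psd",
    "spectral_shift",
    "rbf_kernel",
    "kernel_kmeans",
    "kernel_kmeans_objective",
    "combine_kernels",
    "update_weights_qp",
    "qp_objective",
    "localized_mkl_kmeans",
]

logger = logging.getLogger(__name__)

_SYM_TOL = 1e-8


@dataclass
class KernelMatrix:
    """A symmetric similarity (Gram) matrix with a provenance tag."""

    values: np.ndarray
    source_tag: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape != (n, n):
            raise ValueError("kernel matrix must be square")
        if np.abs(self.values - self.values.T).max(initial=0.0) > 1e-10:
            raise ValueError("kernel matrix is not symmetric within 1e-10")

    @property
    def n_items(self) -> int:
        return self.values.shape[0]


@dataclass
class WeightMatrix:
    """Per-observation, per-dataset kernel weights Theta (N x M).

    Each row sums to one over the datasets in which that observation is
    present; entries for missing (observation, dataset) pairs are exactly 0.
    """

    values: np.ndarray
    observed_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("weights must be an N x M matrix")
        if self.observed_mask is None:
            self.observed_mask = np.ones(self.values.shape, dtype=bool)
        else:
            self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        if self.observed_mask.shape != self.values.shape:
            raise ValueError("observed_mask shape must match weights")
        if (self.values < -1e-9).any():
            raise ValueError("weights must be nonnegative")
        if np.abs(self.values[~self.observed_mask]).max(initial=0.0) > 1e-9:
            raise ValueError("weights of missing observations must be zero")
        sums = self.values.sum(axis=1)
        any_obs = self.observed_mask.any(axis=1)
        if np.abs(sums[any_obs] - 1.0).max(initial=0.0) > 1e-6:
            raise ValueError("each observed row of Theta must sum to 1")


@dataclass
class MKLState:
    """State returned by the alternating localized MKL k-means optimisation."""

    assignment: np.ndarray
    weights: WeightMatrix
    objective_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False


def _as_kernel_array(kernel) -> np.ndarray:
    if isinstance(kernel, (KernelMatrix, ConsensusMatrix)):
        return np.asarray(kernel.values, dtype=float)
    return np.asarray(kernel, dtype=float)


def check_psd(matrix, tol: float = 1e-8) -> tuple[float, bool]:
    """Smallest eigenvalue of a symmetric matrix and whether it is >= -tol."""
    a = _as_kernel_array(matrix)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("matrix must be square")
    if np.abs(a - a.T).max(initial=0.0) > _SYM_TOL:
        raise ValueError("matrix is not symmetric within 1e-8")
    min_eig = float(np.linalg.eigvalsh((a + a.T) / 2.0)[0])
    return min_eig, min_eig >= -tol


def spectral_shift(matrix, tol: float = 1e-8, source_tag: str = "") -> KernelMatrix:
    """Repair a near-PSD matrix by adding ``-min_eig * I`` when needed.

    PSD inputs pass through unchanged; otherwise the diagonal is inflated by
    the magnitude of the most negative eigenvalue, which leaves eigenvectors
    (and hence any clustering derived from them) untouched.
    """
    a = _as_kernel_array(matrix)
    min_eig, is_psd = check_psd(a, tol=tol)
    a = (a + a.T) / 2.0
    if not is_psd:
        logger.info("spectral_shift: inflating diagonal by %.3e (%s)", -min_eig,
                    source_tag or "unnamed kernel")
        a = a + (-min_eig) * np.eye(a.shape[0])
    return KernelMatrix(a, source_tag=source_tag)


def rbf_kernel(data: DatasetMatrix | np.ndarray, sigma: float = 1.0) -> KernelMatrix:
    """Radial basis function kernel ``exp(-||x_i - x_j||^2 / (2 sigma^2))``."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x = data.values if isinstance(data, DatasetMatrix) else np.asarray(data, dtype=float)
    sq = (x**2).sum(axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * x @ x.T, 0.0)
    values = np.exp(-d2 / (2.0 * sigma**2))
    np.fill_diagonal(values, 1.0)
    return KernelMatrix((values + values.T) / 2.0, source_tag=f"rbf:sigma={sigma:g}")


def _normalized_indicator(labels: np.ndarray, K: int) -> np.ndarray:
    """N x K indicator with columns scaled to unit norm (orthonormal)."""
    n = labels.shape[0]
    h = np.zeros((n, K))
    for k in range(1, K + 1):
        members = labels == k
        cnt = members.sum()
        if cnt:
            h[members, k - 1] = 1.0 / np.sqrt(cnt)
    return h


def kernel_kmeans_objective(kernel, partition: Partition | np.ndarray) -> float:
    """Within-cluster sum of squares in feature space: tr(K) - tr(H'KH)."""
    a = _as_kernel_array(kernel)
    labels = partition.labels if isinstance(partition, Partition) else np.asarray(partition)
    K = int(labels.max())
    h = _normalized_indicator(labels, K)
    return float(np.trace(a) - np.trace(h.T @ a @ h))


def _lloyd_refine(a: np.ndarray, labels: np.ndarray, K: int,
                  max_iter: int = 100) -> np.ndarray:
    """Exact kernel k-means Lloyd iterations from an initial labelling.

    Each sweep reassigns every point to the cluster minimising its squared
    feature-space distance to the cluster mean, computed from the Gram
    matrix alone; the objective decreases monotonically.  A cluster that
    empties is re-seeded from the currently worst-fitting point.
    """
    n = a.shape[0]
    labels = labels.copy()
    for _ in range(max_iter):
        # cost[i, k] = -2/n_k sum_{j in k} K_ij + 1/n_k^2 sum_{j,l in k} K_jl
        cost = np.full((n, K), np.inf)
        for k in range(1, K + 1):
            members = labels == k
            nk = int(members.sum())
            if nk == 0:
                continue
            col = a[:, members].sum(axis=1)
            within = a[np.ix_(members, members)].sum()
            cost[:, k - 1] = -2.0 * col / nk + within / nk**2
        new_labels = np.argmin(cost, axis=1) + 1
        for k in range(1, K + 1):  # re-seed emptied clusters
            if not (new_labels == k).any():
                own = cost[np.arange(n), new_labels - 1]
                worst = int(np.argmax(own))
                new_labels[worst] = k
                own[worst] = -np.inf
        if (new_labels == labels).all():
            break
        labels = new_labels
    return labels


def _hartigan_refine(a: np.ndarray, labels: np.ndarray, K: int,
                     max_sweeps: int = 100) -> np.ndarray:
    """First-improvement single-point moves with exact objective deltas.

    Unlike batch Lloyd sweeps, the move criterion accounts for the cluster
    means shifting when a point leaves/joins, so minima that isolate small
    or singleton clusters are reachable.  Clusters are never emptied.
    """
    n = a.shape[0]
    labels = labels.copy()
    onehot = np.zeros((n, K))
    onehot[np.arange(n), labels - 1] = 1.0
    colsums = a @ onehot                       # colsums[i, k] = sum_{j in k} K_ij
    counts = onehot.sum(axis=0)
    within = np.array([colsums[labels == k + 1, k].sum() for k in range(K)])
    for _ in range(max_sweeps):
        moved = False
        for i in range(n):
            p = labels[i] - 1
            n_p = counts[p]
            if n_p <= 1:
                continue
            w_p_new = within[p] - 2.0 * colsums[i, p] + a[i, i]
            gain_p = (-w_p_new / (n_p - 1)) - (-within[p] / n_p)
            w_q_new = within + 2.0 * colsums[i] + a[i, i]
            gain_q = (-w_q_new / (counts + 1)) - (-within / counts)
            delta = gain_p + gain_q
            delta[p] = 0.0
            q = int(np.argmin(delta))
            if delta[q] < -1e-10:
                labels[i] = q + 1
                counts[p] -= 1
                counts[q] += 1
                within[p] = w_p_new
                within[q] = w_q_new[q]
                colsums[:, p] -= a[:, i]
                colsums[:, q] += a[:, i]
                moved = True
        if not moved:
            break
    return labels


def kernel_kmeans(kernel, K: int, seed: int = 0, n_restarts: int = 10) -> Partition:
    """Kernel k-means via spectral relaxation plus Lloyd refinement.

    The K leading eigenvectors of the kernel (kernel PCA directions) are
    row-normalised to unit length (all-zero rows left at zero) and
    discretised with seeded Euclidean k-means; each restart's labelling is
    then refined by exact kernel-space Lloyd iterations and the labelling
    with the lowest within-cluster sum of squares is returned.  Eigenvectors
    are ordered by descending eigenvalue with the sign fixed so the first
    nonzero component is positive, making the output deterministic given the
    seed.
    """
    a = _as_kernel_array(kernel)
    a = (a + a.T) / 2.0
    n = a.shape[0]
    if not (1 <= K <= n):
        raise ValueError(f"K={K} must be in 1..{n}")
    if K == 1:
        return Partition(labels=np.ones(n, dtype=int), K=1)
    try:
        _, v = np.linalg.eigh(a)
    except np.linalg.LinAlgError as exc:
        raise RuntimeError(f"eigendecomposition failed for {n}x{n} kernel: {exc}") from exc
    e = v[:, ::-1][:, :K]
    for j in range(K):
        col = e[:, j]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            e[:, j] = -col
    norms = np.linalg.norm(e, axis=1)
    rows = norms > 1e-12
    e[rows] /= norms[rows, None]
    seeds = np.random.SeedSequence([int(seed) % (2**31 - 1)]).generate_state(2 * n_restarts)
    rng = np.random.default_rng(seeds[-1])
    best_labels, best_obj = None, np.inf
    for r, rs in enumerate(seeds[:-1]):
        if r < n_restarts:  # spectral-embedding starts
            km = KMeans(n_clusters=K, n_init=1, max_iter=300,
                        random_state=int(rs % (2**31 - 1)))
            init = km.fit_predict(e) + 1
        else:  # uniform random starts for basin diversity
            init = rng.integers(1, K + 1, size=n)
            init[rng.permutation(n)[:K]] = np.arange(1, K + 1)
        labels = _hartigan_refine(a, _lloyd_refine(a, init, K), K)
        obj = kernel_kmeans_objective(a, labels)
        if obj < best_obj - 1e-12:
            best_labels, best_obj = labels, obj
    assert best_labels is not None
    return Partition(labels=best_labels, K=K)


def combine_kernels(kernels: Sequence, weights: WeightMatrix | np.ndarray) -> KernelMatrix:
    """Per-sample convex combination ``sum_m theta_im theta_jm K_m(i, j)``."""
    mats = [_as_kernel_array(k) for k in kernels]
    theta = weights.values if isinstance(weights, WeightMatrix) else np.asarray(weights, dtype=float)
    n = mats[0].shape[0]
    if theta.shape != (n, len(mats)):
        raise ValueError(f"weights shape {theta.shape} does not match "
                         f"{len(mats)} kernels of size {n}")
    out = np.zeros((n, n))
    for m, km in enumerate(mats):
        if km.shape != (n, n):
            raise ValueError(f"kernel {m} has shape {km.shape}, expected {(n, n)}")
        out += np.outer(theta[:, m], theta[:, m]) * km
    return KernelMatrix((out + out.T) / 2.0, source_tag="combined")


def _project_rows_to_simplex(v: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row of ``v`` onto the probability simplex
    supported on the True entries of ``mask``; masked entries are set to 0."""
    n, m = v.shape
    x = np.where(mask, v, -np.inf)
    u = np.sort(x, axis=1)[:, ::-1]
    finite = np.isfinite(u)
    cssv = np.cumsum(np.where(finite, u, 0.0), axis=1) - 1.0
    idx = np.arange(1, m + 1)
    cond = finite & (u - cssv / idx > 0)
    rho = np.maximum(cond.sum(axis=1), 1)
    tau = cssv[np.arange(n), rho - 1] / rho
    out = np.maximum(v - tau[:, None], 0.0)
    out[~mask] = 0.0
    return out


def _qp_matrices(kernels: Sequence, assignment: np.ndarray, ridge: float) -> np.ndarray:
    mats = [_as_kernel_array(k) for k in kernels]
    n = mats[0].shape[0]
    h = np.asarray(assignment, dtype=float)
    proj = np.eye(n) - h @ h.T
    qs = np.empty((len(mats), n, n))
    for m, km in enumerate(mats):
        q = km * proj
        qs[m] = (q + q.T) / 2.0
    return qs + ridge * np.eye(n)


def qp_objective(kernels: Sequence, assignment: np.ndarray,
                 weights: WeightMatrix | np.ndarray) -> float:
    """Weight-step objective ``sum_m theta_m' (K_m o (I - HH')) theta_m``.

    Equals ``tr(K_theta) - tr(H' K_theta H)``, the kernel k-means objective
    of the combined kernel at assignment H, so both alternating steps
    optimise the same quantity.
    """
    theta = weights.values if isinstance(weights, WeightMatrix) else np.asarray(weights, dtype=float)
    qs = _qp_matrices(kernels, assignment, ridge=0.0)
    return float(sum(theta[:, m] @ qs[m] @ theta[:, m] for m in range(qs.shape[0])))


def update_weights_qp(
    kernels: Sequence,
    assignment: np.ndarray,
    observed_mask: np.ndarray | None = None,
    ridge: float = 1e-10,
    tol: float = 1e-7,
    max_iter: int = 3000,
    init: np.ndarray | None = None,
) -> WeightMatrix:
    """Solve the convex weight-update QP at fixed cluster assignments.

    Minimises ``sum_m theta_m' Q_m theta_m`` with ``Q_m = K_m o (I - HH')``
    subject to each observation's weights lying on the simplex over its
    observed datasets (and exactly 0 elsewhere).  Each Q_m is a Schur
    product of PSD matrices, hence PSD (asserted); a tiny ridge keeps the
    solver strictly convex so the minimal-norm optimum is returned when the
    minimiser is not unique.  Solved by FISTA with exact per-row simplex
    projection.
    """
    qs = _qp_matrices(kernels, assignment, ridge=ridge)
    n_kernels, n = qs.shape[0], qs.shape[1]
    if observed_mask is None:
        observed_mask = np.ones((n, n_kernels), dtype=bool)
    else:
        observed_mask = np.asarray(observed_mask, dtype=bool)
        if observed_mask.shape != (n, n_kernels):
            raise ValueError("observed_mask must be N x M")

    eig_bounds = [np.linalg.eigvalsh(q) for q in qs]
    min_eig = min(e[0] for e in eig_bounds)
    if min_eig < -1e-8:
        raise RuntimeError(
            f"QP block unexpectedly indefinite (min eigenvalue {min_eig:.3e}); "
            "input kernels are not PSD")
    lipschitz = 2.0 * max(e[-1] for e in eig_bounds)
    if lipschitz <= 0:
        lipschitz = 1.0

    if init is not None:
        theta = _project_rows_to_simplex(np.asarray(init, dtype=float), observed_mask)
    else:
        counts = np.maximum(observed_mask.sum(axis=1), 1)
        theta = observed_mask / counts[:, None]

    def grad(t: np.ndarray) -> np.ndarray:
        return 2.0 * np.stack([qs[m] @ t[:, m] for m in range(n_kernels)], axis=1)

    def objective(t: np.ndarray) -> float:
        return float(sum(t[:, m] @ qs[m] @ t[:, m] for m in range(n_kernels)))

    y, t_mom = theta.copy(), 1.0
    f_prev = np.inf
    for it in range(1, max_iter + 1):
        theta_new = _project_rows_to_simplex(y - grad(y) / lipschitz, observed_mask)
        t_next = (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2)) / 2.0
        y = theta_new + ((t_mom - 1.0) / t_next) * (theta_new - theta)
        theta, t_mom = theta_new, t_next
        if it % 10 == 0 or it == max_iter:
            f = objective(theta)
            if f > f_prev:  # momentum restart keeps the iteration monotone
                y, t_mom = theta.copy(), 1.0
            f_prev = f
            # stop on the gradient-mapping residual (optimality measure)
            step = _project_rows_to_simplex(theta - grad(theta) / lipschitz,
                                            observed_mask)
            if np.abs(step - theta).max() <= tol:
                break
    return WeightMatrix(theta, observed_mask=observed_mask)


def localized_mkl_kmeans(
    kernels: Sequence,
    K: int,
    observed_mask: np.ndarray | None = None,
    tol: float = 1e-5,
    max_iter: int = 100,
    seed: int = 0,
) -> tuple[MKLState, Partition]:
    """Localized multiple-kernel k-means with per-sample dataset weights.

    Starting from uniform weights over each observation's observed datasets,
    alternate (i) kernel k-means on the combined kernel at fixed weights and
    (ii) the convex QP weight update at fixed assignments.  Convergence is
    declared when the relative change of the shared objective falls within
    ``tol``; because the assignment step discretises a spectral relaxation
    the trace need not be monotone, so the best-objective iterate is the one
    returned.
    """
    mats = [_as_kernel_array(k) for k in kernels]
    if not mats:
        raise ValueError("need at least one kernel")
    n = mats[0].shape[0]
    n_kernels = len(mats)
    if observed_mask is None:
        observed_mask = np.ones((n, n_kernels), dtype=bool)
    else:
        observed_mask = np.asarray(observed_mask, dtype=bool)
    counts = observed_mask.sum(axis=1)
    if (counts == 0).any():
        raise ValueError("every observation must be present in at least one dataset")
    theta = observed_mask / counts[:, None]

    trace: list[float] = []
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    last_obj = np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        combined = combine_kernels(mats, theta)
        if np.abs(combined.values).max() <= 1e-12:
            raise ValueError("combined kernel is identically zero")
        part = kernel_kmeans(combined, K, seed=seed)
        h = _normalized_indicator(part.labels, K)
        obj = float(np.trace(combined.values) - np.trace(h.T @ combined.values @ h))
        trace.append(obj)
        if best is None or obj < best[0]:
            best = (obj, part.labels.copy(), theta.copy())
        rel = np.inf if not np.isfinite(last_obj) else abs(obj - last_obj) / max(abs(last_obj), 1e-12)
        if rel <= tol:
            converged = True
            break
        weights = update_weights_qp(mats, h, observed_mask=observed_mask, init=theta)
        theta = weights.values
        last_obj = obj

    assert best is not None
    _, labels, theta_best = best
    assignment = np.zeros((n, K), dtype=int)
    assignment[np.arange(n), labels - 1] = 1
    state = MKLState(
        assignment=assignment,
        weights=WeightMatrix(theta_best, observed_mask=observed_mask),
        objective_trace=trace,
        n_iter=n_iter,
        converged=converged,
    )
    return state, Partition(labels=labels, K=K)
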