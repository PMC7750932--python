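import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_psd_kernel(rng: np.random.Generator, n: int) -> np.ndarray:
    b = rng.standard_normal((n, n))
    return b @ b.T


def random_partition_labels(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """Random labels in 1..k with every cluster nonempty."""
    labels = rng.integers(1, k + 1, size=n)
    labels[rng.permutation(n)[:k]] = np.arange(1, k + 1)
    return labels


def grid_search_qp_oracle(kernels, h, coarse_step=0.01, fine_step=0.001):
    """Independent brute-force oracle for the N=3, M=2 weight QP.

    Exhaustive 0.01-step search over each row's share of kernel 1, then a
    0.001-step refinement around the coarse optimum (the coarse grid alone
    carries O(step^2) objective error).
    """
    proj = np.eye(3) - h @ h.T
    q1, q2 = kernels[0] * proj, kernels[1] * proj

    def evaluate(t1):
        return (np.einsum("ai,ij,aj->a", t1, q1, t1)
                + np.einsum("ai,ij,aj->a", 1 - t1, q2, 1 - t1))

    grid = np.arange(0.0, 1.0 + 1e-12, coarse_step)
    t1 = np.array(np.meshgrid(grid, grid, grid)).reshape(3, -1).T
    values = evaluate(t1)
    center = t1[int(np.argmin(values))]
    axes = [np.clip(np.arange(c - coarse_step, c + coarse_step + 1e-12, fine_step),
                    0.0, 1.0) for c in center]
    t1 = np.array(np.meshgrid(*axes)).reshape(3, -1).T
    return float(min(values.min(), evaluate(t1).min()))
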