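"""Evaluation metrics and file I/O shared by all pipeline stages.

Metrics: the Hubert–Arabie adjusted Rand index (chance-corrected partition
agreement) and Rousseeuw silhouette widths (with the common convention that
singleton clusters score 0), plus the simulation-only oracle that tunes the
RBF kernel width against known true labels.

I/O: CSV readers/writers for data matrices, kernel matrices and label
tables (comma-separated, header row, first column the observation ID), and
a JSON run manifest recording seeds, parameters and package versions.
"""

from __future__ import annotations

import json
import platform
from collections.abc import Sequence
from pathlib import Path

import numpy as np
import pandas as pd
import sklearn
from sklearn import metrics as _skmetrics

from .consensus import DatasetMatrix, Partition

__all__ = [
    "adjusted_rand_index",
    "silhouette_widths",
    "tune_rbf_sigma",
    "read_matrix_csv",
    "read_kernel_csv",
    "write_matrix_csv",
    "write_kernel_csv",
    "read_labels_csv",
    "write_labels_csv",
    "write_run_manifest",
]


def _labels_and_mask(p) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(p, Partition):
        return p.labels, p.included_mask
    labels = np.asarray(p, dtype=int)
    return labels, np.ones(labels.shape[0], dtype=bool)


def adjusted_rand_index(a, b) -> float:
    """Hubert–Arabie adjusted Rand index between two partitions.

    Equals 1 for identical partitions (up to relabelling) and is 0 in
    expectation for independent partitions under the permutation model.
    Partitions with ``included_mask`` are compared on their common items.
    """
    la, ma = _labels_and_mask(a)
    lb, mb = _labels_and_mask(b)
    if la.shape[0] != lb.shape[0]:
        raise ValueError("partitions cover different numbers of observations")
    common = ma & mb
    if common.sum() < 2:
        raise ValueError("need at least 2 common observations to compare partitions")
    return float(_skmetrics.adjusted_rand_score(la[common], lb[common]))


def silhouette_widths(labels, distance: np.ndarray) -> tuple[np.ndarray, float]:
    """Rousseeuw silhouette widths s(i) = (b_i - a_i) / max(a_i, b_i).

    ``a_i`` is the mean distance of item i to the rest of its cluster and
    ``b_i`` the smallest mean distance to another cluster.  Items in
    singleton clusters score 0; with fewer than two clusters every width is
    0 (not an error).  Returns (per-item widths, average width).
    """
    lab, mask = _labels_and_mask(labels)
    distance = np.asarray(distance, dtype=float)
    n = lab.shape[0]
    if distance.shape != (n, n):
        raise ValueError(f"distance matrix shape {distance.shape}, expected {(n, n)}")
    if np.abs(np.diag(distance)).max(initial=0.0) > 1e-8:
        raise ValueError("distance matrix must have a zero diagonal")
    if np.abs(distance - distance.T).max(initial=0.0) > 1e-8:
        raise ValueError("distance matrix must be symmetric")
    if not mask.all():
        raise ValueError("silhouette requires a full partition (no excluded items)")
    uniq = np.unique(lab)
    if uniq.size < 2 or uniq.size >= n:
        return np.zeros(n), 0.0
    widths = _skmetrics.silhouette_samples(distance, lab, metric="precomputed")
    widths = np.asarray(widths, dtype=float)
    return widths, float(widths.mean())


def tune_rbf_sigma(
    data: DatasetMatrix,
    true_labels,
    sigma_grid: Sequence[float],
    K: int,
    seed: int = 0,
    n_repeats: int = 5,
) -> float:
    """Oracle RBF width selection for simulation studies.

    For each grid value, runs kernel k-means on the RBF kernel ``n_repeats``
    times with derived seeds and scores the mean ARI against the known true
    labels; returns the sigma with the highest mean ARI (ties to the
    smallest sigma).  Usable only when the truth is known, i.e. to compute
    an upper bound for the RBF comparator in simulations.
    """
    from .mkl import kernel_kmeans, rbf_kernel  # local import to avoid a cycle

    grid = sorted(float(s) for s in sigma_grid)
    if not grid:
        raise ValueError("sigma_grid is empty")
    truth, _ = _labels_and_mask(true_labels)
    best_sigma, best_score = grid[0], -np.inf
    for sigma in grid:
        kern = rbf_kernel(data, sigma=sigma)
        scores = []
        for r in range(n_repeats):
            rep_seed = int(np.random.SeedSequence([seed, r]).generate_state(1)[0] % (2**31 - 1))
            part = kernel_kmeans(kern, K, seed=rep_seed)
            scores.append(adjusted_rand_index(part, Partition(truth, K=int(truth.max()))))
        mean_score = float(np.mean(scores))
        if mean_score > best_score + 1e-12:
            best_sigma, best_score = sigma, mean_score
    return best_sigma


# ---------------------------------------------------------------------------
# CSV / JSON I/O


def _read_frame(path) -> pd.DataFrame:
    try:
        frame = pd.read_csv(path, index_col=0, float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"could not parse {path}: {exc}") from exc
    if frame.index.has_duplicates:
        dupes = frame.index[frame.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate observation IDs {dupes[:5]}")
    return frame


def read_matrix_csv(path) -> DatasetMatrix:
    """Read an observations x features CSV (first column = observation ID)."""
    frame = _read_frame(path)
    try:
        values = frame.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        bad = [c for c in frame.columns
               if not np.issubdtype(pd.to_numeric(frame[c], errors="coerce").dtype, np.number)
               or pd.to_numeric(frame[c], errors="coerce").isna().any()]
        raise ValueError(f"{path}: non-numeric cells in columns {bad[:5]}") from exc
    return DatasetMatrix(values,
                         obs_ids=tuple(map(str, frame.index)),
                         feature_names=tuple(map(str, frame.columns)))


def read_kernel_csv(path) -> tuple[np.ndarray, tuple[str, ...]]:
    """Read a square kernel/consensus CSV; header and index must agree."""
    frame = _read_frame(path)
    ids = tuple(map(str, frame.index))
    cols = tuple(map(str, frame.columns))
    if ids != cols:
        raise ValueError(f"{path}: kernel header and index disagree "
                         f"(first mismatch at position "
                         f"{next(i for i, (a, b) in enumerate(zip(ids, cols)) if a != b)})")
    return frame.to_numpy(dtype=float), ids


def write_matrix_csv(path, values: np.ndarray, obs_ids: Sequence[str],
                     feature_names: Sequence[str]) -> None:
    """Write a matrix CSV with observation IDs as index."""
    frame = pd.DataFrame(np.asarray(values), index=list(obs_ids),
                         columns=list(feature_names))
    frame.index.name = "obs_id"
    frame.to_csv(path, float_format="%.17g")


def write_kernel_csv(path, values: np.ndarray, obs_ids: Sequence[str]) -> None:
    """Write a square matrix CSV with observation IDs as header and index."""
    write_matrix_csv(path, values, obs_ids, obs_ids)


def read_labels_csv(path) -> tuple[np.ndarray, tuple[str, ...]]:
    """Read a labels CSV with columns (obs_id, cluster)."""
    frame = _read_frame(path)
    col = frame.columns[0]
    labels = pd.to_numeric(frame[col], errors="coerce")
    if labels.isna().any():
        bad = frame.index[labels.isna()].tolist()
        raise ValueError(f"{path}: non-numeric cluster labels at rows {bad[:5]}")
    return labels.to_numpy(dtype=int), tuple(map(str, frame.index))


def write_labels_csv(path, labels: np.ndarray, obs_ids: Sequence[str]) -> None:
    frame = pd.DataFrame({"cluster": np.asarray(labels, dtype=int)},
                         index=list(obs_ids))
    frame.index.name = "obs_id"
    frame.to_csv(path)


def write_run_manifest(path, parameters: dict) -> None:
    """Record run parameters plus package versions for reproducibility."""
    manifest = {
        "parameters": parameters,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
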