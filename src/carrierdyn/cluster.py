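"""Pairwise-RMSD matrices and gromos clustering with centroid extraction.

The gromos scheme is greedy neighbor counting on a pairwise RMSD matrix:
the frame with the most unassigned neighbors within the cutoff seeds each
cluster (it becomes the centroid), it and its neighbors are removed, and
the procedure repeats until every frame is assigned.  Ties on neighbor
count break toward the lowest frame index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geomcore import kabsch_superpose
from .structio import Trajectory

__all__ = [
    "DistanceMatrix",
    "ClusterResult",
    "pairwise_rmsd_matrix",
    "gromos_cluster",
    "representative",
    "cutoff_scan",
]


@dataclass
class DistanceMatrix:
    n_frames: int
    values: np.ndarray
    selection: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.shape != (self.n_frames, self.n_frames):
            raise ValueError("matrix shape must be (n_frames, n_frames)")
        if not np.allclose(v, v.T, atol=1e-9) or np.any(np.diag(v) != 0) or np.any(v < 0):
            raise ValueError("matrix must be symmetric, zero-diagonal, non-negative")
        self.values = v

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values)


@dataclass
class ClusterResult:
    """1-based per-frame labels in extraction order, centroids and sizes."""

    labels: np.ndarray
    centroids: list[int]
    sizes: list[int]
    cutoff: float

    def __post_init__(self) -> None:
        if sum(self.sizes) != len(self.labels):
            raise ValueError("cluster sizes must sum to the frame count")

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Cluster": np.arange(1, self.n_clusters + 1),
                "Size": self.sizes,
                "CentroidFrame": self.centroids,
            }
        )


def pairwise_rmsd_matrix(
    traj: Trajectory, selection: np.ndarray, drop_first: int = 0
) -> DistanceMatrix:
    """Kabsch-superposed RMSD between every frame pair on a selection.

    ``drop_first`` discards the leading (pre-equilibration) frames before
    building the matrix.
    """
    selection = np.asarray(selection, int)
    if selection.size == 0:
        raise ValueError("empty selection")
    coords = traj.coordinates[drop_first:, selection, :]
    n = len(coords)
    if n < 2:
        raise ValueError("need at least 2 frames after trimming")
    # Precenter once; pairwise fitted RMSD from SVD singular values:
    # rmsd_ij^2 = (|A|^2 + |B|^2 - 2 * sum(corrected singular values)) / N
    centered = coords - coords.mean(axis=1, keepdims=True)
    sq = np.einsum("fij,fij->f", centered, centered)
    n_atoms = len(selection)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            h = centered[i].T @ centered[j]
            s = np.linalg.svd(h, compute_uv=False)
            if np.linalg.det(h) < 0:
                s[-1] = -s[-1]
            msd = (sq[i] + sq[j] - 2.0 * s.sum()) / n_atoms
            values[i, j] = values[j, i] = np.sqrt(max(msd, 0.0))
    return DistanceMatrix(n_frames=n, values=values, selection=selection)


def gromos_cluster(matrix: DistanceMatrix, cutoff: float) -> ClusterResult:
    """Greedy neighbor-count clustering of a pairwise RMSD matrix."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    n = matrix.n_frames
    within = matrix.values <= cutoff
    np.fill_diagonal(within, False)
    unassigned = np.ones(n, bool)
    labels = np.zeros(n, int)
    centroids: list[int] = []
    sizes: list[int] = []
    label = 0
    while unassigned.any():
        label += 1
        counts = np.where(unassigned, (within & unassigned).sum(axis=1), -1)
        center = int(np.argmax(counts))  # first max: lowest-index tiebreak
        members = within[center] & unassigned
        members[center] = True
        labels[members] = label
        centroids.append(center)
        sizes.append(int(members.sum()))
        unassigned &= ~members
    return ClusterResult(labels=labels, centroids=centroids, sizes=sizes, cutoff=cutoff)


def representative(result: ClusterResult) -> int:
    """Centroid frame of the most populated cluster (ties: first extracted)."""
    if result.n_clusters < 1:
        raise ValueError("no clusters")
    best = int(np.argmax(result.sizes))  # first max: earliest extraction wins
    return result.centroids[best]


def cutoff_scan(matrix: DistanceMatrix, cutoffs: np.ndarray) -> pd.DataFrame:
    """Cluster counts per cutoff, to support rule-of-thumb cutoff choice."""
    rows = []
    for c in np.asarray(cutoffs, float):
        res = gromos_cluster(matrix, float(c))
        rows.append(
            {
                "Cutoff": float(c),
                "NClusters": res.n_clusters,
                "NSingletons": int(sum(1 for s in res.sizes if s == 1)),
            }
        )
    return pd.DataFrame(rows, columns=["Cutoff", "NClusters", "NSingletons"])
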