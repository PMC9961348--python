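"""Superposition, RMSD/RMSF, aromatic-ring geometry and pairwise alignment.

Rigid-body fitting uses the Kabsch algorithm (SVD of the paired covariance,
reflection-corrected).  The RMSF follows the usual trajectory convention:
frames are superposed onto the average structure, the average is recomputed,
frames are fitted once more, and the per-atom fluctuation is measured about
the final mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .structio import Trajectory

__all__ = [
    "SuperpositionResult",
    "RingGeometry",
    "PairAlignment",
    "RankDeficiencyError",
    "kabsch_superpose",
    "paired_rmsd",
    "rmsf",
    "ring_geometry",
    "align_sequences",
]


class RankDeficiencyError(ValueError):
    """Point set is (near-)collinear; the rotation is under-determined."""


@dataclass(frozen=True)
class SuperpositionResult:
    """A proper rigid transform mapping mobile onto reference.

    ``transformed = mobile @ rotation.T + translation`` minimizes the paired
    RMSD; ``rmsd`` is evaluated after the transform.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_pairs: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


@dataclass(frozen=True)
class RingGeometry:
    centroid: np.ndarray
    normal: np.ndarray
    ring_atom_names: tuple[str, ...] = ()


@dataclass(frozen=True)
class PairAlignment:
    """Matched (non-gap) residue pairs of a global pairwise alignment."""

    pairs: tuple[tuple[int, int], ...]
    score: float

    def __post_init__(self) -> None:
        for (a0, b0), (a1, b1) in zip(self.pairs, self.pairs[1:]):
            if a1 <= a0 or b1 <= b0:
                raise ValueError("alignment pairs must be strictly increasing")


def _check_rank(points: np.ndarray, what: str) -> None:
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] <= 1e-8 * max(s[0], 1.0):
        raise RankDeficiencyError(f"{what} point set is collinear or degenerate")


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Least-squares proper rigid transform of ``mobile`` onto ``reference``.

    Raises for fewer than three pairs or collinear point sets, where the
    rotation would be under-determined.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape:
        raise ValueError("mobile and reference must have the same shape")
    n = len(mobile)
    if n < 3:
        raise ValueError(f"superposition needs at least 3 pairs, got {n}")
    _check_rank(mobile, "mobile")
    _check_rank(reference, "reference")

    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    a = mobile - mc
    b = reference - rc
    h = a.T @ b
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    translation = rc - rotation @ mc
    moved = mobile @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return SuperpositionResult(rotation, translation, rmsd, n)


def paired_rmsd(a: np.ndarray, b: np.ndarray, superpose: bool = False) -> float:
    """RMSD over paired coordinates, optionally after a Kabsch fit."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("coordinate arrays must have the same shape")
    if len(a) == 0:
        raise ValueError("empty selection: no pairs to compare")
    if superpose:
        return kabsch_superpose(a, b).rmsd
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def rmsf(
    traj: Trajectory,
    selection: np.ndarray | None = None,
    fit_selection: np.ndarray | None = None,
) -> np.ndarray:
    """Per-atom root-mean-square fluctuation about the fitted mean structure.

    Frames are superposed onto the running mean structure and the mean is
    recomputed, iterating until the mean stops moving (1e-10 Å, at most ten
    passes — rigid-plus-jitter data converges by the third).  ``selection``
    picks the atoms reported; ``fit_selection`` (default: the same atoms)
    picks the atoms defining the superposition, the usual way to measure a
    flexible region's fluctuation in the frame of a rigid core.
    """
    if traj.frame_count < 2:
        raise ValueError("RMSF needs at least 2 frames")
    coords = traj.coordinates
    if selection is None:
        selection = np.arange(traj.topology.n_atoms)
    selection = np.asarray(selection, int)
    fit = selection if fit_selection is None else np.asarray(fit_selection, int)
    fitted = coords
    previous_mean = None
    for _ in range(10):
        reference = fitted[:, fit, :].mean(axis=0)
        fitted = np.stack(
            [
                kabsch_superpose(frame[fit], reference).apply(frame)
                for frame in fitted
            ]
        )
        mean = fitted[:, fit, :].mean(axis=0)
        if previous_mean is not None and np.abs(mean - previous_mean).max() < 1e-10:
            break
        previous_mean = mean
    sub = fitted[:, selection, :]
    mean = sub.mean(axis=0)
    return np.sqrt(np.mean(np.sum((sub - mean) ** 2, axis=2), axis=0))


def ring_geometry(
    ring_coords: np.ndarray, ring_atom_names: tuple[str, ...] = ()
) -> RingGeometry:
    """Centroid and unit normal of an (approximately planar) ring.

    The normal is the eigenvector of the smallest covariance eigenvalue,
    canonicalized to a positive z-component (positive x if z vanishes).
    """
    coords = np.asarray(ring_coords, float)
    if len(coords) < 3:
        raise ValueError("ring geometry needs at least 3 atoms")
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    _u, _s, vt = np.linalg.svd(centered)
    normal = vt[-1]
    if abs(normal[2]) > 1e-12:
        if normal[2] < 0:
            normal = -normal
    elif normal[0] < 0:
        normal = -normal
    return RingGeometry(centroid, normal / np.linalg.norm(normal), ring_atom_names)


def align_sequences(
    seq_a: str,
    seq_b: str,
    open_gap: float = 10.0,
    extend_gap: float = 1.0,
) -> PairAlignment:
    """Global Needleman–Wunsch alignment (BLOSUM62, affine gaps).

    Returns the matched residue index pairs used to pair Cα atoms across
    homologous structures.  An empty sequence yields zero pairs.
    """
    if not seq_a or not seq_b:
        return PairAlignment(pairs=(), score=0.0)
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = -abs(open_gap)
    aligner.extend_gap_score = -abs(extend_gap)
    alignment = aligner.align(seq_a.upper(), seq_b.upper())[0]
    pairs: list[tuple[int, int]] = []
    for (a_start, a_end), (b_start, b_end) in zip(*alignment.aligned):
        for off in range(a_end - a_start):
            pairs.append((a_start + off, b_start + off))
    return PairAlignment(pairs=tuple(pairs), score=float(alignment.score))
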