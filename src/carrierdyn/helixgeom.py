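"""Local helix axes, bending profiles and kink localization.

The axis construction is the HELANAL-style sliding window of four
consecutive Cα atoms: the two bisector vectors at the inner pair of
residues point toward the helix axis, and their cross product gives the
local axis direction.  Bending between consecutive window axes localizes a
kink; the single per-helix bending angle is the angle between the mean axes
of the first and last thirds of the windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structio import HelixDefinition, Trajectory, select

__all__ = [
    "HelixAxisProfile",
    "local_axes",
    "bending_profile",
    "trajectory_profile",
    "profile_report",
]


@dataclass
class HelixAxisProfile:
    """Per-window axes and bend angles of one helix (one frame or a mean)."""

    helix: HelixDefinition
    window_axes: np.ndarray          # (n_residues - 3, 3) unit vectors
    local_bends: np.ndarray          # degrees between consecutive axes
    global_bend: float               # degrees, first-third vs last-third mean axes
    kink_position: tuple[int, int]   # author-numbered residue boundary (i, i+1)
    frame: int | str = 0             # frame index or "mean"

    @property
    def max_local_bend(self) -> float:
        return float(self.local_bends.max()) if len(self.local_bends) else 0.0


def local_axes(ca_coords: np.ndarray) -> np.ndarray:
    """Unit local-axis vectors from sliding four-Cα windows.

    For window residues P1..P4, the bisectors V1 = (P1-P2)+(P3-P2) and
    V2 = (P2-P3)+(P4-P3) both point radially toward the axis; their cross
    product is the local axis, sign-canonicalized to run N→C.
    Straight-line (untwisted) input is degenerate and raises.
    """
    ca = np.asarray(ca_coords, float)
    n = len(ca)
    if n < 4:
        raise ValueError(f"need at least 4 Cα positions, got {n}")
    p1, p2, p3, p4 = ca[:-3], ca[1:-2], ca[2:-1], ca[3:]
    v1 = (p1 - p2) + (p3 - p2)
    v2 = (p2 - p3) + (p4 - p3)
    axes = np.cross(v1, v2)
    norms = np.linalg.norm(axes, axis=1)
    scale = max(np.linalg.norm(ca[-1] - ca[0]), 1.0)
    if np.any(norms <= 1e-10 * scale):
        raise ValueError(
            "degenerate window: collinear Cα positions give no local axis"
        )
    axes /= norms[:, None]
    direction = ca[-1] - ca[0]
    flip = axes @ direction < 0
    axes[flip] = -axes[flip]
    return axes


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    # atan2 form: stable for near-parallel vectors, unlike arccos of the dot
    return float(
        np.degrees(np.arctan2(np.linalg.norm(np.cross(u, v)), np.dot(u, v)))
    )


def _mean_axis(axes: np.ndarray) -> np.ndarray:
    m = axes.mean(axis=0)
    return m / np.linalg.norm(m)


def _kink_from_bends(
    local_bends: np.ndarray, helix: HelixDefinition
) -> tuple[int, int]:
    # np.argmax returns the first maximum, i.e. ties break toward the
    # N-terminus as required.
    i = int(np.argmax(local_bends))
    return (helix.start + i + 1, helix.start + i + 2)


def bending_profile(
    axes: np.ndarray, helix: HelixDefinition, frame: int | str = 0
) -> HelixAxisProfile:
    """Bend angles between consecutive local axes, and the kink position."""
    axes = np.asarray(axes, float)
    if len(axes) < 2:
        raise ValueError("need at least 2 window axes")
    dots = np.einsum("ij,ij->i", axes[:-1], axes[1:])
    crosses = np.linalg.norm(np.cross(axes[:-1], axes[1:]), axis=1)
    local_bends = np.degrees(np.arctan2(crosses, dots))
    third = max(len(axes) // 3, 1)
    global_bend = _angle_deg(_mean_axis(axes[:third]), _mean_axis(axes[-third:]))
    return HelixAxisProfile(
        helix=helix,
        window_axes=axes,
        local_bends=local_bends,
        global_bend=global_bend,
        kink_position=_kink_from_bends(local_bends, helix),
        frame=frame,
    )


def trajectory_profile(
    traj: Trajectory, helix: HelixDefinition, chain: str | None = None
) -> tuple[list[HelixAxisProfile], HelixAxisProfile]:
    """Per-frame profiles plus the trajectory-mean profile of one helix.

    Angles are averaged arithmetically across frames (adequate in the
    sub-90° operating regime of TM helix bends); the mean profile's kink is
    localized on the frame-averaged local bends.
    """
    ca_idx = select(traj, [helix.residue_range], atom_names={"CA"})
    if chain is not None:
        ca_idx = ca_idx[traj.topology.chains[ca_idx] == chain]
    if len(ca_idx) < 4:
        raise ValueError(
            f"helix {helix.label}: found {len(ca_idx)} Cα atoms, need ≥ 4"
        )
    per_frame: list[HelixAxisProfile] = []
    for f in range(traj.frame_count):
        axes = local_axes(traj.frames[f][ca_idx])
        per_frame.append(bending_profile(axes, helix, frame=f))
    mean_bends = np.mean([p.local_bends for p in per_frame], axis=0)
    mean_global = float(np.mean([p.global_bend for p in per_frame]))
    mean_axes = np.mean([p.window_axes for p in per_frame], axis=0)
    mean_axes /= np.linalg.norm(mean_axes, axis=1)[:, None]
    mean_profile = HelixAxisProfile(
        helix=helix,
        window_axes=mean_axes,
        local_bends=mean_bends,
        global_bend=mean_global,
        kink_position=_kink_from_bends(mean_bends, helix),
        frame="mean",
    )
    return per_frame, mean_profile


def profile_report(profiles: list[HelixAxisProfile]) -> pd.DataFrame:
    rows = [
        {
            "Helix": p.helix.label,
            "Frame": p.frame,
            "GlobalBend": p.global_bend,
            "KinkResidueI": p.kink_position[0],
            "KinkResidueJ": p.kink_position[1],
            "MaxLocalBend": p.max_local_bend,
        }
        for p in profiles
    ]
    return pd.DataFrame(
        rows,
        columns=["Helix", "Frame", "GlobalBend", "KinkResidueI", "KinkResidueJ", "MaxLocalBend"],
    )
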