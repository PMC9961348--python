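"""Synthetic trajectories with planted, exactly-known geometric features.

The generator emulates what the analysis stages must recover from a
six-helix transmembrane bundle: ideal and kinked α-helices, pairwise
interactions that switch between a bound and an unbound geometry with
Bernoulli (or exact-count) occupancy, isotropic Gaussian coordinate jitter,
and a two-state pair of trajectories whose conformational asymmetry is
confined to a chosen helix subset.

Side chains are minimal pseudo-residues: each planted interaction adds only
the atoms its detector keys on (OD1/OD2 and NZ for a salt bridge, a ring
hexagon and a cationic nitrogen for cation-π, ...), with correct PDB names.
Switching between bound and unbound geometry is teleportation, not
kinetics — only the occupancy statistics matter to the analyses under test.

Every fixture is deterministic: one random stream per trajectory, seeded
from the spec.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .structio import HelixDefinition, Structure, Trajectory

__all__ = [
    "BundleSpec",
    "PlantedInteraction",
    "TwoStateSpec",
    "GroundTruth",
    "rotation_matrix",
    "build_ideal_helix",
    "build_kinked_helix",
    "build_bundle",
    "helix_definitions",
    "ca_structure",
    "make_trajectory",
    "generate_trajectory",
    "generate_two_state",
]

# Detection cutoffs the unbound geometry must clear (plus 3σ of jitter).
_DETECTION_CUTOFF = {
    "salt_bridge": 4.0,
    "hbond": 3.0,
    "hydrophobic": 4.5,
    "cation_pi": 6.0,
}


def rotation_matrix(axis: Sequence[float], degrees: float) -> np.ndarray:
    """Rodrigues rotation matrix about an arbitrary axis."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    a = np.deg2rad(degrees)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(a) * k + (1 - np.cos(a)) * (k @ k)


def _perpendicular(u: np.ndarray) -> np.ndarray:
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    p = np.cross(u, ref)
    return p / np.linalg.norm(p)


@dataclass(frozen=True)
class BundleSpec:
    """Geometry of an idealized antiparallel six-helix bundle.

    Defaults are canonical α-helix parameters (1.5 Å rise, 100° twist,
    2.3 Å Cα radius); the bundle radius is chosen so that flanking helices
    touch at van-der-Waals contact range, as TM helices in a carrier do.
    """

    n_helices: int = 6
    residues_per_helix: int = 30
    rise: float = 1.5
    twist: float = 100.0
    ca_radius: float = 2.3
    bundle_radius: float = 8.0
    tilt: float = 0.0
    seed: int = 0
    chain: str = "A"
    antiparallel: bool = True

    def __post_init__(self) -> None:
        for name in ("rise", "twist", "ca_radius", "bundle_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_helices < 1 or self.residues_per_helix < 4:
            raise ValueError("need ≥ 1 helix of ≥ 4 residues")

    def helix_residues(self, k: int) -> tuple[int, int]:
        """Inclusive author-numbered residue range of helix k (1-based)."""
        start = (k - 1) * self.residues_per_helix + 1
        return (start, start + self.residues_per_helix - 1)


@dataclass(frozen=True)
class PlantedInteraction:
    """One pairwise interaction planted with known geometry and occupancy."""

    kind: str
    res_a: int
    res_b: int
    occupancy: float
    bound_distance: float
    bound_angle: float | None = None
    unbound_distance: float = 12.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in _DETECTION_CUTOFF:
            raise ValueError(f"unknown interaction kind {self.kind!r}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must be in [0, 1]")
        if not self.label:
            object.__setattr__(
                self, "label", f"{self.kind}:{self.res_a}-{self.res_b}"
            )

    def check_margin(self, jitter_sigma: float) -> None:
        cutoff = _DETECTION_CUTOFF[self.kind]
        if self.unbound_distance <= cutoff + 3.0 * jitter_sigma:
            raise ValueError(
                f"{self.label}: unbound distance {self.unbound_distance} must "
                f"exceed cutoff {cutoff} + 3σ"
            )


@dataclass(frozen=True)
class TwoStateSpec:
    """Two conformational states differing on a helix subset.

    Each moved helix is displaced along its own radial direction by
    ``translation`` Å, with the sign alternating between consecutive moved
    helices (out, in, out, ...), and optionally rotated about its own axis.
    The alternation gives the displacement field zero net translation and
    zero net torque, so the planted asymmetry survives a rigid superposition
    of the moved helix group instead of being absorbed by it.
    """

    base: BundleSpec = field(default_factory=BundleSpec)
    moved_helices: tuple[int, ...] = (6, 1, 2)
    translation: float = 1.8
    rotation: float = 0.0
    jitter_sigma: float = 0.1

    def __post_init__(self) -> None:
        moved = set(self.moved_helices)
        if not moved or not moved < set(range(1, self.base.n_helices + 1)):
            raise ValueError(
                "moved_helices must be a non-empty strict subset of the bundle"
            )


@dataclass
class GroundTruth:
    """Sidecar record of everything the generator planted."""

    interactions: list[dict] = field(default_factory=list)
    bound: dict[str, np.ndarray] = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def records(self) -> list[dict]:
        out = []
        for label, flags in self.bound.items():
            out.extend(
                {"frame": f, "interaction": label, "bound": bool(b)}
                for f, b in enumerate(flags)
            )
        return out

    def empirical_fraction(self, label: str) -> float:
        return float(np.mean(self.bound[label]))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "interactions": self.interactions,
            "records": self.records(),
            "extras": self.extras,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        bound: dict[str, list] = {}
        for rec in payload["records"]:
            bound.setdefault(rec["interaction"], []).append(
                (rec["frame"], rec["bound"])
            )
        return cls(
            interactions=payload["interactions"],
            bound={
                label: np.array([b for _f, b in sorted(vals)], bool)
                for label, vals in bound.items()
            },
            extras=payload.get("extras", {}),
        )


# ---------------------------------------------------------------------------
# Helix and bundle geometry


def build_ideal_helix(
    n: int, rise: float = 1.5, twist: float = 100.0, radius: float = 2.3
) -> np.ndarray:
    """Cα coordinates of an ideal α-helix whose axis is +z."""
    if n < 4:
        raise ValueError("need at least 4 residues")
    i = np.arange(n)
    w = np.deg2rad(twist)
    return np.column_stack(
        [radius * np.cos(i * w), radius * np.sin(i * w), i * rise]
    )


def build_kinked_helix(
    n: int,
    kink_angle: float,
    kink_after: int,
    rise: float = 1.5,
    twist: float = 100.0,
    radius: float = 2.3,
) -> np.ndarray:
    """An ideal helix kinked between residues ``kink_after`` and the next.

    Residues up to ``kink_after`` (1-based) follow the ideal segment; the
    remainder is rotated rigidly by ``kink_angle`` about an axis
    perpendicular to the first segment's axis, pivoting on the junction Cα
    so the chain stays continuous.  The angle between the two segments'
    analytic axes is exactly ``kink_angle``.
    """
    if not 4 <= kink_after <= n - 4:
        raise ValueError("kink_after must leave ≥ 4 residues on each side")
    base = build_ideal_helix(n, rise, twist, radius)
    if kink_angle == 0.0:
        return base
    rot = rotation_matrix([0.0, 1.0, 0.0], kink_angle)
    pivot = base[kink_after - 1]
    out = base.copy()
    out[kink_after:] = (base[kink_after:] - pivot) @ rot.T + pivot
    return out


def helix_definitions(spec: BundleSpec) -> tuple[HelixDefinition, ...]:
    return tuple(
        HelixDefinition(f"H{k}", spec.helix_residues(k))
        for k in range(1, spec.n_helices + 1)
    )


def _helix_coords(spec: BundleSpec, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Base CA and CB coordinates of helix k, placed in the bundle."""
    n = spec.residues_per_helix
    ca = build_ideal_helix(n, spec.rise, spec.twist, spec.ca_radius)
    cb = build_ideal_helix(n, spec.rise, spec.twist, spec.ca_radius + 1.5)
    both = np.concatenate([ca, cb])
    both = both - both.mean(axis=0)
    if spec.antiparallel and k % 2 == 0:
        both = both @ rotation_matrix([1.0, 0.0, 0.0], 180.0).T
    theta = np.deg2rad((k - 1) * 360.0 / spec.n_helices)
    radial = np.array([np.cos(theta), np.sin(theta), 0.0])
    if spec.tilt:
        tangent = np.array([-np.sin(theta), np.cos(theta), 0.0])
        both = both @ rotation_matrix(tangent, spec.tilt).T
    both = both + spec.bundle_radius * radial
    return both[:n], both[n:]


def build_bundle(spec: BundleSpec) -> Structure:
    """The jitter-free bundle topology: ALA residues with CA + CB atoms."""
    serials, names, elements, resnames, resnums, chains, coords = (
        [], [], [], [], [], [], []
    )
    serial = 1
    for k in range(1, spec.n_helices + 1):
        start, _ = spec.helix_residues(k)
        ca, cb = _helix_coords(spec, k)
        for i in range(spec.residues_per_helix):
            for name, xyz in (("CA", ca[i]), ("CB", cb[i])):
                serials.append(serial)
                names.append(name)
                elements.append("C")
                resnames.append("ALA")
                resnums.append(start + i)
                chains.append(spec.chain)
                coords.append(xyz)
                serial += 1
    return Structure(
        serials, names, elements, resnames, resnums, chains, np.array(coords)
    )


def ca_structure(
    coords: np.ndarray,
    start_resnum: int = 1,
    chain: str = "A",
    residue_name: str = "GLY",
) -> Structure:
    """Wrap bare Cα coordinates as a one-atom-per-residue Structure."""
    coords = np.asarray(coords, float)
    n = len(coords)
    return Structure(
        serials=list(range(1, n + 1)),
        names=["CA"] * n,
        elements=["C"] * n,
        residue_names=[residue_name] * n,
        residue_numbers=list(range(start_resnum, start_resnum + n)),
        chains=[chain] * n,
        coords=coords,
    )


def make_trajectory(
    structure: Structure,
    n_frames: int,
    jitter_sigma: float = 0.0,
    seed: int = 0,
) -> Trajectory:
    """Frames = the static structure plus iid isotropic Gaussian jitter."""
    rng = np.random.default_rng(seed)
    base = structure.coords
    frames = [
        base + rng.normal(0.0, jitter_sigma, base.shape) if jitter_sigma else base.copy()
        for _ in range(n_frames)
    ]
    return Trajectory(structure, frames)


# ---------------------------------------------------------------------------
# Planted interactions

# Atoms each planted kind installs on its two residues, besides CA.
# "movable" atoms teleport between the bound and unbound geometry.
_PLANT_RESNAMES = {
    "salt_bridge": ("ASP", "LYS"),
    "hbond": ("TYR", "GLU"),
    "hydrophobic": ("LEU", "LEU"),
    "cation_pi": ("PHE", "LYS"),
}

_RING_NAMES = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")


def _plant_geometry(
    plant: PlantedInteraction, ca_a: np.ndarray, ca_b: np.ndarray
) -> tuple[list[tuple[str, str, np.ndarray]], list[tuple[str, str, np.ndarray, np.ndarray]]]:
    """Static atoms of residue A and movable atoms of residue B.

    Returns (static, movable); static entries are (residue_slot, atom_name,
    xyz); movable entries are (residue_slot, atom_name, bound_xyz,
    unbound_xyz).  Residue slot "a" or "b".
    """
    u = ca_b - ca_a
    u = u / np.linalg.norm(u)
    p = _perpendicular(u)
    static: list[tuple[str, str, np.ndarray]] = []
    movable: list[tuple[str, str, np.ndarray, np.ndarray]] = []
    d, d_un = plant.bound_distance, plant.unbound_distance

    if plant.kind == "salt_bridge":
        od1 = ca_a + 1.5 * u
        static += [("a", "OD1", od1), ("a", "OD2", od1 + 0.8 * p - 0.3 * u)]
        movable.append(("b", "NZ", od1 + d * u, od1 + d_un * u))
    elif plant.kind == "hbond":
        oh = ca_a + 1.5 * u
        theta = np.deg2rad(plant.bound_angle if plant.bound_angle is not None else 164.0)
        r_dh = 1.0
        # Triangle donor-H-acceptor: law of sines places H so the
        # donor-H-acceptor angle is exactly the planted one.
        sin_at_acceptor = np.clip(r_dh * np.sin(theta) / d, -1.0, 1.0)
        angle_at_donor = np.pi - theta - np.arcsin(sin_at_acceptor)
        hh = oh + r_dh * (np.cos(angle_at_donor) * u + np.sin(angle_at_donor) * p)
        static += [("a", "OH", oh), ("a", "HH", hh)]
        movable.append(("b", "OE1", oh + d * u, oh + d_un * u))
    elif plant.kind == "hydrophobic":
        cd1 = ca_a + 1.5 * u
        static.append(("a", "CD1", cd1))
        movable.append(("b", "CD1", cd1 + d * u, cd1 + d_un * u))
    elif plant.kind == "cation_pi":
        centroid = ca_a + 2.0 * u
        normal = p
        in_plane = np.cross(normal, u)
        in_plane /= np.linalg.norm(in_plane)
        for j, name in enumerate(_RING_NAMES):
            ang = np.deg2rad(60.0 * j)
            static.append(
                ("a", name, centroid + 1.39 * (np.cos(ang) * u + np.sin(ang) * in_plane))
            )
        alpha = np.deg2rad(plant.bound_angle if plant.bound_angle is not None else 90.0)
        bound = centroid + d * (np.cos(alpha) * u + np.sin(alpha) * normal)
        movable.append(("b", "NZ", bound, centroid + d_un * u))
    return static, movable


def generate_trajectory(
    spec: BundleSpec,
    planted: Sequence[PlantedInteraction],
    n_frames: int,
    seed: int | None = None,
    jitter_sigma: float = 0.05,
    occupancy_mode: str = "bernoulli",
) -> tuple[Trajectory, GroundTruth]:
    """Bundle trajectory with planted interactions and a ground-truth record.

    Each planted interaction independently samples bound/unbound per frame —
    iid Bernoulli by default, or exactly round(p·n_frames) bound frames at
    shuffled positions with ``occupancy_mode="exact"`` (used when a test
    needs the empirical fraction to hit the occupancy exactly).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be ≥ 1")
    if occupancy_mode not in ("bernoulli", "exact"):
        raise ValueError("occupancy_mode must be 'bernoulli' or 'exact'")
    seed = spec.seed if seed is None else seed
    used: set[int] = set()
    for plant in planted:
        plant.check_margin(jitter_sigma)
        for res in (plant.res_a, plant.res_b):
            if res in used:
                raise ValueError(
                    f"residue {res} appears in more than one planted "
                    "interaction: conflicting geometries"
                )
            used.add(res)

    base = build_bundle(spec)
    coords = base.coords.copy()
    chain = spec.chain

    # Rebuild the atom table: planted residues swap their CB for the
    # kind-specific side-chain atoms.
    atom_rows: list[tuple[str, str, str, int]] = []  # (name, element, resname, resnum)
    static_xyz: list[np.ndarray] = []
    movable_slots: list[dict] = []  # per planted: atom row index, bound/unbound xyz

    plants_by_res: dict[int, tuple[PlantedInteraction, str]] = {}
    for plant in planted:
        plants_by_res[plant.res_a] = (plant, "a")
        plants_by_res[plant.res_b] = (plant, "b")

    geometry: dict[str, tuple[list, list]] = {}
    for plant in planted:
        ca_a = coords[base.atom_index(chain, plant.res_a, "CA")]
        ca_b = coords[base.atom_index(chain, plant.res_b, "CA")]
        geometry[plant.label] = _plant_geometry(plant, ca_a, ca_b)

    movable_index: dict[str, list[tuple[int, np.ndarray, np.ndarray]]] = {
        p.label: [] for p in planted
    }
    n_res = spec.n_helices * spec.residues_per_helix
    for resnum in range(1, n_res + 1):
        ca_i = base.atom_index(chain, resnum, "CA")
        if resnum not in plants_by_res:
            atom_rows.append(("CA", "C", "ALA", resnum))
            static_xyz.append(coords[ca_i])
            atom_rows.append(("CB", "C", "ALA", resnum))
            static_xyz.append(coords[base.atom_index(chain, resnum, "CB")])
            continue
        plant, slot = plants_by_res[resnum]
        resname = _PLANT_RESNAMES[plant.kind][0 if slot == "a" else 1]
        atom_rows.append(("CA", "C", resname, resnum))
        static_xyz.append(coords[ca_i])
        static, movable = geometry[plant.label]
        for s_slot, name, xyz in static:
            if s_slot == slot:
                element = "H" if name.startswith("H") else name[0]
                atom_rows.append((name, element, resname, resnum))
                static_xyz.append(xyz)
        for m_slot, name, bound_xyz, unbound_xyz in movable:
            if m_slot == slot:
                atom_rows.append((name, name[0], resname, resnum))
                static_xyz.append(unbound_xyz)
                movable_index[plant.label].append(
                    (len(static_xyz) - 1, bound_xyz, unbound_xyz)
                )

    topology = Structure(
        serials=list(range(1, len(atom_rows) + 1)),
        names=[r[0] for r in atom_rows],
        elements=[r[1] for r in atom_rows],
        residue_names=[r[2] for r in atom_rows],
        residue_numbers=[r[3] for r in atom_rows],
        chains=[chain] * len(atom_rows),
        coords=np.array(static_xyz),
    )

    rng = np.random.default_rng(seed)
    truth = GroundTruth(extras={"seed": seed, "jitter_sigma": jitter_sigma})
    for plant in planted:
        if occupancy_mode == "bernoulli":
            flags = rng.random(n_frames) < plant.occupancy
        else:
            k = int(round(plant.occupancy * n_frames))
            flags = np.zeros(n_frames, bool)
            flags[:k] = True
            rng.shuffle(flags)
        truth.bound[plant.label] = flags
        truth.interactions.append(
            {
                "label": plant.label,
                "kind": plant.kind,
                "res_a": plant.res_a,
                "res_b": plant.res_b,
                "occupancy": plant.occupancy,
                "bound_distance": plant.bound_distance,
                "bound_angle": plant.bound_angle,
                "unbound_distance": plant.unbound_distance,
            }
        )

    base_xyz = topology.coords
    frames = []
    for f in range(n_frames):
        frame = base_xyz.copy()
        for plant in planted:
            bound = bool(truth.bound[plant.label][f])
            for row, bound_xyz, unbound_xyz in movable_index[plant.label]:
                frame[row] = bound_xyz if bound else unbound_xyz
        if jitter_sigma:
            frame = frame + rng.normal(0.0, jitter_sigma, frame.shape)
        frames.append(frame)
    return Trajectory(topology, frames), truth


def generate_two_state(
    spec: TwoStateSpec, n_frames: int, seed: int | None = None
) -> tuple[Trajectory, Trajectory, GroundTruth]:
    """Two trajectories differing by planted per-helix displacements.

    State A is the base bundle plus jitter.  In state B every helix listed
    in ``moved_helices`` is translated along its own radial direction by the
    spec's magnitude, signs alternating (+, -, +, ...) in list order, and
    rotated about its own axis if a rotation is specified.
    """
    base_spec = spec.base
    seed = base_spec.seed if seed is None else seed
    structure = build_bundle(base_spec)
    displaced = structure.coords.copy()
    pattern = []
    for j, k in enumerate(spec.moved_helices):
        sign = 1.0 if j % 2 == 0 else -1.0
        pattern.append(sign)
        theta = np.deg2rad((k - 1) * 360.0 / base_spec.n_helices)
        radial = np.array([np.cos(theta), np.sin(theta), 0.0])
        lo, hi = base_spec.helix_residues(k)
        mask = (structure.residue_numbers >= lo) & (structure.residue_numbers <= hi)
        if spec.rotation:
            center = displaced[mask].mean(axis=0)
            rot = rotation_matrix([0.0, 0.0, 1.0], sign * spec.rotation)
            displaced[mask] = (displaced[mask] - center) @ rot.T + center
        displaced[mask] += sign * spec.translation * radial

    rng = np.random.default_rng(seed)
    sigma = spec.jitter_sigma
    frames_a = [
        structure.coords + rng.normal(0.0, sigma, structure.coords.shape)
        for _ in range(n_frames)
    ]
    frames_b = [
        displaced + rng.normal(0.0, sigma, displaced.shape) for _ in range(n_frames)
    ]
    moved_structure = Structure(
        structure.serials, structure.names, structure.elements,
        structure.residue_names, structure.residue_numbers, structure.chains,
        displaced,
    )
    truth = GroundTruth(
        extras={
            "moved_helices": list(spec.moved_helices),
            "translation": spec.translation,
            "rotation": spec.rotation,
            "sign_pattern": pattern,
            "jitter_sigma": sigma,
            "seed": seed,
        }
    )
    return (
        Trajectory(structure, frames_a),
        Trajectory(moved_structure, frames_b),
        truth,
    )
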