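"""Per-frame interaction detection and trajectory persistence statistics.

Four interaction classes are detected between residues: salt bridges
(acidic-oxygen / basic-nitrogen minimum distance, no angle criterion),
hydrogen bonds (heavy-atom distance plus donor–H–acceptor angle when
hydrogens exist), hydrophobic contacts (apolar side-chain heavy atoms), and
cation-π (aromatic ring centroid to cationic nitrogen, with the elevation
angle of the cation over the ring plane monitored but not thresholded).

The trajectory-level summary of one residue pair is an
:class:`InteractionSeries`: per-frame presence, distance and angle, the
persistence (fraction of frames present), and averages over present frames
only — the quantities the occupancy tables of carrier MD studies report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .geomcore import ring_geometry
from .structio import HelixDefinition, Structure, Trajectory, select

__all__ = [
    "ResidueRef",
    "InteractionSeries",
    "ContactMap",
    "ContactInterface",
    "SaltBridgeDetector",
    "HBondDetector",
    "HydrophobicDetector",
    "CationPiDetector",
    "detect_salt_bridges",
    "detect_hbonds",
    "detect_hydrophobic",
    "cation_pi_series",
    "build_series",
    "scan_salt_bridge_series",
    "scan_hydrophobic_series",
    "filter_by_persistence",
    "interhelix_contact_map",
    "series_report",
]

ResidueRef = tuple[str, int]  # (chain, author residue number)

ACIDIC_ATOMS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}
BASIC_ATOMS: dict[str, tuple[str, ...]] = {
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
}
HIS_BASIC_ATOMS: tuple[str, ...] = ("ND1", "NE2")

# Apolar side-chain heavy atoms per residue (C and S only; Tyr contributes
# its ring carbons but not the hydroxyl).
APOLAR_SIDECHAIN: dict[str, tuple[str, ...]] = {
    "ALA": ("CB",),
    "VAL": ("CB", "CG1", "CG2"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "PRO": ("CB", "CG", "CD"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CB", "CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "MET": ("CB", "CG", "SD", "CE"),
    "CYS": ("CB", "SG"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
}

# Six-membered aromatic ring atoms used for cation-π geometry.  For Trp the
# six-membered (benzene) ring is the default; the five-ring and full indole
# are selectable.  Arginine's guanidinium plane is treated as a "ring".
RING_ATOMS: dict[str, tuple[str, ...]] = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "ARG": ("NE", "CZ", "NH1", "NH2"),
}
TRP_FIVE_RING: tuple[str, ...] = ("CG", "CD1", "NE1", "CE2", "CD2")
TRP_INDOLE: tuple[str, ...] = TRP_FIVE_RING + ("CE3", "CZ2", "CZ3", "CH2")


def _residue_label(top: Structure, ref: ResidueRef) -> str:
    start, _ = top.residue_index[ref]
    resname = str(top.residue_names[start]).capitalize()
    return f"{resname}{ref[1]}"


@dataclass
class InteractionSeries:
    """One residue pair's interaction over a trajectory."""

    kind: str
    partner_a: str
    partner_b: str
    present: np.ndarray
    distance: np.ndarray
    angle: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.present = np.asarray(self.present, bool)
        self.distance = np.asarray(self.distance, float)
        if self.angle is not None:
            self.angle = np.asarray(self.angle, float)
        if len(self.present) != len(self.distance):
            raise ValueError("present and distance must have equal length")
        if len(self.present) == 0:
            raise ValueError("a series needs at least one frame")

    @property
    def frame_count(self) -> int:
        return len(self.present)

    @property
    def fraction(self) -> float:
        """Persistence: fraction of frames in which the interaction holds."""
        return float(np.mean(self.present))

    @property
    def avg_distance(self) -> float:
        """Mean distance over present frames only (nan if never present)."""
        if not self.present.any():
            return float("nan")
        return float(np.mean(self.distance[self.present]))

    @property
    def avg_angle(self) -> float:
        if self.angle is None or not self.present.any():
            return float("nan")
        vals = self.angle[self.present]
        vals = vals[np.isfinite(vals)]
        return float(np.mean(vals)) if len(vals) else float("nan")


# ---------------------------------------------------------------------------
# Detectors.  Each detector measures a residue pair in one frame (distance
# and, where meaningful, angle — regardless of the cutoff) and decides
# presence from the measurement; whole-frame scans enumerate qualifying pairs.


class SaltBridgeDetector:
    """Acidic O vs basic N minimum-distance criterion, no angle gate."""

    kind = "salt_bridge"

    def __init__(self, cutoff: float = 4.0, include_his: bool = False) -> None:
        if cutoff <= 0:
            raise ValueError("cutoff must be > 0")
        self.cutoff = cutoff
        self.include_his = include_his

    def _basic_atoms(self, resname: str) -> tuple[str, ...]:
        if resname in BASIC_ATOMS:
            return BASIC_ATOMS[resname]
        if resname == "HIS" and self.include_his:
            return HIS_BASIC_ATOMS
        return ()

    def _pair_indices(
        self, top: Structure, pair: tuple[ResidueRef, ResidueRef]
    ) -> tuple[np.ndarray, np.ndarray]:
        ref_a, ref_b = pair
        name_a = str(top.residue_names[top.residue_index[ref_a][0]])
        name_b = str(top.residue_names[top.residue_index[ref_b][0]])
        if name_a in ACIDIC_ATOMS:
            acidic, basic = ref_a, ref_b
        elif name_b in ACIDIC_ATOMS:
            acidic, basic = ref_b, ref_a
        else:
            raise ValueError(f"neither {ref_a} nor {ref_b} is acidic")
        a_span = top.residue_atoms(*acidic)
        b_span = top.residue_atoms(*basic)
        a_names = ACIDIC_ATOMS[str(top.residue_names[a_span[0]])]
        b_names = self._basic_atoms(str(top.residue_names[b_span[0]]))
        a_idx = np.array([i for i in a_span if top.names[i] in a_names], int)
        b_idx = np.array([i for i in b_span if top.names[i] in b_names], int)
        return a_idx, b_idx

    def measure(
        self, top: Structure, coords: np.ndarray,
        pair: tuple[ResidueRef, ResidueRef],
    ) -> tuple[float, float]:
        a_idx, b_idx = self._pair_indices(top, pair)
        if len(a_idx) == 0 or len(b_idx) == 0:
            return float("inf"), float("nan")
        dist = cdist(coords[a_idx], coords[b_idx]).min()
        return float(dist), float("nan")

    def qualifies(self, distance: float, angle: float) -> bool:
        return distance <= self.cutoff

    def scan(
        self, top: Structure, coords: np.ndarray
    ) -> list[tuple[tuple[ResidueRef, ResidueRef], float]]:
        acidic_res, basic_res = [], []
        for ref, (start, _end) in top.residue_index.items():
            resname = str(top.residue_names[start])
            if resname in ACIDIC_ATOMS:
                acidic_res.append(ref)
            elif self._basic_atoms(resname):
                basic_res.append(ref)
        hits = []
        for ra in acidic_res:
            for rb in basic_res:
                a_idx, b_idx = self._pair_indices(top, (ra, rb))
                if len(a_idx) == 0 or len(b_idx) == 0:
                    warnings.warn(
                        f"charged residue pair {ra}/{rb} lacks side-chain "
                        "atoms; skipped",
                        stacklevel=2,
                    )
                    continue
                dist = float(cdist(coords[a_idx], coords[b_idx]).min())
                if dist <= self.cutoff:
                    hits.append(((ra, rb), dist))
        return hits


class HydrophobicDetector:
    """Minimum apolar side-chain heavy-atom distance criterion."""

    kind = "hydrophobic"

    def __init__(self, cutoff: float = 4.5) -> None:
        if cutoff <= 0:
            raise ValueError("cutoff must be > 0")
        self.cutoff = cutoff

    def _apolar_indices(self, top: Structure, ref: ResidueRef) -> np.ndarray:
        span = top.residue_atoms(*ref)
        names = APOLAR_SIDECHAIN.get(str(top.residue_names[span[0]]), ())
        return np.array([i for i in span if top.names[i] in names], int)

    def measure(
        self, top: Structure, coords: np.ndarray,
        pair: tuple[ResidueRef, ResidueRef],
    ) -> tuple[float, float]:
        a_idx = self._apolar_indices(top, pair[0])
        b_idx = self._apolar_indices(top, pair[1])
        if len(a_idx) == 0 or len(b_idx) == 0:
            return float("inf"), float("nan")
        return float(cdist(coords[a_idx], coords[b_idx]).min()), float("nan")

    def qualifies(self, distance: float, angle: float) -> bool:
        return distance <= self.cutoff

    def scan(
        self, top: Structure, coords: np.ndarray
    ) -> list[tuple[tuple[ResidueRef, ResidueRef], float]]:
        refs = [
            ref
            for ref, (start, _e) in top.residue_index.items()
            if str(top.residue_names[start]) in APOLAR_SIDECHAIN
        ]
        hits = []
        for i, ra in enumerate(refs):
            for rb in refs[i + 1:]:
                if ra[0] == rb[0] and abs(ra[1] - rb[1]) < 2:
                    continue  # skip self and sequence neighbours
                dist, _ = self.measure(top, coords, (ra, rb))
                if dist <= self.cutoff:
                    hits.append(((ra, rb), dist))
        return hits


class HBondDetector:
    """Donor-acceptor heavy distance plus donor–H–acceptor angle.

    Donors and acceptors are given as ``(chain, resnum, atom_name)`` heavy
    atoms.  A donor's hydrogen is any H-named atom of the same residue
    within 1.3 Å of the donor heavy atom.  Topologies without hydrogens
    waive the angle criterion (the angle is reported as nan).
    """

    kind = "hbond"

    def __init__(
        self,
        donors: Sequence[tuple[str, int, str]],
        acceptors: Sequence[tuple[str, int, str]],
        distance_cutoff: float = 3.0,
        angle_cutoff: float = 135.0,
    ) -> None:
        self.donors = list(donors)
        self.acceptors = list(acceptors)
        self.distance_cutoff = distance_cutoff
        self.angle_cutoff = angle_cutoff

    @staticmethod
    def _has_hydrogens(top: Structure) -> bool:
        return any(str(e).upper() == "H" for e in top.elements)

    @staticmethod
    def _donor_hydrogen(
        top: Structure, coords: np.ndarray, donor_idx: int
    ) -> int | None:
        chain = str(top.chains[donor_idx])
        resnum = int(top.residue_numbers[donor_idx])
        for i in top.residue_atoms(chain, resnum):
            if str(top.elements[i]).upper() == "H":
                if np.linalg.norm(coords[i] - coords[donor_idx]) <= 1.3:
                    return int(i)
        return None

    def measure(
        self, top: Structure, coords: np.ndarray,
        pair: tuple[tuple[str, int, str], tuple[str, int, str]],
    ) -> tuple[float, float]:
        donor, acceptor = pair
        d_idx = top.atom_index(*donor)
        a_idx = top.atom_index(*acceptor)
        dist = float(np.linalg.norm(coords[d_idx] - coords[a_idx]))
        angle = float("nan")
        if self._has_hydrogens(top):
            h_idx = self._donor_hydrogen(top, coords, d_idx)
            if h_idx is not None:
                v1 = coords[d_idx] - coords[h_idx]
                v2 = coords[a_idx] - coords[h_idx]
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
        return dist, angle

    def qualifies(self, distance: float, angle: float) -> bool:
        if distance > self.distance_cutoff:
            return False
        if np.isnan(angle):
            return True  # no hydrogens: distance-only criterion
        return angle >= self.angle_cutoff

    def scan(
        self, top: Structure, coords: np.ndarray
    ) -> list[tuple[tuple, float, float]]:
        hits = []
        for donor in self.donors:
            for acceptor in self.acceptors:
                if donor[:2] == tuple(acceptor[:2]):
                    continue
                dist, angle = self.measure(top, coords, (donor, acceptor))
                if self.qualifies(dist, angle):
                    hits.append(((donor, acceptor), dist, angle))
        return hits


class CationPiDetector:
    """Ring-centroid to cation distance with ring-plane elevation angle.

    The cation position is the nitrogen atom of the cationic group; the
    angle is the elevation of the centroid→cation vector over the ring
    plane (90° on the normal, 0° in-plane).  Presence is distance-only.
    """

    kind = "cation_pi"

    def __init__(self, distance_cutoff: float = 6.0, trp_ring: str = "six") -> None:
        if distance_cutoff <= 0:
            raise ValueError("cutoff must be > 0")
        self.distance_cutoff = distance_cutoff
        self.trp_ring = trp_ring

    def ring_atom_names(self, resname: str) -> tuple[str, ...]:
        if resname == "TRP":
            return {
                "six": RING_ATOMS["TRP"],
                "five": TRP_FIVE_RING,
                "indole": TRP_INDOLE,
            }[self.trp_ring]
        if resname not in RING_ATOMS:
            raise ValueError(f"{resname} has no aromatic/planar ring definition")
        return RING_ATOMS[resname]

    def measure(
        self, top: Structure, coords: np.ndarray,
        pair: tuple[ResidueRef, tuple[str, int, str]],
    ) -> tuple[float, float]:
        aromatic, cation = pair
        span = top.residue_atoms(*aromatic)
        resname = str(top.residue_names[span[0]])
        names = self.ring_atom_names(resname)
        ring_idx = [i for i in span if top.names[i] in names]
        if len(ring_idx) != len(names):
            missing = set(names) - {str(top.names[i]) for i in ring_idx}
            raise ValueError(
                f"residue {aromatic} ({resname}) is missing ring atoms {sorted(missing)}"
            )
        ring = ring_geometry(coords[ring_idx], names)
        cation_xyz = coords[top.atom_index(*cation)]
        v = cation_xyz - ring.centroid
        dist = float(np.linalg.norm(v))
        sin_elev = abs(np.dot(v, ring.normal)) / max(dist, 1e-12)
        angle = float(np.degrees(np.arcsin(np.clip(sin_elev, -1.0, 1.0))))
        return dist, angle

    def qualifies(self, distance: float, angle: float) -> bool:
        return distance <= self.distance_cutoff


# ---------------------------------------------------------------------------
# Frame-level convenience wrappers


def detect_salt_bridges(
    top: Structure, coords: np.ndarray, cutoff: float = 4.0,
    include_his: bool = False,
) -> list[tuple[tuple[ResidueRef, ResidueRef], float]]:
    return SaltBridgeDetector(cutoff, include_his).scan(top, coords)


def detect_hbonds(
    top: Structure, coords: np.ndarray,
    donors: Sequence[tuple[str, int, str]],
    acceptors: Sequence[tuple[str, int, str]],
    distance_cutoff: float = 3.0, angle_cutoff: float = 135.0,
) -> list[tuple[tuple, float, float]]:
    return HBondDetector(donors, acceptors, distance_cutoff, angle_cutoff).scan(
        top, coords
    )


def detect_hydrophobic(
    top: Structure, coords: np.ndarray, cutoff: float = 4.5
) -> list[tuple[tuple[ResidueRef, ResidueRef], float]]:
    return HydrophobicDetector(cutoff).scan(top, coords)


# ---------------------------------------------------------------------------
# Trajectory-level series


def build_series(traj: Trajectory, detector, pair) -> InteractionSeries:
    """Apply a detector to one pair in every frame and summarize."""
    if traj.frame_count == 0:
        raise ValueError("trajectory has no frames")
    top = traj.topology
    n = traj.frame_count
    present = np.zeros(n, bool)
    distance = np.full(n, np.nan)
    angle = np.full(n, np.nan)
    for f in range(n):
        d, a = detector.measure(top, traj.frames[f], pair)
        distance[f] = d
        angle[f] = a
        present[f] = detector.qualifies(d, a)
    has_angle = np.isfinite(angle).any()
    return InteractionSeries(
        kind=detector.kind,
        partner_a=_pair_label(top, pair[0]),
        partner_b=_pair_label(top, pair[1]),
        present=present,
        distance=distance,
        angle=angle if has_angle else None,
    )


def _pair_label(top: Structure, ref) -> str:
    if len(ref) == 3:  # (chain, resnum, atom)
        return f"{_residue_label(top, (ref[0], ref[1]))}@{ref[2]}"
    return _residue_label(top, tuple(ref))


def cation_pi_series(
    traj: Trajectory,
    aromatic: ResidueRef,
    cation: tuple[str, int, str],
    distance_cutoff: float = 6.0,
    trp_ring: str = "six",
) -> InteractionSeries:
    """Cation-π series between one aromatic residue and one cationic atom."""
    detector = CationPiDetector(distance_cutoff, trp_ring)
    return build_series(traj, detector, (aromatic, cation))


def _grouped_min_series(
    traj: Trajectory,
    kind: str,
    cutoff: float,
    groups_a: list[tuple[ResidueRef, np.ndarray]],
    groups_b: list[tuple[ResidueRef, np.ndarray]],
    pair_valid,
) -> list[InteractionSeries]:
    """Vectorized residue-pair minimum-distance series over all frames.

    One cdist per frame over the pooled atoms, reduced blockwise to
    per-residue-pair minima; a series is emitted for every valid pair that
    qualifies in at least one frame.
    """
    if not groups_a or not groups_b:
        return []
    top = traj.topology
    idx_a = np.concatenate([g for _, g in groups_a])
    idx_b = np.concatenate([g for _, g in groups_b])
    off_a = np.cumsum([0] + [len(g) for _, g in groups_a])[:-1]
    off_b = np.cumsum([0] + [len(g) for _, g in groups_b])[:-1]
    n = traj.frame_count
    mins = np.empty((n, len(groups_a), len(groups_b)))
    for f in range(n):
        d = cdist(traj.frames[f][idx_a], traj.frames[f][idx_b])
        d = np.minimum.reduceat(d, off_a, axis=0)
        mins[f] = np.minimum.reduceat(d, off_b, axis=1)
    present = mins <= cutoff
    ever = present.any(axis=0)
    out: list[InteractionSeries] = []
    for i, (ref_a, _) in enumerate(groups_a):
        for j, (ref_b, _) in enumerate(groups_b):
            if not ever[i, j] or not pair_valid(ref_a, ref_b):
                continue
            out.append(
                InteractionSeries(
                    kind=kind,
                    partner_a=_residue_label(top, ref_a),
                    partner_b=_residue_label(top, ref_b),
                    present=present[:, i, j],
                    distance=mins[:, i, j],
                )
            )
    return out


def scan_salt_bridge_series(
    traj: Trajectory, cutoff: float = 4.0, include_his: bool = False
) -> list[InteractionSeries]:
    """Every salt bridge present in at least one frame, as a series."""
    top = traj.topology
    det = SaltBridgeDetector(cutoff, include_his)
    acidic, basic = [], []
    for ref, (start, end) in top.residue_index.items():
        resname = str(top.residue_names[start])
        if resname in ACIDIC_ATOMS:
            names = ACIDIC_ATOMS[resname]
            idx = np.array([i for i in range(start, end) if top.names[i] in names], int)
            if len(idx) == 0:
                warnings.warn(
                    f"charged residue {ref} lacks side-chain atoms; skipped",
                    stacklevel=2,
                )
                continue
            acidic.append((ref, idx))
        else:
            names = det._basic_atoms(resname)
            if not names:
                continue
            idx = np.array([i for i in range(start, end) if top.names[i] in names], int)
            if len(idx) == 0:
                warnings.warn(
                    f"charged residue {ref} lacks side-chain atoms; skipped",
                    stacklevel=2,
                )
                continue
            basic.append((ref, idx))
    return _grouped_min_series(
        traj, "salt_bridge", cutoff, acidic, basic, lambda a, b: True
    )


def scan_hydrophobic_series(
    traj: Trajectory, cutoff: float = 4.5
) -> list[InteractionSeries]:
    """Every hydrophobic contact present in at least one frame, as a series."""
    top = traj.topology
    groups = []
    for ref, (start, end) in top.residue_index.items():
        names = APOLAR_SIDECHAIN.get(str(top.residue_names[start]), ())
        idx = np.array([i for i in range(start, end) if top.names[i] in names], int)
        if len(idx):
            groups.append((ref, idx))

    def valid(a: ResidueRef, b: ResidueRef) -> bool:
        # unordered pairs once; skip self and sequence neighbours
        if a >= b:
            return False
        return a[0] != b[0] or abs(a[1] - b[1]) >= 2

    return _grouped_min_series(traj, "hydrophobic", cutoff, groups, groups, valid)


def filter_by_persistence(
    series: Iterable[InteractionSeries], threshold: float = 0.10
) -> list[InteractionSeries]:
    """Keep series strictly above the persistence threshold, most persistent
    first (ties keep input order)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    kept = [s for s in series if s.fraction > threshold]
    return sorted(kept, key=lambda s: -s.fraction)


def series_report(series: Iterable[InteractionSeries]) -> pd.DataFrame:
    """Occupancy-table layout: Residue1, Residue2, Fraction, AvgDistance, AvgAngle."""
    rows = [
        {
            "Residue1": s.partner_a,
            "Residue2": s.partner_b,
            "Kind": s.kind,
            "Fraction": s.fraction,
            "AvgDistance": s.avg_distance,
            "AvgAngle": s.avg_angle,
        }
        for s in series
    ]
    return pd.DataFrame(
        rows, columns=["Residue1", "Residue2", "Kind", "Fraction", "AvgDistance", "AvgAngle"]
    )


# ---------------------------------------------------------------------------
# Interhelix contact maps


@dataclass(frozen=True)
class ContactInterface:
    helix_a: str
    range_a: tuple[int, int] | None
    helix_b: str
    range_b: tuple[int, int] | None
    count: int


@dataclass
class ContactMap:
    interfaces: list[ContactInterface]
    cutoff: float
    helices: tuple[HelixDefinition, ...] = field(default_factory=tuple)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for e in self.interfaces:
            rows.append(
                {
                    "HelixA": e.helix_a,
                    "RangeA": f"{e.range_a[0]}-{e.range_a[1]}" if e.range_a else "",
                    "HelixB": e.helix_b,
                    "RangeB": f"{e.range_b[0]}-{e.range_b[1]}" if e.range_b else "",
                    "Contacts": e.count,
                }
            )
        return pd.DataFrame(rows, columns=["HelixA", "RangeA", "HelixB", "RangeB", "Contacts"])


def interhelix_contact_map(
    structure: Structure,
    helices: Sequence[HelixDefinition],
    cutoff: float = 4.5,
    coords: np.ndarray | None = None,
) -> ContactMap:
    """Heavy-atom contact counts for every unordered helix pair.

    Alongside each count, the sub-range of residues actually in contact
    (minimum..maximum residue with at least one contact) is reported.
    """
    if coords is None:
        coords = structure.coords
    heavy = np.array([str(e).upper() != "H" for e in structure.elements])
    idx_by_helix: dict[str, np.ndarray] = {}
    for h in helices:
        idx = select(structure, [h.residue_range])
        idx_by_helix[h.label] = idx[heavy[idx]]
    interfaces: list[ContactInterface] = []
    for i, ha in enumerate(helices):
        for hb in helices[i + 1:]:
            ia, ib = idx_by_helix[ha.label], idx_by_helix[hb.label]
            if len(ia) == 0 or len(ib) == 0:
                interfaces.append(ContactInterface(ha.label, None, hb.label, None, 0))
                continue
            dmat = cdist(coords[ia], coords[ib])
            mask = dmat <= cutoff
            count = int(mask.sum())
            if count == 0:
                interfaces.append(ContactInterface(ha.label, None, hb.label, None, 0))
                continue
            rows, cols = np.nonzero(mask)
            res_a = structure.residue_numbers[ia[np.unique(rows)]]
            res_b = structure.residue_numbers[ib[np.unique(cols)]]
            interfaces.append(
                ContactInterface(
                    ha.label, (int(res_a.min()), int(res_a.max())),
                    hb.label, (int(res_b.min()), int(res_b.max())),
                    count,
                )
            )
    return ContactMap(interfaces, cutoff, tuple(helices))
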