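"""Structure/trajectory data model, multi-model PDB I/O, and selections.

The trajectory dialect is multi-model PDB: one ``MODEL``/``ENDMDL`` block per
frame, identical atom lists across frames, author residue numbering kept
verbatim (the carrier literature numbers from the unprocessed sequence, Met1
included, and so does everything downstream of this module).
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "HelixDefinition",
    "AnalysisConfig",
    "PdbParseError",
    "MalformedTrajectoryError",
    "read_pdb",
    "write_pdb",
    "select",
]


class PdbParseError(ValueError):
    """An unparsable record; the message names the offending line number."""


class MalformedTrajectoryError(ValueError):
    """Models of a multi-model file do not share one atom list."""


@dataclass(frozen=True)
class Atom:
    """One atom of the topology; coordinates are frame-0 coordinates in Å."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain: str
    coords: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError(f"atom {self.serial}: coords must be a finite 3-vector")
        object.__setattr__(self, "coords", c)


class Structure:
    """An ordered atom list with a (chain, residue_number) -> atom-span index.

    Atoms of one residue must be contiguous; the residue index covers every
    atom exactly once.  Internally the identity fields are parallel numpy
    arrays so selections and detectors can vectorize.
    """

    def __init__(
        self,
        serials: Sequence[int],
        names: Sequence[str],
        elements: Sequence[str],
        residue_names: Sequence[str],
        residue_numbers: Sequence[int],
        chains: Sequence[str],
        coords: np.ndarray,
    ) -> None:
        n = len(names)
        self.serials = np.asarray(serials, dtype=int)
        self.names = np.asarray(names, dtype=object)
        self.elements = np.asarray(elements, dtype=object)
        self.residue_names = np.asarray(residue_names, dtype=object)
        self.residue_numbers = np.asarray(residue_numbers, dtype=int)
        self.chains = np.asarray(chains, dtype=object)
        self.coords = np.asarray(coords, dtype=float).reshape(n, 3)
        if not (
            len(self.serials) == len(self.elements) == len(self.residue_names)
            == len(self.residue_numbers) == len(self.chains) == n
        ):
            raise ValueError("field arrays must have equal length")
        self.residue_index = self._build_residue_index()

    def _build_residue_index(self) -> dict[tuple[str, int], tuple[int, int]]:
        index: dict[tuple[str, int], tuple[int, int]] = {}
        start = 0
        for i in range(1, self.n_atoms + 1):
            end_of_run = i == self.n_atoms or (
                self.chains[i] != self.chains[start]
                or self.residue_numbers[i] != self.residue_numbers[start]
            )
            if end_of_run:
                key = (str(self.chains[start]), int(self.residue_numbers[start]))
                if key in index:
                    raise ValueError(
                        f"residue {key} is not contiguous in the atom list"
                    )
                index[key] = (start, i)
                start = i
        return index

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def atoms(self) -> list[Atom]:
        return [
            Atom(
                serial=int(self.serials[i]),
                name=str(self.names[i]),
                element=str(self.elements[i]),
                residue_name=str(self.residue_names[i]),
                residue_number=int(self.residue_numbers[i]),
                chain=str(self.chains[i]),
                coords=self.coords[i],
            )
            for i in range(self.n_atoms)
        ]

    def residue_atoms(self, chain: str, residue_number: int) -> np.ndarray:
        """Indices of the atoms of one residue, in topology order."""
        start, end = self.residue_index[(chain, residue_number)]
        return np.arange(start, end)

    def atom_index(self, chain: str, residue_number: int, name: str) -> int:
        span = self.residue_atoms(chain, residue_number)
        for i in span:
            if self.names[i] == name:
                return int(i)
        raise KeyError(f"no atom {name!r} in residue {chain}/{residue_number}")

    def sequence(self, chain: str | None = None) -> str:
        """One-letter sequence of the (first) chain, in residue order."""
        if chain is None:
            chain = str(self.chains[0])
        seen: list[str] = []
        for (ch, _num), (start, _end) in self.residue_index.items():
            if ch == chain:
                seen.append(_THREE_TO_ONE.get(str(self.residue_names[start]), "X"))
        return "".join(seen)


class Trajectory:
    """A topology plus one (n_atoms, 3) Å coordinate array per frame."""

    def __init__(self, topology: Structure, frames: Sequence[np.ndarray]) -> None:
        if len(frames) < 1:
            raise ValueError("a trajectory needs at least one frame")
        self.topology = topology
        self.frames = [np.asarray(f, dtype=float) for f in frames]
        for i, f in enumerate(self.frames):
            if f.shape != (topology.n_atoms, 3):
                raise MalformedTrajectoryError(
                    f"frame {i} has shape {f.shape}, expected "
                    f"({topology.n_atoms}, 3)"
                )

    @property
    def frame_count(self) -> int:
        return len(self.frames)

    @property
    def coordinates(self) -> np.ndarray:
        """All frames stacked as (frame_count, n_atoms, 3)."""
        return np.stack(self.frames)

    def frame_structure(self, i: int) -> Structure:
        s = self.topology
        return Structure(
            s.serials, s.names, s.elements, s.residue_names,
            s.residue_numbers, s.chains, self.frames[i],
        )


@dataclass(frozen=True)
class HelixDefinition:
    """A labelled transmembrane helix given as an inclusive residue range."""

    label: str
    residue_range: tuple[int, int]

    def __post_init__(self) -> None:
        start, end = self.residue_range
        if start > end:
            raise ValueError(f"helix {self.label}: start {start} > end {end}")

    @property
    def start(self) -> int:
        return self.residue_range[0]

    @property
    def end(self) -> int:
        return self.residue_range[1]

    @property
    def n_residues(self) -> int:
        return self.end - self.start + 1


# The six TM helices of the carrier, author numbering (Met1 retained).
DEFAULT_HELICES: tuple[HelixDefinition, ...] = (
    HelixDefinition("H1", (10, 40)),
    HelixDefinition("H2", (76, 100)),
    HelixDefinition("H3", (110, 144)),
    HelixDefinition("H4", (172, 197)),
    HelixDefinition("H5", (209, 239)),
    HelixDefinition("H6", (269, 297)),
)

# Residue ranges of the cytoplasmic and matrix halves of the carrier,
# used for the gate-focused clustering selections.
CYTOPLASMIC_HALF: tuple[tuple[int, int], ...] = ((2, 17), (90, 117), (186, 220), (284, 301))
MATRIX_HALF: tuple[tuple[int, int], ...] = (
    (18, 39), (56, 89), (118, 143), (153, 185), (221, 239), (248, 283),
)


@dataclass
class AnalysisConfig:
    """Geometric cutoffs and selections driving every analysis stage.

    Units are Å for distances and degrees for angles.  The persistence
    threshold is a fraction of frames; interactions present in no more than
    that fraction are dropped from reports.
    """

    helices: tuple[HelixDefinition, ...] = DEFAULT_HELICES
    salt_bridge_cutoff: float = 4.0
    hbond_distance_cutoff: float = 3.0
    hbond_angle_cutoff: float = 135.0
    hydrophobic_cutoff: float = 4.5
    cation_pi_distance_cutoff: float = 6.0
    contact_map_cutoff: float = 4.5
    persistence_threshold: float = 0.10
    cluster_cutoff: float = 0.1
    his_in_salt_bridges: bool = False
    drop_first_frames: int = 0
    cytoplasmic_half: tuple[tuple[int, int], ...] = CYTOPLASMIC_HALF
    matrix_half: tuple[tuple[int, int], ...] = MATRIX_HALF

    def __post_init__(self) -> None:
        for name in (
            "salt_bridge_cutoff", "hbond_distance_cutoff", "hbond_angle_cutoff",
            "hydrophobic_cutoff", "cation_pi_distance_cutoff",
            "contact_map_cutoff", "cluster_cutoff",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 < self.persistence_threshold < 1.0:
            raise ValueError("persistence_threshold must be in (0, 1)")
        labels = [h.label for h in self.helices]
        if len(set(labels)) != len(labels):
            raise ValueError("helix labels must be unique")
        _check_disjoint([h.residue_range for h in self.helices], "helices")
        _check_disjoint(self.cytoplasmic_half, "cytoplasmic_half")
        _check_disjoint(self.matrix_half, "matrix_half")

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise KeyError(f"unknown config key(s): {sorted(unknown)}")
        if "helices" in data:
            data["helices"] = tuple(
                HelixDefinition(h["label"], (int(h["range"][0]), int(h["range"][1])))
                if isinstance(h, dict)
                else h
                for h in data["helices"]
            )
        for key in ("cytoplasmic_half", "matrix_half"):
            if key in data:
                data[key] = tuple((int(a), int(b)) for a, b in data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["helices"] = [
            {"label": h.label, "range": list(h.residue_range)} for h in self.helices
        ]
        out["cytoplasmic_half"] = [list(r) for r in self.cytoplasmic_half]
        out["matrix_half"] = [list(r) for r in self.matrix_half]
        return out

    def helix(self, label: str) -> HelixDefinition:
        for h in self.helices:
            if h.label == label:
                return h
        raise KeyError(f"no helix labelled {label!r}")


def _check_disjoint(ranges: Iterable[tuple[int, int]], what: str) -> None:
    spans = sorted(ranges)
    for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
        if b0 <= a1:
            raise ValueError(f"{what}: ranges {(a0, a1)} and {(b0, b1)} overlap")


# ---------------------------------------------------------------------------
# PDB I/O

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def _guess_element(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if len(stripped) >= 2 and stripped[:2].upper() in ("CL", "BR", "FE", "ZN", "MG", "NA"):
        return stripped[:2].capitalize()
    return stripped[:1].upper()


def read_pdb(path: str | Path) -> Trajectory:
    """Read a single- or multi-model PDB file into a :class:`Trajectory`.

    Every MODEL must list the same atoms in the same order.  Author residue
    numbers are preserved verbatim.  Alternate locations: the first altloc of
    each atom is kept.  Insertion codes are rejected.
    """
    path = Path(path)
    models: list[list[tuple]] = []
    current: list[tuple] | None = None
    seen_model_record = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            record = line[:6]
            if record == "MODEL ":
                seen_model_record = True
                if current is not None:
                    models.append(current)
                current = []
            elif record == "ENDMDL":
                if current is not None:
                    models.append(current)
                current = None
            elif record in ("ATOM  ", "HETATM"):
                if current is None:
                    current = []
                altloc = line[16]
                if altloc not in (" ", "", "A", "1"):
                    continue  # keep first altloc only
                if line[26] not in (" ", ""):
                    raise PdbParseError(
                        f"{path.name}:{lineno}: insertion codes are not supported"
                    )
                try:
                    serial = int(line[6:11])
                    name = line[12:16].strip()
                    resname = line[17:20].strip()
                    chain = line[21] if line[21] != " " else "A"
                    resnum = int(line[22:26])
                    xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
                except (ValueError, IndexError) as exc:
                    raise PdbParseError(
                        f"{path.name}:{lineno}: unparsable ATOM record ({exc})"
                    ) from None
                element = line[76:78].strip() if len(line) >= 78 else ""
                if not element:
                    element = _guess_element(name)
                current.append((serial, name, element, resname, resnum, chain, xyz))
    if current:
        models.append(current)
    if not models:
        raise PdbParseError(f"{path.name}: no ATOM/HETATM records found")
    if seen_model_record:
        models = [m for m in models if m]

    first = models[0]
    identity = [(a[1], a[3], a[4], a[5]) for a in first]
    for m, model in enumerate(models[1:], start=2):
        if len(model) != len(first):
            raise MalformedTrajectoryError(
                f"{path.name}: MODEL {m} has {len(model)} atoms, "
                f"MODEL 1 has {len(first)}"
            )
        if [(a[1], a[3], a[4], a[5]) for a in model] != identity:
            raise MalformedTrajectoryError(
                f"{path.name}: MODEL {m} atom identities differ from MODEL 1"
            )

    topology = Structure(
        serials=[a[0] for a in first],
        names=[a[1] for a in first],
        elements=[a[2] for a in first],
        residue_names=[a[3] for a in first],
        residue_numbers=[a[4] for a in first],
        chains=[a[5] for a in first],
        coords=np.array([a[6] for a in first], dtype=float),
    )
    frames = [np.array([a[6] for a in model], dtype=float) for model in models]
    return Trajectory(topology, frames)


def _format_atom_line(
    serial: int, name: str, resname: str, chain: str, resnum: int, xyz: np.ndarray,
    element: str,
) -> str:
    # PDB v3.3 convention: 1-3 character names start in column 14.
    if len(name) < 4:
        name_field = f" {name:<3s}"
    else:
        name_field = f"{name:<4s}"
    return (
        f"ATOM  {serial:>5d} {name_field} {resname:>3s} {chain:1s}{resnum:>4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element:>2s}\n"
    )


def write_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as (multi-model) PDB.

    Single-frame trajectories are written without MODEL records; multi-frame
    ones get one MODEL/ENDMDL block per frame.  Coordinates are rounded to
    the 3-decimal PDB precision.
    """
    if traj.frame_count < 1 or not traj.frames:
        raise ValueError("nothing to write: trajectory has no frames")
    top = traj.topology
    with open(path, "w") as fh:
        multi = traj.frame_count > 1
        for f, frame in enumerate(traj.frames, start=1):
            if multi:
                fh.write(f"MODEL {f:>8d}\n")
            for i in range(top.n_atoms):
                fh.write(
                    _format_atom_line(
                        int(top.serials[i]), str(top.names[i]),
                        str(top.residue_names[i]), str(top.chains[i]),
                        int(top.residue_numbers[i]), frame[i],
                        str(top.elements[i]),
                    )
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def select(
    obj: Trajectory | Structure,
    residue_ranges: Sequence[tuple[int, int]],
    atom_names: Iterable[str] | None = None,
) -> np.ndarray:
    """Atom indices whose residue falls in any inclusive range.

    If ``atom_names`` is given, the atom name must additionally be in that
    set (an empty set therefore selects nothing).  Indices come back in
    topology order; a selection matching nothing warns but is not an error.
    """
    top = obj.topology if isinstance(obj, Trajectory) else obj
    mask = np.zeros(top.n_atoms, dtype=bool)
    for start, end in residue_ranges:
        mask |= (top.residue_numbers >= start) & (top.residue_numbers <= end)
    if atom_names is not None:
        names = set(atom_names)
        mask &= np.array([n in names for n in top.names], dtype=bool)
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        warnings.warn(
            f"selection over ranges {list(residue_ranges)} matched no atoms",
            stacklevel=2,
        )
    return idx
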