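"""Conformational-asymmetry comparison between two carrier states.

Two structures (two states of one protein, or two homologs paired by a
global sequence alignment) are compared helix group by helix group: the
Cα atoms of each group are superposed independently and the all-pair RMSD
plus per-residue deviations are reported.  A group whose internal geometry
is conserved between the states fits to a small residual; a group whose
helices repack reports the repacking as RMSD.  Contact-map differencing
localizes the asymmetry to individual helix interfaces.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .geomcore import PairAlignment, kabsch_superpose
from .interactions import ContactMap
from .structio import HelixDefinition, Structure

__all__ = [
    "InterfaceComparison",
    "ContactDelta",
    "compare_helix_groups",
    "contact_asymmetry",
    "comparison_report",
]


@dataclass
class InterfaceComparison:
    group_label: str
    n_pairs: int
    rmsd: float
    per_residue: list[tuple[int, float]]  # (author residue number in A, Å)

    def to_dict(self) -> dict:
        return {
            "group": self.group_label,
            "n_pairs": self.n_pairs,
            "rmsd": self.rmsd,
            "per_residue": [[r, d] for r, d in self.per_residue],
        }


@dataclass(frozen=True)
class ContactDelta:
    interface: str
    count_a: int
    count_b: int

    @property
    def delta(self) -> int:
        return self.count_b - self.count_a


def _ca_map(structure: Structure) -> dict[tuple[str, int], int]:
    out = {}
    for i in range(structure.n_atoms):
        if structure.names[i] == "CA":
            out[(str(structure.chains[i]), int(structure.residue_numbers[i]))] = i
    return out


def _residue_order(structure: Structure) -> list[tuple[str, int]]:
    return list(structure.residue_index.keys())


def compare_helix_groups(
    struct_a: Structure,
    struct_b: Structure,
    groups: Sequence[Sequence[HelixDefinition]],
    pairing: PairAlignment | None = None,
) -> list[InterfaceComparison]:
    """Independent Kabsch superposition of each helix group's paired Cα.

    With ``pairing=None`` residues are paired by identical (chain, author
    number); a :class:`~carrierdyn.geomcore.PairAlignment` pairs them by
    alignment column instead (indices into each structure's residue order),
    the cross-homolog use case.  The RMSD is the all-pair RMSD after the
    group fit, with no iterative pruning.
    """
    ca_a = _ca_map(struct_a)
    ca_b = _ca_map(struct_b)
    if pairing is None:
        paired = [(key, key) for key in ca_a if key in ca_b]
    else:
        order_a = _residue_order(struct_a)
        order_b = _residue_order(struct_b)
        paired = [
            (order_a[i], order_b[j])
            for i, j in pairing.pairs
            if order_a[i] in ca_a and order_b[j] in ca_b
        ]
    results: list[InterfaceComparison] = []
    for group in groups:
        label = "-".join(h.label for h in group)
        ranges = [h.residue_range for h in group]
        in_group = [
            (ka, kb)
            for ka, kb in paired
            if any(lo <= ka[1] <= hi for lo, hi in ranges)
        ]
        if len(in_group) < 3:
            raise ValueError(
                f"group {label}: only {len(in_group)} paired residues, need ≥ 3"
            )
        xyz_a = np.array([struct_a.coords[ca_a[ka]] for ka, _ in in_group])
        xyz_b = np.array([struct_b.coords[ca_b[kb]] for _, kb in in_group])
        fit = kabsch_superpose(xyz_b, xyz_a)
        moved = fit.apply(xyz_b)
        dev = np.linalg.norm(moved - xyz_a, axis=1)
        results.append(
            InterfaceComparison(
                group_label=label,
                n_pairs=len(in_group),
                rmsd=fit.rmsd,
                per_residue=[
                    (ka[1], float(d)) for (ka, _), d in zip(in_group, dev)
                ],
            )
        )
    return results


def contact_asymmetry(map_a: ContactMap, map_b: ContactMap) -> list[ContactDelta]:
    """Per-interface contact-count differences, sorted by |delta| descending.

    Both maps must come from identical helix definitions and cutoff.
    ``delta = count_b - count_a``.
    """
    if map_a.cutoff != map_b.cutoff or map_a.helices != map_b.helices:
        raise ValueError("contact maps were built with different definitions")
    by_key_b = {(e.helix_a, e.helix_b): e for e in map_b.interfaces}
    deltas = []
    for ea in map_a.interfaces:
        key = (ea.helix_a, ea.helix_b)
        if key not in by_key_b:
            raise ValueError(f"interface {key} missing from second map")
        eb = by_key_b[key]
        deltas.append(ContactDelta(f"{ea.helix_a}-{ea.helix_b}", ea.count, eb.count))
    return sorted(deltas, key=lambda d: -abs(d.delta))


def comparison_report(
    comparisons: Sequence[InterfaceComparison],
    deltas: Sequence[ContactDelta] | None = None,
) -> dict:
    """JSON-serializable report of group RMSDs and contact deltas."""
    out: dict = {"groups": [c.to_dict() for c in comparisons]}
    if deltas is not None:
        out["contact_deltas"] = [
            {
                "interface": d.interface,
                "count_a": d.count_a,
                "count_b": d.count_b,
                "delta": d.delta,
            }
            for d in deltas
        ]
    return out
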