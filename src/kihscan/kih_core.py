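"""Knobs-into-holes detection between helix segments.

The packing unit is the side-chain center: the unweighted centroid of a
residue's heavy side-chain atoms (CA for glycine).  A residue is a *knob*
into another helix when its center lies within the packing cutoff of at
least four side-chain centers on that helix; the four nearest form its
*hole*.  A helix pair whose knobs are mutually inserted (each a member of
the other's hole) packs knobs-into-holes and is a candidate coiled-coil
interface.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .helix_model import HelixSegment
from .structure_io import Residue

__all__ = [
    "DEFAULT_CUTOFF",
    "SideChainCenter",
    "Contact",
    "Knob",
    "HelixPairInterface",
    "side_chain_center",
    "compute_centers",
    "contact_map",
    "find_knobs",
    "classify_knob",
    "pair_interfaces",
]

log = logging.getLogger(__name__)

#: Default packing cutoff in Angstrom.
DEFAULT_CUTOFF = 7.0
#: Packing-angle boundaries (degrees) of the 4-level knob classification.
TYPE_ANGLE_DEEP = 45.0
TYPE_ANGLE_LATERAL = 90.0
#: A helix pair is accepted as coiled coil with at least this many knobs
#: across both directions (and at least one complementary pair).
MIN_INTERFACE_KNOBS = 3


@dataclass(frozen=True)
class SideChainCenter:
    residue: Residue
    helix_id: int
    position: np.ndarray
    n_atoms: int


@dataclass(frozen=True)
class Contact:
    """An inter-helix side-chain-center pair within the packing cutoff."""

    residue_a: Residue
    residue_b: Residue
    helix_a: int
    helix_b: int
    distance: float


@dataclass
class Knob:
    knob_residue: Residue
    knob_helix: int
    hole_helix: int
    hole_residues: list[Residue]
    hole_center: np.ndarray
    hole_distances: list[float]
    knob_type: int = 0
    packing_angle: Optional[float] = None

    @property
    def key(self) -> tuple[tuple[str, str], int]:
        return (self.knob_residue.key, self.hole_helix)


@dataclass
class HelixPairInterface:
    helix_a: int
    helix_b: int
    knobs_ab: list[Knob]
    knobs_ba: list[Knob]
    complementary_pairs: list[tuple[Knob, Knob]]
    is_coiled_coil: bool

    @property
    def n_knobs(self) -> int:
        return len(self.knobs_ab) + len(self.knobs_ba)


def side_chain_center(r: Residue, helix_id: int = 0) -> Optional[SideChainCenter]:
    """Unweighted centroid of heavy side-chain atoms (CB outward).

    Glycine -- or any residue with no side-chain heavy atoms -- uses its
    CA position.  A residue with neither is skipped with a warning.
    """
    side = r.side_chain_atoms
    if side:
        pos = np.mean([a.position for a in side], axis=0)
        return SideChainCenter(r, helix_id, pos, len(side))
    ca = r.atom("CA")
    if ca is None:
        log.warning("residue %s/%s has no CA and no side chain; skipped",
                    r.chain_id, r.label)
        return None
    return SideChainCenter(r, helix_id, ca.position.copy(), 1)


def compute_centers(helices: list[HelixSegment]) -> dict[tuple[str, str], SideChainCenter]:
    """Side-chain centers for every residue of every helix segment."""
    centers: dict[tuple[str, str], SideChainCenter] = {}
    for h in helices:
        for r in h.residues:
            c = side_chain_center(r, h.helix_id)
            if c is not None:
                centers[r.key] = c
    return centers


def contact_map(helices: list[HelixSegment],
                centers: dict[tuple[str, str], SideChainCenter],
                cutoff: float = DEFAULT_CUTOFF) -> list[Contact]:
    """All inter-helix center pairs with distance <= cutoff (inclusive).

    Uses a k-d tree for the pair query; the result is identical to the
    all-pairs computation and is returned in a deterministic order.
    """
    if cutoff <= 0:
        raise ValueError("packing cutoff must be positive")
    items = sorted(centers.values(),
                   key=lambda c: (c.residue.chain_id, c.residue.seq_id,
                                  c.residue.icode))
    if len(items) < 2:
        return []
    pts = np.array([c.position for c in items])
    tree = cKDTree(pts)
    contacts = []
    for i, j in tree.query_pairs(cutoff):
        a, b = items[i], items[j]
        if a.helix_id == b.helix_id:
            continue
        d = float(np.linalg.norm(a.position - b.position))
        contacts.append(Contact(a.residue, b.residue, a.helix_id, b.helix_id, d))
    contacts.sort(key=lambda c: (c.residue_a.chain_id, c.residue_a.seq_id,
                                 c.residue_a.icode, c.residue_b.chain_id,
                                 c.residue_b.seq_id, c.residue_b.icode))
    return contacts


def find_knobs(contacts: list[Contact],
               centers: dict[tuple[str, str], SideChainCenter],
               cutoff: float = DEFAULT_CUTOFF) -> list[Knob]:
    """Knobs from the contact map: >=4 contacts on one target helix.

    The hole is the 4 contacted residues nearest the knob's center, ties
    broken by ascending residue number.  A residue may be a knob into
    several helices -- one record per target helix.
    """
    per_target: dict[tuple[tuple[str, str], int], list[tuple[float, Residue]]] = {}
    for c in contacts:
        per_target.setdefault((c.residue_a.key, c.helix_b), []).append(
            (c.distance, c.residue_b))
        per_target.setdefault((c.residue_b.key, c.helix_a), []).append(
            (c.distance, c.residue_a))
    knobs = []
    for (res_key, target_helix), hits in sorted(
            per_target.items(), key=lambda kv: (kv[0][0], kv[0][1])):
        if len(hits) < 4:
            continue
        hits.sort(key=lambda t: (t[0], t[1].seq_id, t[1].icode))
        hole = hits[:4]
        knob_center = centers[res_key]
        hole_positions = [centers[r.key].position for _, r in hole]
        knobs.append(Knob(
            knob_residue=knob_center.residue,
            knob_helix=knob_center.helix_id,
            hole_helix=target_helix,
            hole_residues=[r for _, r in hole],
            hole_center=np.mean(hole_positions, axis=0),
            hole_distances=[d for d, _ in hole],
        ))
    knobs.sort(key=lambda k: (k.knob_residue.chain_id, k.knob_residue.seq_id,
                              k.knob_residue.icode, k.hole_helix))
    return knobs


def classify_knob(k: Knob, centers: dict[tuple[str, str], SideChainCenter],
                  cutoff: float = DEFAULT_CUTOFF) -> Knob:
    """Assign the packing angle and the 4-level knob type in place.

    The packing angle is the angle at CA between the side-chain-center
    direction and the hole-center direction: 0 deg means the side chain
    points straight into the hole.  Types: 4 = CA itself within cutoff of
    all four hole centers and angle < 45 deg (through-hole insertion);
    3 = angle < 45 deg; 2 = 45-90 deg; 1 = peripheral (>= 90 deg or
    undefined, e.g. glycine where CA is the center).
    """
    ca = k.knob_residue.atom("CA")
    center = centers[k.knob_residue.key].position
    if ca is None:
        k.packing_angle, k.knob_type = None, 1
        return k
    v_side = center - ca.position
    v_hole = k.hole_center - ca.position
    ns, nh = np.linalg.norm(v_side), np.linalg.norm(v_hole)
    if ns < 1e-6 or nh < 1e-6:
        k.packing_angle, k.knob_type = None, 1
        return k
    cosang = float(np.clip(np.dot(v_side, v_hole) / (ns * nh), -1.0, 1.0))
    angle = math.degrees(math.acos(cosang))
    k.packing_angle = angle
    if angle < TYPE_ANGLE_DEEP:
        deep = all(
            np.linalg.norm(centers[r.key].position - ca.position) <= cutoff
            for r in k.hole_residues)
        k.knob_type = 4 if deep else 3
    elif angle < TYPE_ANGLE_LATERAL:
        k.knob_type = 2
    else:
        k.knob_type = 1
    return k


def pair_interfaces(knobs: list[Knob],
                    min_knobs: int = MIN_INTERFACE_KNOBS) -> list[HelixPairInterface]:
    """Group knobs per unordered helix pair and test complementarity.

    Knobs k1 (A into B) and k2 (B into A) are complementary when each is
    a member of the other's hole.  A pair is a coiled-coil interface when
    it has at least one complementary pair and ``min_knobs`` knobs in
    total across both directions.
    """
    by_pair: dict[tuple[int, int], list[Knob]] = {}
    for k in knobs:
        pair = (min(k.knob_helix, k.hole_helix), max(k.knob_helix, k.hole_helix))
        by_pair.setdefault(pair, []).append(k)
    interfaces = []
    for (ha, hb) in sorted(by_pair):
        members = by_pair[(ha, hb)]
        knobs_ab = [k for k in members if k.knob_helix == ha]
        knobs_ba = [k for k in members if k.knob_helix == hb]
        comp = []
        for k1 in knobs_ab:
            hole1 = {r.key for r in k1.hole_residues}
            for k2 in knobs_ba:
                if (k2.knob_residue.key in hole1
                        and k1.knob_residue.key in {r.key for r in k2.hole_residues}):
                    comp.append((k1, k2))
        interfaces.append(HelixPairInterface(
            helix_a=ha, helix_b=hb, knobs_ab=knobs_ab, knobs_ba=knobs_ba,
            complementary_pairs=comp,
            is_coiled_coil=bool(comp) and len(members) >= min_knobs))
    return interfaces
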