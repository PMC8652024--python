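"""Assemble knobs-into-holes interfaces into coiled coils and assign registers.

Helices are nodes and accepted KIH interfaces are edges of a graph; each
connected component of two or more helices is one coiled-coil assembly,
with no upper bound on the number of helices.  A component containing a
graph cycle is reported as cyclic -- the signature of an α-helical
barrel, where each helix packs only against its two ring neighbours.
Heptad registers (a-g) are anchored on knob spacings: knobs 3 residues
apart sit at a and d, knobs 4 apart at d and a, and the register is
propagated over the helix by heptad arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

from .geometry import HelixAxis, interhelix_angle
from .helix_model import HelixSegment
from .kih_core import HelixPairInterface, Knob

__all__ = [
    "CoiledCoilAssembly",
    "RegisterAssignment",
    "assemble",
    "pair_orientation",
    "assign_register",
]

_LETTERS = "abcdefg"


@dataclass
class RegisterAssignment:
    """Heptad register for one helix, anchored on its knob spacings."""

    helix_id: int
    letters: dict[tuple[str, str], str]  # residue key -> a..g
    anchor_residue: Optional[str] = None
    anchor_letter: Optional[str] = None
    conflicts: int = 0  # knob-spacing anchors disagreeing with the adopted phase


@dataclass
class CoiledCoilAssembly:
    cc_id: int
    helices: list[HelixSegment]
    interfaces: list[HelixPairInterface]
    topology: str = "open"  # open | cyclic
    orientations: dict[tuple[int, int], str] = field(default_factory=dict)
    pair_angles: dict[tuple[int, int], Optional[float]] = field(default_factory=dict)
    registers: dict[int, RegisterAssignment] = field(default_factory=dict)

    @property
    def order(self) -> int:
        return len(self.helices)

    def register_of(self, residue_key: tuple[str, str]) -> str:
        for reg in self.registers.values():
            if residue_key in reg.letters:
                return reg.letters[residue_key]
        return ""

    def knobs(self) -> list[Knob]:
        out = []
        for iface in self.interfaces:
            out.extend(iface.knobs_ab)
            out.extend(iface.knobs_ba)
        return out


def assemble(interfaces: list[HelixPairInterface],
             helices: list[HelixSegment]) -> list[CoiledCoilAssembly]:
    """Connected components of the coiled-coil interface graph.

    Only interfaces with ``is_coiled_coil`` contribute edges.  Components
    are ordered by (smallest chain id, smallest first residue) of their
    member helices so output is stable across runs.
    """
    by_id = {h.helix_id: h for h in helices}
    graph = nx.Graph()
    accepted = [i for i in interfaces if i.is_coiled_coil]
    for iface in accepted:
        graph.add_edge(iface.helix_a, iface.helix_b)
    assemblies = []
    for component in nx.connected_components(graph):
        members = sorted(component)
        if len(members) < 2:
            continue
        sub = graph.subgraph(component)
        member_helices = [by_id[m] for m in members]
        assemblies.append(CoiledCoilAssembly(
            cc_id=0,
            helices=member_helices,
            interfaces=[i for i in accepted if i.helix_a in component],
            topology="cyclic" if sub.number_of_edges() >= sub.number_of_nodes()
                     else "open",
        ))
    assemblies.sort(key=lambda a: (min(h.chain_id for h in a.helices),
                                   min(h.first.seq_id for h in a.helices)))
    for i, a in enumerate(assemblies, start=1):
        a.cc_id = i
    return assemblies


def pair_orientation(ha: HelixSegment, hb: HelixSegment,
                     axes: dict[int, Optional[HelixAxis]]
                     ) -> tuple[str, Optional[float]]:
    """Parallel/antiparallel call for a helix pair from their fitted axes.

    The crossing angle is arccos of the dot product of the N->C unit axis
    vectors; < 90 deg is parallel (ties to parallel), otherwise
    antiparallel.  Returns ("unassigned", None) when either axis could
    not be fitted.
    """
    axis_a, axis_b = axes.get(ha.helix_id), axes.get(hb.helix_id)
    if axis_a is None or axis_b is None:
        return "unassigned", None
    angle = interhelix_angle(axis_a, axis_b)
    return ("parallel" if angle < 90.0 else "antiparallel"), angle


def assign_register(h: HelixSegment, knobs_on_h: list[Knob]) -> RegisterAssignment:
    """Heptad register for one helix from the spacings of its knobs.

    Consecutive knob residues i < j anchor the register: spacing 3 means
    (i=a, j=d); spacing 4 means (i=d, j=a).  Each anchor implies a heptad
    phase; the majority phase is adopted (earliest anchor wins ties) and
    dissenting anchors are counted as conflicts.  Spacings that are
    neither 3 nor 4 (mod-7 ambiguous) contribute no anchor.  With fewer
    than 2 knobs, or no usable spacing, the register stays unassigned.
    """
    reg = RegisterAssignment(helix_id=h.helix_id, letters={})
    positions = sorted({k.knob_residue.seq_id for k in knobs_on_h
                        if any(r is k.knob_residue for r in h.residues)})
    if len(positions) < 2:
        return reg
    # phase p: residue with seq_id s gets letter (s + p) mod 7
    anchors: list[int] = []
    for i, j in zip(positions, positions[1:]):
        spacing = j - i
        if spacing == 3:
            anchors.append((0 - i) % 7)   # i -> 'a'
        elif spacing == 4:
            anchors.append((3 - i) % 7)   # i -> 'd'
    if not anchors:
        return reg
    counts: dict[int, int] = {}
    for p in anchors:
        counts[p] = counts.get(p, 0) + 1
    best = max(counts.values())
    phase = next(p for p in anchors if counts[p] == best)
    reg.conflicts = sum(1 for p in anchors if p != phase)
    for r in h.residues:
        if not r.icode:
            reg.letters[r.key] = _LETTERS[(r.seq_id + phase) % 7]
    anchor_seq = positions[0]
    reg.anchor_residue = str(anchor_seq)
    reg.anchor_letter = _LETTERS[(anchor_seq + phase) % 7]
    return reg


def annotate_assembly(assembly: CoiledCoilAssembly,
                      axes: dict[int, Optional[HelixAxis]]) -> CoiledCoilAssembly:
    """Fill in orientations, pair angles and per-helix registers."""
    by_id = {h.helix_id: h for h in assembly.helices}
    for iface in assembly.interfaces:
        ha, hb = by_id[iface.helix_a], by_id[iface.helix_b]
        orientation, angle = pair_orientation(ha, hb, axes)
        assembly.orientations[(iface.helix_a, iface.helix_b)] = orientation
        assembly.pair_angles[(iface.helix_a, iface.helix_b)] = (
            round(angle, 1) if angle is not None else None)
    knobs = assembly.knobs()
    for h in assembly.helices:
        mine = [k for k in knobs if k.knob_helix == h.helix_id]
        assembly.registers[h.helix_id] = assign_register(h, mine)
    return assembly
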