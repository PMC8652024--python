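"""Idealized coiled-coil generator and brute-force knob oracle.

Backbones follow the classic two-level (Crick) parameterization: an
α-helix of radius R1 wound on a left-handed superhelix of radius R0 and
pitch P.  Backbone atom geometry comes from a template α-helix built
internally from ideal bond lengths, angles and (φ, ψ) torsions; each atom
type's cylindrical offsets relative to CA are transferred onto the local
superhelical frame.  A single pseudo side-chain atom (CB, on the local
outward bisector at the standard Cα-Cβ bond length) stands in for the
side chain, which is all a side-chain-center-based knobs-into-holes
search needs.

The module also carries :func:`brute_force_knobs`, a deliberately naive
all-pairs re-derivation of the knob definition used as an independent
oracle against the production detector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .helix_model import HelixSegment
from .kih_core import compute_centers, side_chain_center
from .structure_io import Atom, Residue, Structure

__all__ = [
    "CrickParams",
    "crick_backbone",
    "parallel_dimer",
    "antiparallel_dimer",
    "barrel",
    "core_heptad_classes",
    "brute_force_knobs",
    "knob_signature",
]

_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclass(frozen=True)
class CrickParams:
    """Parameters of an idealized coiled-coil bundle.

    Defaults are canonical dimer values from the coiled-coil literature:
    superhelical radius R0 = 4.9 A, helix (CA) radius R1 = 2.26 A,
    3.62 residues per α-helical turn and superhelical pitch P = 148 A.
    ``interface_phase`` sets which minor-helix positions face the bundle
    core (None picks the canonical a/d-straddling phase);
    ``orientations`` holds +1 (N->C up) or -1 per helix; ``jitter`` adds
    seeded Gaussian coordinate noise (keep < 0.3 A for stable
    assignments).
    """

    n_helices: int = 2
    superhelical_radius: float = 4.9   # R0, A
    helix_radius: float = 2.26         # R1, A (CA radius)
    residues_per_turn: float = 3.62    # minor helix, lab frame
    pitch: float = 148.0               # superhelical pitch P, A
    rise_per_residue: float = 1.495    # along the superhelical path, A
    n_residues: int = 28
    phase_offsets: Optional[Sequence[float]] = None   # azimuth per helix, rad
    interface_phase: Optional[float] = None           # minor phase of the core
    orientations: Optional[Sequence[int]] = None      # +1 / -1 per helix
    z_offsets: Optional[Sequence[float]] = None       # axial shift per helix, A
    jitter: float = 0.0                # Gaussian sigma, A
    seed: int = 0
    residue_name: str = "ALA"
    #: distance (A) from CA to the pseudo side-chain atom, placed along
    #: the local outward bisector (the minor-helix radial through CA) at
    #: the standard Cα-Cβ bond length.
    side_chain_reach: float = 1.53

    def __post_init__(self) -> None:
        if self.n_helices < 1:
            raise ValueError("n_helices must be >= 1")
        if self.superhelical_radius < 0:
            raise ValueError("superhelical radius R0 must be >= 0")
        if self.pitch <= 0:
            raise ValueError("superhelical pitch P must be > 0")
        if self.n_residues < 7:
            raise ValueError("need at least one heptad of residues")
        if self.jitter >= 0.3:
            raise ValueError("jitter >= 0.3 A destabilizes assignments")

    @property
    def rise_z(self) -> float:
        """Rise per residue along the superhelix (z) axis."""
        alpha = math.atan2(2 * math.pi * self.superhelical_radius, self.pitch)
        return self.rise_per_residue * math.cos(alpha)

    @property
    def minor_twist(self) -> float:
        """Per-residue minor-helix rotation in the superhelical rotating
        frame (radians); the left-handed supercoil absorbs the difference
        between the lab-frame twist and the heptad-averaged 3.5."""
        return 2 * math.pi / self.residues_per_turn + 2 * math.pi * self.rise_z / self.pitch

    @property
    def default_interface_phase(self) -> float:
        # core (a/d) positions straddle the inward direction psi = pi
        return math.pi - self.minor_twist / 4.0

    def helix_phase(self, j: int) -> float:
        base = 2 * math.pi * j / self.n_helices
        if self.phase_offsets is not None:
            base += self.phase_offsets[j]
        return base

    def helix_orientation(self, j: int) -> int:
        if self.orientations is None:
            return 1
        return 1 if self.orientations[j] >= 0 else -1


# --- ideal α-helix template -------------------------------------------------

_BOND_N_CA, _BOND_CA_C, _BOND_C_N, _BOND_C_O = 1.458, 1.525, 1.329, 1.231
_ANG_N_CA_C, _ANG_CA_C_N, _ANG_C_N_CA, _ANG_CA_C_O = 111.2, 116.6, 121.9, 120.8
_PHI, _PSI, _OMEGA = -57.8, -47.0, 180.0


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d from internal coordinates (natural extension frame)."""
    angle, torsion = math.radians(angle_deg), math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(torsion),
        bond * math.sin(angle) * math.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _ideal_helix_backbone(n: int, phi: float = _PHI,
                          psi: float = _PSI) -> list[dict[str, np.ndarray]]:
    """n residues of an ideal peptide backbone (N, CA, C, O) built from
    bond lengths/angles and the given (φ, ψ) torsions; defaults are
    α-helical."""
    res: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_BOND_N_CA, 0.0, 0.0])
    ang = math.radians(_ANG_N_CA_C)
    c0 = ca0 + _BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    res.append({"N": n0, "CA": ca0, "C": c0})
    for _ in range(1, n):
        prev = res[-1]
        n_next = _nerf(prev["N"], prev["CA"], prev["C"], _BOND_C_N, _ANG_CA_C_N, psi)
        ca_next = _nerf(prev["CA"], prev["C"], n_next, _BOND_N_CA, _ANG_C_N_CA, _OMEGA)
        c_next = _nerf(prev["C"], n_next, ca_next, _BOND_CA_C, _ANG_N_CA_C, phi)
        res.append({"N": n_next, "CA": ca_next, "C": c_next})
    for i, r in enumerate(res):
        if i + 1 < len(res):
            u = r["C"] - r["CA"]
            v = r["C"] - res[i + 1]["N"]
            bis = u / np.linalg.norm(u) + v / np.linalg.norm(v)
            r["O"] = r["C"] + _BOND_C_O * bis / np.linalg.norm(bis)
        else:
            r["O"] = _nerf(r["N"], r["CA"], r["C"], _BOND_C_O, _ANG_CA_C_O,
                           psi + 180.0)
    return res


def _helix_template() -> dict:
    """Cylindrical offsets of N, C, O relative to CA on the ideal helix.

    Fits the helix axis of a 15-residue ideal helix and records, for the
    middle residue, each backbone atom's (radius offset vs CA, azimuth
    offset vs CA, axial offset vs CA) plus the per-residue twist and the
    CA radius.
    """
    bb = _ideal_helix_backbone(15)
    cas = np.array([r["CA"] for r in bb])
    centroid = cas.mean(axis=0)
    _, _, vt = np.linalg.svd(cas - centroid)
    axis = vt[0]
    if np.dot(axis, cas[-1] - cas[0]) < 0:
        axis = -axis
    # orthonormal frame about the axis
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, axis)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - np.dot(ref, axis) * axis
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)

    def cyl(p: np.ndarray) -> tuple[float, float, float]:
        rel = p - centroid
        z = float(np.dot(rel, axis))
        x, y = float(np.dot(rel, e1)), float(np.dot(rel, e2))
        return math.hypot(x, y), math.atan2(y, x), z

    mid = 7
    r_ca, psi_ca, z_ca = cyl(bb[mid]["CA"])
    offsets = {}
    for name in ("N", "C", "O"):
        r, psi, z = cyl(bb[mid][name])
        dpsi = (psi - psi_ca + math.pi) % (2 * math.pi) - math.pi
        offsets[name] = (r - r_ca, dpsi, z - z_ca)
    _, psi_next, _ = cyl(bb[mid + 1]["CA"])
    twist = (psi_next - psi_ca) % (2 * math.pi)
    return {"ca_radius": r_ca, "offsets": offsets, "twist": twist}


_TEMPLATE = _helix_template()




def crick_backbone(p: CrickParams) -> Structure:
    """Generate an idealized coiled-coil Structure from Crick parameters.

    Each helix's CA trace follows the minor helix (radius R1) wound on a
    left-handed superhelix (radius R0, pitch P); N, C and O are placed
    from the ideal-helix template in the local superhelical frame, and a
    single pseudo side-chain CB is added on the local outward bisector.
    Helix *i* of a Cn arrangement is phase-rotated by 2πi/n; helices with
    orientation -1 run N->C in the -z direction.
    """
    rng = np.random.default_rng(p.seed) if p.jitter > 0 else None
    omega1 = p.minor_twist
    phi1 = (p.interface_phase if p.interface_phase is not None
            else p.default_interface_phase)
    rise_z = p.rise_z
    two_pi = 2 * math.pi
    s = Structure(source_format="pdb", name="crick-fixture")
    for j in range(p.n_helices):
        chain_id = _CHAIN_IDS[j % len(_CHAIN_IDS)]
        phi0 = p.helix_phase(j)
        sign = p.helix_orientation(j)
        # Antiparallel helices default to a two-residue axial shift so the
        # core ladders of up- and down-running neighbours interdigitate,
        # as they do in real antiparallel coiled coils.
        if p.z_offsets is not None:
            z_shift = p.z_offsets[j]
        else:
            z_shift = 0.0 if sign > 0 else -2.0 * rise_z
        residues: list[Residue] = []
        placed: list[dict[str, np.ndarray]] = []
        for k in range(p.n_residues):
            z = (k if sign > 0 else p.n_residues - 1 - k) * rise_z + z_shift
            dz_dk = sign * rise_z
            if p.superhelical_radius > 0:
                big_phi = phi0 - two_pi * z / p.pitch       # left-handed
                dphi_dk = -two_pi * dz_dk / p.pitch
                c0 = np.array([p.superhelical_radius * math.cos(big_phi),
                               p.superhelical_radius * math.sin(big_phi), z])
                tangent = np.array([
                    -p.superhelical_radius * math.sin(big_phi) * dphi_dk,
                    p.superhelical_radius * math.cos(big_phi) * dphi_dk,
                    dz_dk])
            else:
                big_phi = phi0
                c0 = np.array([0.0, 0.0, z])
                tangent = np.array([0.0, 0.0, dz_dk])
            t_hat = tangent / np.linalg.norm(tangent)
            radial = np.array([math.cos(big_phi), math.sin(big_phi), 0.0])
            n_hat = radial - np.dot(radial, t_hat) * t_hat
            n_hat /= np.linalg.norm(n_hat)
            b_hat = np.cross(t_hat, n_hat)
            psi_ca = phi1 + omega1 * k

            def at(radius_off: float, dpsi: float, dz: float) -> np.ndarray:
                radius = p.helix_radius + radius_off
                psi = psi_ca + dpsi
                return (c0 + dz * t_hat
                        + radius * (math.cos(psi) * n_hat + math.sin(psi) * b_hat))

            coords = {"CA": at(0.0, 0.0, 0.0)}
            for name, (dr, dpsi, dz) in _TEMPLATE["offsets"].items():
                coords[name] = at(dr, dpsi, dz)
            # pseudo side chain: outward bisector = the minor-helix radial
            # through CA, extended by the Cα-Cβ bond length
            coords["CB"] = at(p.side_chain_reach, 0.0, 0.0)
            if rng is not None:
                for name in coords:
                    coords[name] = coords[name] + rng.normal(0.0, p.jitter, 3)
            placed.append(coords)
            atoms = [Atom(name, "C" if name in ("CA", "C", "CB") else name[0],
                          coords[name])
                     for name in ("N", "CA", "C", "O", "CB")]
            residues.append(Residue(chain_id=chain_id, seq_id=k + 1, icode="",
                                    name=p.residue_name, atoms=atoms))
        s.chains[chain_id] = residues
    from .structure_io import apply_modres
    return apply_modres(s)


def parallel_dimer(**overrides) -> Structure:
    """Canonical parallel two-helix coiled coil."""
    return crick_backbone(CrickParams(n_helices=2, **overrides))


def antiparallel_dimer(**overrides) -> Structure:
    """Canonical antiparallel two-helix coiled coil."""
    overrides.setdefault("orientations", (1, -1))
    return crick_backbone(CrickParams(n_helices=2, **overrides))


#: Axis-to-axis packing distance targeted between ring neighbours of a
#: Cn barrel fixture (A); sets the barrel radius via R0 = d / (2 sin(pi/n)).
BARREL_PACKING_DISTANCE = 9.2
#: Superhelical pitch per unit radius kept constant across barrel sizes so
#: the pitch angle matches the canonical dimer values.
_PITCH_PER_RADIUS = 148.0 / 4.9


def barrel(n: int, **overrides) -> Structure:
    """Cn α-helical barrel fixture: n helices in a cyclic ring.

    The superhelical radius grows with n so that ring neighbours keep a
    constant packing distance, and the pitch scales with the radius so
    the superhelical pitch angle stays at the canonical dimer value.
    """
    if n < 2:
        raise ValueError("a barrel needs at least 2 helices")
    r0 = overrides.pop("superhelical_radius",
                       BARREL_PACKING_DISTANCE / (2 * math.sin(math.pi / n)))
    pitch = overrides.pop("pitch", _PITCH_PER_RADIUS * r0)
    return crick_backbone(CrickParams(
        n_helices=n, superhelical_radius=r0, pitch=pitch, **overrides))


def core_heptad_classes(p: CrickParams) -> set[int]:
    """The two residue classes (mod 7) the generator points at the core.

    These are the intended knob positions: the two heptad classes whose
    mean minor-helix phase lies closest to the inward direction psi = pi.
    """
    omega1 = p.minor_twist
    phi1 = (p.interface_phase if p.interface_phase is not None
            else p.default_interface_phase)
    dist = {}
    for cls in range(7):
        ds = []
        for k in range(cls, p.n_residues, 7):
            psi = phi1 + omega1 * k
            ds.append(abs((psi - math.pi + math.pi) % (2 * math.pi) - math.pi))
        dist[cls] = float(np.mean(ds))
    ranked = sorted(range(7), key=lambda c: dist[c])
    return set(ranked[:2])


# --- independent oracle -----------------------------------------------------

def brute_force_knobs(s: Structure, helices: list[HelixSegment],
                      cutoff: float) -> dict:
    """Literal all-pairs re-derivation of the knob/hole definition.

    No spatial indexing: every pair of side-chain centers on different
    helices is measured; a residue with >= 4 partners within the cutoff
    on one helix is a knob and its hole is the 4 nearest (ties by
    ascending residue number).  Returns ``{(knob_key, hole_helix):
    (hole_key_1..4 sorted)}`` for set-wise comparison with the
    production detector.
    """
    entries = []
    for h in helices:
        for r in h.residues:
            c = side_chain_center(r, h.helix_id)
            if c is not None:
                entries.append(c)
    result = {}
    for me in entries:
        partners: dict[int, list[tuple[float, Residue]]] = {}
        for other in entries:
            if other.helix_id == me.helix_id or other is me:
                continue
            d = float(np.linalg.norm(me.position - other.position))
            if d <= cutoff:
                partners.setdefault(other.helix_id, []).append((d, other.residue))
        for helix_id, hits in partners.items():
            if len(hits) < 4:
                continue
            hits.sort(key=lambda t: (t[0], t[1].seq_id, t[1].icode))
            hole = tuple(sorted(r.key for _, r in hits[:4]))
            result[(me.residue.key, helix_id)] = hole
    return result


def knob_signature(knobs) -> dict:
    """Reduce production Knob records to the oracle's comparison form."""
    return {(k.knob_residue.key, k.hole_helix):
            tuple(sorted(r.key for r in k.hole_residues))
            for k in knobs}
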