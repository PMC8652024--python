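"""Helix-axis fitting and interface geometry.

A helix axis is the principal component of the segment's CA coordinates,
sign-fixed to point N->C.  Crossing (interhelix) angles are the unsigned
angle between two fitted axes in [0, 180] degrees; per-knob packing
angles are tabulated for reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional

import numpy as np
import pandas as pd

from .helix_model import HelixSegment

if TYPE_CHECKING:  # pragma: no cover
    from .cc_assembly import CoiledCoilAssembly

__all__ = ["HelixAxis", "fit_helix_axis", "interhelix_angle", "knob_packing_angles"]

MIN_AXIS_RESIDUES = 7


@dataclass(frozen=True)
class HelixAxis:
    centroid: np.ndarray
    direction: np.ndarray  # unit vector, N -> C
    #: straightness diagnostic: RMS spread of the CA radial distances about
    #: their mean.  An ideal straight helix scores ~0 (every CA sits at the
    #: helix radius); kinks and curvature inflate it.
    rmsd: float


def fit_helix_axis(h: HelixSegment) -> Optional[HelixAxis]:
    """Least-squares line through the CA trace (first principal component).

    Returns None when fewer than ``MIN_AXIS_RESIDUES`` CA atoms are
    available.  The direction satisfies direction . (CA_last - CA_first) > 0.
    """
    cas = [r.atom("CA") for r in h.residues]
    pts = np.array([a.position for a in cas if a is not None])
    if len(pts) < MIN_AXIS_RESIDUES:
        return None
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    span = pts[-1] - pts[0]
    if float(np.dot(direction, span)) < 0:
        direction = -direction
    residual = centered - np.outer(centered @ direction, direction)
    radii = np.linalg.norm(residual, axis=1)
    rmsd = float(np.sqrt(np.mean((radii - radii.mean()) ** 2)))
    return HelixAxis(centroid=centroid, direction=direction / np.linalg.norm(direction),
                     rmsd=rmsd)


def interhelix_angle(a: HelixAxis, b: HelixAxis) -> float:
    """Unsigned crossing angle between two fitted axes, degrees in [0, 180]."""
    cosang = float(np.clip(np.dot(a.direction, b.direction), -1.0, 1.0))
    return math.degrees(math.acos(cosang))


def knob_packing_angles(assembly: "CoiledCoilAssembly") -> pd.DataFrame:
    """One row per knob of the assembly: identity, packing angle, type.

    Knobs with an undefined angle (glycine: CA is the side-chain center)
    appear with a missing packing_angle.
    """
    rows = []
    for iface in assembly.interfaces:
        for k in iface.knobs_ab + iface.knobs_ba:
            r = k.knob_residue
            rows.append({
                "cc_id": assembly.cc_id,
                "chain": r.chain_id,
                "residue": r.label,
                "name": r.name,
                "knob_helix": k.knob_helix,
                "hole_helix": k.hole_helix,
                "packing_angle": (round(k.packing_angle, 1)
                                  if k.packing_angle is not None else None),
                "knob_type": k.knob_type,
            })
    df = pd.DataFrame(rows, columns=["cc_id", "chain", "residue", "name",
                                     "knob_helix", "hole_helix",
                                     "packing_angle", "knob_type"])
    if not df.empty:
        df = df.sort_values(["chain", "knob_helix", "residue", "hole_helix"],
                            key=_natural_key).reset_index(drop=True)
    return df


def _natural_key(col: pd.Series) -> pd.Series:
    if col.name == "residue":
        return col.map(lambda s: int("".join(c for c in str(s) if c.isdigit() or c == "-")
                                     or 0))
    return col
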