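"""Per-residue helix assignment and helix-segment construction.

Two routes produce the same :class:`SecondaryStructureMap`: parsing a
classic DSSP output file, or an internal assigner that applies the
Kabsch-Sander electrostatic hydrogen-bond model to the backbone.  Maximal
runs of 'H' residues become :class:`HelixSegment` objects, optionally
grown at each end by the helix-extension parameter before the
knobs-into-holes search.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .structure_io import Residue, Structure

__all__ = [
    "SecondaryStructureMap",
    "HelixSegment",
    "DsspMismatchError",
    "parse_dssp",
    "assign_helices_internal",
    "build_helices",
    "extend_helices",
    "MIN_HELIX_LENGTH",
]

log = logging.getLogger(__name__)

#: Minimum helix length in residues (one heptad): a helix shorter than one
#: repeat cannot carry a meaningful coiled-coil register.
MIN_HELIX_LENGTH = 7

_SS_CODES = {"H", "G", "I", "E"}

# Kabsch & Sander electrostatic model: E = q1*q2*f * (1/rON + 1/rCH - 1/rOH - 1/rCN)
# with |q1*q2*f| = 0.42*0.20*332 = 27.888 kcal/mol*A; the short O..H and long
# C..N distances of a real hydrogen bond make the bracket negative, so the
# coupling enters with positive sign and a bond is called below -0.5 kcal/mol.
_KS_COUPLING = 27.888
_KS_CUTOFF = -0.5
_MIN_DIST = 0.5  # guard against singular 1/r for clashing coordinates


class DsspMismatchError(Exception):
    """Residues listed in the DSSP file are absent from the structure."""


@dataclass
class SecondaryStructureMap:
    """ss code per (chain_id, residue label); codes H/G/I/E/other."""

    codes: dict[tuple[str, str], str]
    source: str  # "dssp_file" | "internal"
    #: ordered pairs of residue keys straddling an explicit chain break
    breaks: set[tuple[tuple[str, str], tuple[str, str]]] = field(default_factory=set)

    def code(self, chain_id: str, label: str) -> str:
        return self.codes.get((chain_id, str(label)), "other")


@dataclass
class HelixSegment:
    """A maximal run of α-helical residues on one chain."""

    helix_id: int
    chain_id: str
    residues: list[Residue]
    extended_n: int = 0
    extended_c: int = 0

    @property
    def first(self) -> Residue:
        return self.residues[0]

    @property
    def last(self) -> Residue:
        return self.residues[-1]

    def __len__(self) -> int:
        return len(self.residues)

    def __contains__(self, residue: Residue) -> bool:
        return any(r is residue for r in self.residues)

    @property
    def residue_keys(self) -> list[tuple[str, str]]:
        return [r.key for r in self.residues]

    def describe(self) -> str:
        return (f"helix {self.helix_id}: chain {self.chain_id} "
                f"{self.first.label}-{self.last.label} ({len(self)} res)")


def parse_dssp(path: str | Path, s: Structure) -> SecondaryStructureMap:
    """Parse a classic fixed-column DSSP output file.

    Only chain, residue number+icode and the summary secondary-structure
    code are read.  ``'!'`` chain-break markers are recorded so segments
    never span them.  Residues listed in the DSSP file but missing from
    ``s`` raise :class:`DsspMismatchError` naming the offenders.
    """
    text = Path(path).read_text()
    if text.lstrip().startswith(("data_", "#")) and "_dssp" in text[:2000]:
        raise DsspMismatchError(
            "mmCIF-flavoured DSSP output is not supported; "
            "supply classic fixed-column DSSP or use the internal assigner")
    codes: dict[tuple[str, str], str] = {}
    breaks: set[tuple[tuple[str, str], tuple[str, str]]] = set()
    in_data = False
    missing: list[str] = []
    prev_key: Optional[tuple[str, str]] = None
    pending_break = False
    for line in text.splitlines():
        if not in_data:
            if line.lstrip().startswith("#") and "RESIDUE" in line and "AA" in line:
                in_data = True
            continue
        if len(line) > 13 and line[13] == "!":
            pending_break = True
            continue
        if len(line) < 17:
            continue
        label = (line[5:10].strip() + line[10].strip())
        chain = line[11].strip()
        if not label:
            continue
        key = (chain, label)
        if s.residue(chain, label) is None:
            missing.append(f"{chain}/{label}")
        code = line[16].strip()
        codes[key] = code if code in _SS_CODES else "other"
        if pending_break and prev_key is not None:
            breaks.add((prev_key, key))
        pending_break = False
        prev_key = key
    if not codes:
        raise DsspMismatchError("no residue records found in DSSP file")
    if missing:
        raise DsspMismatchError(
            "DSSP residues absent from structure: " + ", ".join(missing[:20]))
    return SecondaryStructureMap(codes=codes, source="dssp_file", breaks=breaks)


def _backbone(r: Residue) -> Optional[dict[str, np.ndarray]]:
    out = {}
    for name in ("N", "CA", "C", "O"):
        a = r.atom(name)
        if a is None:
            return None
        out[name] = a.position
    return out


def _hbond_energy(acceptor: dict[str, np.ndarray],
                  donor: dict[str, np.ndarray],
                  donor_prev: dict[str, np.ndarray]) -> float:
    """Kabsch-Sander energy of CO(acceptor) ... HN(donor), kcal/mol.

    The amide hydrogen is reconstructed from the preceding peptide plane:
    H sits 1 A from N, opposite the preceding carbonyl C=O direction.
    """
    co = donor_prev["C"] - donor_prev["O"]
    norm = np.linalg.norm(co)
    h = donor["N"] + co / norm if norm > 1e-9 else donor["N"]
    r_on = max(np.linalg.norm(acceptor["O"] - donor["N"]), _MIN_DIST)
    r_ch = max(np.linalg.norm(acceptor["C"] - h), _MIN_DIST)
    r_oh = max(np.linalg.norm(acceptor["O"] - h), _MIN_DIST)
    r_cn = max(np.linalg.norm(acceptor["C"] - donor["N"]), _MIN_DIST)
    return _KS_COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def assign_helices_internal(s: Structure) -> SecondaryStructureMap:
    """Assign α-helix codes from backbone geometry alone.

    Hydrogen bonds are called with the Kabsch-Sander electrostatic model;
    residue *i* starts a 4-turn when CO(i)...HN(i+4) is bonded, and a
    residue is labelled H when it lies inside two consecutive 4-turns --
    the standard DSSP α-helix convention.  Residues with missing backbone
    atoms are labelled 'other' with a warning.
    """
    codes: dict[tuple[str, str], str] = {}
    for chain_id, residues in s.chains.items():
        bb = []
        for r in residues:
            b = _backbone(r)
            if b is None:
                log.warning("missing backbone atoms in %s/%s; labelled 'other'",
                            chain_id, r.label)
            bb.append(b)
        n = len(residues)
        turn4 = [False] * n
        for i in range(n):
            j = i + 4
            if j >= n or bb[i] is None or bb[j] is None or bb[j - 1] is None:
                continue
            if not _contiguous(residues[i:j + 1], bb[i:j + 1]):
                continue
            if _hbond_energy(bb[i], bb[j], bb[j - 1]) < _KS_CUTOFF:
                turn4[i] = True
        helical = [False] * n
        for i in range(1, n):
            if turn4[i - 1] and turn4[i]:
                for j in range(i, min(i + 4, n)):
                    helical[j] = True
        for r, b, h in zip(residues, bb, helical):
            codes[r.key] = "H" if (h and b is not None) else "other"
    return SecondaryStructureMap(codes=codes, source="internal")


def _contiguous(residues: list[Residue], bb: list[Optional[dict]]) -> bool:
    for a, b in zip(residues, residues[1:]):
        if b.seq_id - a.seq_id not in (0, 1):
            return False
    for a, b in zip(bb, bb[1:]):
        if a is not None and b is not None:
            if np.linalg.norm(b["N"] - a["C"]) > 2.5:  # broken peptide bond
                return False
    return True


def build_helices(ssmap: SecondaryStructureMap, s: Structure,
                  min_len: int = MIN_HELIX_LENGTH,
                  include_310: bool = False,
                  include_pi: bool = False) -> list[HelixSegment]:
    """Collect maximal runs of helical residues into :class:`HelixSegment`.

    Only code 'H' seeds segments by default; ``include_310``/``include_pi``
    admit G and I codes.  Runs shorter than ``min_len`` are dropped.
    Segments never span chain breaks (recorded markers, gaps in author
    numbering, or broken peptide bonds).
    """
    wanted = {"H"} | ({"G"} if include_310 else set()) | ({"I"} if include_pi else set())
    helices: list[HelixSegment] = []
    next_id = 1
    for chain_id in sorted(s.chains):
        residues = s.chains[chain_id]
        run: list[Residue] = []

        def flush() -> None:
            nonlocal next_id
            if len(run) >= min_len:
                helices.append(HelixSegment(next_id, chain_id, list(run)))
                next_id += 1
            run.clear()

        for r in residues:
            code = ssmap.code(chain_id, r.label)
            if code not in wanted:
                flush()
                continue
            if run and not _adjacent(run[-1], r, ssmap):
                flush()
            run.append(r)
        flush()
    return helices


def _adjacent(a: Residue, b: Residue, ssmap: SecondaryStructureMap) -> bool:
    if (a.key, b.key) in ssmap.breaks:
        return False
    if b.seq_id - a.seq_id != 1 or a.icode or b.icode:
        return b.seq_id == a.seq_id and bool(b.icode)  # insertion-code runs
    ca, nb = a.atom("C"), b.atom("N")
    if ca is not None and nb is not None:
        if np.linalg.norm(nb.position - ca.position) > 2.5:
            return False
    return True


def extend_helices(helices: list[HelixSegment], s: Structure,
                   ext: int) -> list[HelixSegment]:
    """Grow each segment by up to ``ext`` residues at each end.

    Extension only walks over residues that exist, are contiguous on the
    same chain, and belong to no other segment; touching segments are
    never merged.  ``ext=0`` returns the input segments unchanged.
    """
    if ext < 0:
        raise ValueError("helix extension must be >= 0")
    if ext == 0:
        return helices
    claimed: set[int] = set()
    for h in helices:
        claimed.update(id(r) for r in h.residues)
    empty = SecondaryStructureMap(codes={}, source="internal")
    out: list[HelixSegment] = []
    for h in helices:
        chain = s.chains[h.chain_id]
        idx_first = next(i for i, r in enumerate(chain) if r is h.residues[0])
        idx_last = next(i for i, r in enumerate(chain) if r is h.residues[-1])
        n_added = []
        i = idx_first
        while len(n_added) < ext and i > 0:
            cand = chain[i - 1]
            if id(cand) in claimed or not _adjacent(cand, chain[i], empty):
                break
            n_added.append(cand)
            i -= 1
        c_added = []
        i = idx_last
        while len(c_added) < ext and i + 1 < len(chain):
            cand = chain[i + 1]
            if id(cand) in claimed or not _adjacent(chain[i], cand, empty):
                break
            c_added.append(cand)
            i += 1
        for r in n_added + c_added:
            claimed.add(id(r))
        out.append(HelixSegment(
            h.helix_id, h.chain_id,
            list(reversed(n_added)) + list(h.residues) + c_added,
            extended_n=len(n_added), extended_c=len(c_added)))
    return out
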