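"""Read PDB/mmCIF coordinate files into a uniform structure model.

Parsing is delegated to :mod:`gemmi`; this module reduces whatever gemmi
returns to a small, format-agnostic hierarchy (:class:`Structure` ->
:class:`Residue` -> :class:`Atom`) holding only what knobs-into-holes
analysis needs: heavy-atom coordinates of polymer residues, one model,
one conformer per atom, and modified-residue annotations so that
downstream stages are residue-identity agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "StructureError",
    "FormatError",
    "EmptyStructureError",
    "read_structure",
    "read_structure_string",
    "apply_modres",
    "write_pdb",
    "write_mmcif",
    "STANDARD_AMINO_ACIDS",
    "COMMON_MODIFICATIONS",
]


class StructureError(Exception):
    """Base class for structure ingestion problems."""


class FormatError(StructureError):
    """The file could not be parsed as PDB or mmCIF."""


class EmptyStructureError(StructureError):
    """No protein residues survived ingestion."""


#: The 20 proteinogenic residues (3-letter codes).
STANDARD_AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: Built-in parent table for modifications common enough that files often
#: omit the MODRES record.  Used only for reporting; geometry always works
#: from the atoms actually present.
COMMON_MODIFICATIONS = {
    "MSE": "MET",
    "SEP": "SER",
    "TPO": "THR",
    "PTR": "TYR",
    "CSO": "CYS",
    "CME": "CYS",
    "OCS": "CYS",
    "MLY": "LYS",
    "KCX": "LYS",
    "HYP": "PRO",
    "PCA": "GLU",
    "CGU": "GLU",
    "FME": "MET",
    "MLE": "LEU",
    "AIB": "ALA",
    "DAL": "ALA",
    "NLE": "LEU",
}

_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}
_WATER_NAMES = {"HOH", "DOD", "WAT", "H2O"}


@dataclass(frozen=True)
class Atom:
    """A heavy atom: label, element symbol and Cartesian position (A)."""

    name: str
    element: str
    position: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite coordinates for atom {self.name!r}")


@dataclass
class Residue:
    """One polymer residue with its heavy atoms.

    ``seq_id`` is the author residue number; ``icode`` the insertion code
    (empty when absent).  ``parent_name`` equals ``name`` for standard
    residues and the standard parent for modified ones (``UNK`` when no
    mapping is known); it is set by :func:`apply_modres` and used only for
    reporting, never for geometry.
    """

    chain_id: str
    seq_id: int
    icode: str
    name: str
    atoms: list[Atom]
    het: bool = False
    parent_name: str = ""
    is_modified: bool = False

    @property
    def key(self) -> tuple[str, str]:
        return (self.chain_id, self.label)

    @property
    def label(self) -> str:
        """Author number + insertion code, e.g. ``'52'`` or ``'52A'``."""
        return f"{self.seq_id}{self.icode}".strip()

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def side_chain_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.name not in _BACKBONE_NAMES]

    def one_letter(self) -> str:
        code = self.parent_name or self.name
        info = gemmi.find_tabulated_residue(code)
        if info is not None and info.is_amino_acid():
            letter = info.one_letter_code.upper()
            if letter.isalpha():
                return letter
        return "X"


@dataclass
class Structure:
    """Chains of residues from a single model of a coordinate file."""

    chains: dict[str, list[Residue]] = field(default_factory=dict)
    model_id: int = 1
    source_format: str = "pdb"
    modres_records: list[tuple[str, str, str, str]] = field(default_factory=list)
    name: str = ""

    def residues(self) -> Iterator[Residue]:
        for chain in self.chains.values():
            yield from chain

    def residue(self, chain_id: str, label: str) -> Optional[Residue]:
        for r in self.chains.get(chain_id, ()):
            if r.label == str(label):
                return r
        return None

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains.values())

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())


def _pick_conformer(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # Highest occupancy wins; ties broken by altloc label so 'A' beats 'B'.
    return min(atoms, key=lambda a: (-a.occ, a.altloc or "~"))


def _convert(st: gemmi.Structure, source_format: str) -> Structure:
    if len(st) == 0:
        raise EmptyStructureError("file contains no coordinate models")
    model = st[0]
    out = Structure(model_id=model.num if model.num else 1,
                    source_format=source_format, name=st.name.lower())
    for mr in st.mod_residues:
        out.modres_records.append(
            (mr.res_id.name, mr.chain_name,
             f"{mr.res_id.seqid.num}{mr.res_id.seqid.icode}".strip(),
             mr.parent_comp_id))
    for chain in model:
        residues: list[Residue] = []
        seen: set[str] = set()
        for res in chain:
            if res.name in _WATER_NAMES:
                continue
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in res:
                if atom.element.is_hydrogen:
                    continue
                by_name.setdefault(atom.name, []).append(atom)
            atoms = []
            for atom_name in by_name:
                g = _pick_conformer(by_name[atom_name])
                atoms.append(Atom(atom_name, g.element.name,
                                  np.array([g.pos.x, g.pos.y, g.pos.z])))
            if not any(a.name == "CA" for a in atoms):
                continue  # ligands/ions: cannot take part in KIH packing
            label = f"{res.seqid.num}{res.seqid.icode}".strip()
            if label in seen:
                continue  # microheterogeneity: keep the first residue version
            seen.add(label)
            residues.append(Residue(
                chain_id=chain.name, seq_id=res.seqid.num,
                icode=res.seqid.icode.strip(), name=res.name, atoms=atoms,
                het=(res.het_flag == "H"),
            ))
        if residues:
            residues.sort(key=lambda r: (r.seq_id, r.icode))
            out.chains[chain.name] = residues
    if out.n_residues == 0:
        raise EmptyStructureError("no protein residues found in structure")
    return out


def _detect_format(path: Path, format_hint: Optional[str]) -> str:
    if format_hint in ("pdb", "mmcif"):
        return format_hint
    suffix = path.suffix.lower()
    if suffix in (".cif", ".mmcif"):
        return "mmcif"
    if suffix in (".pdb", ".ent"):
        return "pdb"
    head = path.read_text(errors="replace")[:4096]
    return "mmcif" if ("_atom_site." in head or head.startswith("data_")) else "pdb"


def read_structure(path: str | Path, format_hint: Optional[str] = None) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    The first model is used, hydrogens are stripped, the highest-occupancy
    conformer is kept per atom, and waters and non-polymer heteroatoms
    (anything without a CA) are dropped.  ``format_hint`` forces the
    format; otherwise it is inferred from the extension and content.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    return read_structure_string(path.read_text(errors="replace"),
                                 _detect_format(path, format_hint))


def read_structure_string(text: str, fmt: str) -> Structure:
    """Parse PDB or mmCIF content supplied as a string (``fmt``: pdb|mmcif)."""
    try:
        if fmt == "mmcif":
            block = gemmi.cif.read_string(text).sole_block()
            st = gemmi.make_structure_from_block(block)
        elif fmt == "pdb":
            st = gemmi.read_pdb_string(text)
        else:
            raise FormatError(f"unknown format {fmt!r} (expected pdb or mmcif)")
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"could not parse {fmt} input: {exc}") from exc
    return apply_modres(_convert(st, fmt))


def apply_modres(s: Structure) -> Structure:
    """Annotate each residue with its standard parent identity.

    MODRES records (or the built-in table of common modifications) set
    ``parent_name`` for modified residues; unmatched non-standard residues
    get ``UNK`` and stay fully eligible as knobs and holes.  Annotation
    only -- no atoms are touched.
    """
    modres = {(chain, label): parent
              for (_het, chain, label, parent) in s.modres_records}
    for r in s.residues():
        if r.name in STANDARD_AMINO_ACIDS:
            r.parent_name = r.name
            r.is_modified = False
            continue
        parent = modres.get((r.chain_id, r.label)) or COMMON_MODIFICATIONS.get(r.name)
        r.parent_name = parent if parent else "UNK"
        r.is_modified = True
    return s


# ---------------------------------------------------------------------------
# Writers (fixture output and round-trip tests; ingestion always uses gemmi)

def _pdb_atom_name(a: Atom) -> str:
    # Element right-justified in columns 13-14 per PDB convention.
    if len(a.name) >= 4:
        return a.name[:4]
    if len(a.element) == 2 or (len(a.name) == 3 and not a.name.startswith(a.element)):
        return f"{a.name:<4}"[:4]
    return f" {a.name:<3}"


def write_pdb(s: Structure) -> str:
    """Render a Structure as PDB text (ATOM/HETATM/MODRES/TER/END)."""
    lines = []
    for (het, chain, label, parent) in s.modres_records:
        num, icode = _split_label(label)
        # columns: idCode 8-11, resName 13-15, chain 17, seqNum 19-22,
        # iCode 23, stdRes 25-27
        lines.append(f"MODRES XXXX {het:>3} {chain:1} {num:>4}{icode or ' '} "
                     f"{parent:>3}  MODIFIED RESIDUE")
    serial = 1
    for chain_id, residues in s.chains.items():
        for r in residues:
            record = "HETATM" if r.het else "ATOM  "
            for a in r.atoms:
                x, y, z = a.position
                lines.append(
                    f"{record}{serial:>5} {_pdb_atom_name(a)} {r.name:>3} "
                    f"{chain_id:1}{r.seq_id:>4}{r.icode or ' '}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {a.element:>2}")
                serial += 1
        lines.append(f"TER   {serial:>5}      {residues[-1].name:>3} "
                     f"{chain_id:1}{residues[-1].seq_id:>4}")
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_mmcif(s: Structure) -> str:
    """Render a Structure as a minimal mmCIF atom_site loop."""
    lines = [
        f"data_{s.name or 'kihscan'}",
        "#",
        "loop_",
        "_atom_site.group_PDB",
        "_atom_site.id",
        "_atom_site.type_symbol",
        "_atom_site.label_atom_id",
        "_atom_site.label_alt_id",
        "_atom_site.label_comp_id",
        "_atom_site.label_asym_id",
        "_atom_site.label_entity_id",
        "_atom_site.label_seq_id",
        "_atom_site.pdbx_PDB_ins_code",
        "_atom_site.Cartn_x",
        "_atom_site.Cartn_y",
        "_atom_site.Cartn_z",
        "_atom_site.occupancy",
        "_atom_site.B_iso_or_equiv",
        "_atom_site.auth_seq_id",
        "_atom_site.auth_asym_id",
        "_atom_site.pdbx_PDB_model_num",
    ]
    serial = 1
    for entity, (chain_id, residues) in enumerate(s.chains.items(), start=1):
        for i, r in enumerate(residues, start=1):
            group = "HETATM" if r.het else "ATOM"
            for a in r.atoms:
                x, y, z = a.position
                lines.append(
                    f"{group} {serial} {a.element} {a.name} . {r.name} "
                    f"{chain_id} {entity} {i} {r.icode or '?'} "
                    f"{x:.3f} {y:.3f} {z:.3f} 1.00 0.00 "
                    f"{r.seq_id} {chain_id} 1")
                serial += 1
    if s.modres_records:
        lines += [
            "#",
            "loop_",
            "_pdbx_struct_mod_residue.id",
            "_pdbx_struct_mod_residue.label_comp_id",
            "_pdbx_struct_mod_residue.auth_asym_id",
            "_pdbx_struct_mod_residue.auth_seq_id",
            "_pdbx_struct_mod_residue.PDB_ins_code",
            "_pdbx_struct_mod_residue.parent_comp_id",
            "_pdbx_struct_mod_residue.details",
        ]
        for i, (het, chain, label, parent) in enumerate(s.modres_records, start=1):
            num, icode = _split_label(label)
            lines.append(f"{i} {het} {chain} {num} {icode or '?'} {parent} ?")
    lines.append("#")
    return "\n".join(lines) + "\n"


def _split_label(label: str) -> tuple[int, str]:
    digits = "".join(ch for ch in label if ch.isdigit() or ch == "-")
    icode = label[len(digits):].strip()
    return int(digits), icode
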