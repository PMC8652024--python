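"""Helix assignment: DSSP parsing, the internal assigner, segments,
extension."""

from pathlib import Path

import numpy as np
import pytest

from kihscan import fixtures
from kihscan.fixtures import CrickParams, _ideal_helix_backbone, crick_backbone
from kihscan.helix_model import (DsspMismatchError, SecondaryStructureMap,
                                 assign_helices_internal, build_helices,
                                 extend_helices, parse_dssp)
from kihscan.structure_io import Atom, Residue, Structure

from conftest import DATA, make_chain_structure, make_residue

DSSP_HEADER = (
    "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N    "
    "N-H-->O    O-->H-N    TCO  KAPPA ALPHA  PHI   PSI    X-CA   Y-CA   Z-CA\n")


def _dssp_text(entries):
    """entries: list of (num, chain, ss) or '!' break markers."""
    lines = ["mock dssp output\n", DSSP_HEADER]
    serial = 1
    for e in entries:
        if e == "!":
            lines.append(f"{serial:5d}        !*\n")
        else:
            num, chain, ss = e
            lines.append(f"{serial:5d}{num:5d} {chain} A  {ss} \n")
        serial += 1
    return "".join(lines)


def _structure_from_backbone(bb, chain_id="A", start=1):
    residues = []
    for i, r in enumerate(bb):
        atoms = [Atom(n, "C" if n in ("CA", "C") else n[0], r[n])
                 for n in ("N", "CA", "C", "O")]
        residues.append(Residue(chain_id=chain_id, seq_id=start + i, icode="",
                                name="ALA", atoms=atoms, parent_name="ALA"))
    s = Structure()
    s.chains[chain_id] = residues
    return s


def test_parse_dssp_transcribes_codes(tmp_path, dimer):
    entries = [(i, "A", "H" if 5 <= i <= 18 else " ") for i in range(1, 29)]
    entries += [(i, "B", " ") for i in range(1, 29)]
    p = tmp_path / "x.dssp"
    p.write_text(_dssp_text(entries))
    m = parse_dssp(p, dimer)
    assert m.source == "dssp_file"
    assert all(m.code("A", str(i)) == "H" for i in range(5, 19))
    assert m.code("A", "4") == "other" and m.code("A", "19") == "other"


def test_parse_dssp_break_splits_segments(tmp_path, dimer):
    entries = [(i, "A", "H") for i in range(2, 12)] + ["!"] + \
              [(i, "A", "H") for i in range(12, 26)]
    p = tmp_path / "x.dssp"
    p.write_text(_dssp_text(entries))
    m = parse_dssp(p, dimer)
    helices = build_helices(m, dimer)
    spans = [(h.first.seq_id, h.last.seq_id) for h in helices]
    assert (2, 11) in spans and (12, 25) in spans
    assert not any(a <= 11 < b for a, b in spans)


def test_parse_dssp_g_code_excluded_by_default(tmp_path, dimer):
    entries = [(i, "A", "G") for i in range(2, 16)]
    p = tmp_path / "x.dssp"
    p.write_text(_dssp_text(entries))
    m = parse_dssp(p, dimer)
    assert m.code("A", "5") == "G"
    assert build_helices(m, dimer) == []
    assert len(build_helices(m, dimer, include_310=True)) == 1


def test_parse_dssp_mismatch_error(tmp_path, dimer):
    p = tmp_path / "x.dssp"
    p.write_text(_dssp_text([(999, "Z", "H")] * 1))
    with pytest.raises(DsspMismatchError, match="Z/999"):
        parse_dssp(p, dimer)


def test_internal_assigner_ideal_straight_helix():
    s = crick_backbone(CrickParams(n_helices=1, superhelical_radius=0.0,
                                   n_residues=21))
    m = assign_helices_internal(s)
    interior = [m.code("A", str(i)) for i in range(3, 20)]
    assert all(c == "H" for c in interior)


def test_internal_assigner_extended_chain_has_no_helix():
    s = _structure_from_backbone(_ideal_helix_backbone(12, phi=180.0, psi=180.0))
    m = assign_helices_internal(s)
    assert all(c == "other" for c in m.codes.values())


def test_internal_assigner_short_peptide():
    s = _structure_from_backbone(_ideal_helix_backbone(4))
    m = assign_helices_internal(s)
    assert all(c == "other" for c in m.codes.values())


def test_internal_assigner_matches_reference_dssp(dimer):
    """The internal assigner reproduces the frozen DSSP labels of the
    ideal dimer fixture (>= 90% residue agreement; identical segments
    on interior residues)."""
    ref = parse_dssp(DATA / "dimer_parallel.dssp", dimer)
    internal = assign_helices_internal(dimer)
    keys = list(ref.codes)
    agree = sum(ref.codes[k] == internal.codes.get(k, "other") for k in keys)
    assert agree / len(keys) >= 0.90
    h_ref = build_helices(ref, dimer)
    h_int = build_helices(internal, dimer)
    assert len(h_ref) == len(h_int) == 2
    for a, b in zip(h_ref, h_int):
        assert {r.seq_id for r in a.residues[1:-1]} <= {r.seq_id for r in b.residues}
        assert {r.seq_id for r in b.residues[1:-1]} <= {r.seq_id for r in a.residues}


def _ssmap(chain_runs):
    codes = {}
    for chain, runs in chain_runs.items():
        for start, stop, code in runs:
            for i in range(start, stop + 1):
                codes[(chain, str(i))] = code
    return SecondaryStructureMap(codes=codes, source="internal")


def _poly_ala(chain, start, stop, spacing=3.8):
    return [make_residue(chain, i, ca=(spacing * i, 0, 0),
                         cb=(spacing * i, 1.5, 0))
            for i in range(start, stop + 1)]


def test_build_helices_runs_and_threshold():
    s = make_chain_structure(("A", _poly_ala("A", 1, 40)))
    m = _ssmap({"A": [(3, 16, "H"), (20, 24, "H")]})
    helices = build_helices(m, s, min_len=7)
    assert len(helices) == 1  # 5-residue run dropped
    assert (helices[0].first.seq_id, helices[0].last.seq_id) == (3, 16)


def test_build_helices_two_chains_distinct_ids():
    s = make_chain_structure(("A", _poly_ala("A", 1, 20)),
                             ("B", _poly_ala("B", 1, 20)))
    m = _ssmap({"A": [(2, 15, "H")], "B": [(4, 17, "H")]})
    helices = build_helices(m, s)
    assert [h.chain_id for h in helices] == ["A", "B"]
    assert helices[0].helix_id != helices[1].helix_id


def test_extension_zero_is_identity(dimer_result):
    helices = dimer_result.helices
    assert extend_helices(helices, dimer_result.structure, 0) is helices


def test_extension_arithmetic():
    s = make_chain_structure(("A", _poly_ala("A", 8, 25)))
    m = _ssmap({"A": [(10, 20, "H")]})
    helices = build_helices(m, s)
    ext = extend_helices(helices, s, 2)
    assert (ext[0].first.seq_id, ext[0].last.seq_id) == (8, 22)
    assert (ext[0].extended_n, ext[0].extended_c) == (2, 2)


def test_extension_stops_at_numbering_gap():
    residues = _poly_ala("A", 8, 20) + _poly_ala("A", 22, 25)  # 21 missing
    s = make_chain_structure(("A", residues))
    m = _ssmap({"A": [(10, 18, "H")]})
    ext = extend_helices(build_helices(m, s), s, 2)
    assert ext[0].last.seq_id == 20


def test_extension_never_merges_segments():
    s = make_chain_structure(("A", _poly_ala("A", 1, 30)))
    m = _ssmap({"A": [(2, 12, "H"), (15, 25, "H")]})
    helices = build_helices(m, s)
    ext = extend_helices(helices, s, 3)
    assert len(ext) == 2
    claimed = [r.seq_id for h in ext for r in h.residues]
    assert len(claimed) == len(set(claimed))  # no residue in two segments


def test_extension_monotone():
    s = make_chain_structure(("A", _poly_ala("A", 1, 30)))
    m = _ssmap({"A": [(8, 20, "H")]})
    base = build_helices(m, s)
    prev = set()
    for ext in range(4):
        cur = {r.seq_id for h in extend_helices(base, s, ext) for r in h.residues}
        assert prev <= cur
        prev = cur
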