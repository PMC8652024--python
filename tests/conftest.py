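"""Shared fixtures: generated coiled-coil structures and pipeline helpers."""

from pathlib import Path

import numpy as np
import pytest

from kihscan import fixtures
from kihscan.report import RunConfig, run_pipeline
from kihscan.structure_io import Atom, Residue, Structure

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def dimer():
    """Default ideal parallel dimer (R0=4.9 A, P=148 A, 28 residues)."""
    return fixtures.parallel_dimer()


@pytest.fixture(scope="session")
def ap_dimer():
    return fixtures.antiparallel_dimer()


@pytest.fixture(scope="session")
def dimer_result(dimer):
    return analyze(dimer)


def analyze(structure, cutoff=7.0, extension=0):
    """Run the full pipeline on an in-memory structure (internal helix
    assignment)."""
    cfg = RunConfig(input_path="fixture.pdb", internal_ss=True,
                    cutoff=cutoff, extension=extension)
    return run_pipeline(cfg, structure=structure)


def make_residue(chain_id, seq_id, name="ALA", ca=(0.0, 0.0, 0.0), cb=None,
                 extra=()):
    """Minimal residue for unit tests: CA, optional CB, extra side atoms."""
    atoms = [Atom("CA", "C", np.asarray(ca, dtype=float))]
    if cb is not None:
        atoms.append(Atom("CB", "C", np.asarray(cb, dtype=float)))
    for i, pos in enumerate(extra):
        atoms.append(Atom(f"CG{i or ''}", "C", np.asarray(pos, dtype=float)))
    return Residue(chain_id=chain_id, seq_id=seq_id, icode="", name=name,
                   atoms=atoms, parent_name=name)


def make_chain_structure(*chains):
    """Structure from {chain_id: [residues]} pairs given as (cid, residues)."""
    s = Structure()
    for cid, residues in chains:
        s.chains[cid] = list(residues)
    return s
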