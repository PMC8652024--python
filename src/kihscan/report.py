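"""Pipeline driver and output rendering.

``run_pipeline`` wires the stages together -- structure ingestion, helix
assignment, knobs-into-holes detection, coiled-coil assembly, geometry --
and the renderers serialize the result as a human-readable text report, a
PyMOL script, JSON/CSV tables and optional angle-distribution plots.
Identical input and configuration always produce byte-identical text
outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .cc_assembly import CoiledCoilAssembly, annotate_assembly, assemble
from .geometry import HelixAxis, fit_helix_axis, knob_packing_angles
from .helix_model import (HelixSegment, assign_helices_internal, build_helices,
                          extend_helices, parse_dssp)
from .kih_core import (DEFAULT_CUTOFF, classify_knob, compute_centers,
                       contact_map, find_knobs, pair_interfaces)
from .structure_io import Structure, read_structure

__all__ = ["RunConfig", "RunResult", "run_pipeline", "render_text_report",
           "render_pymol_script", "render_tables", "render_plots", "write_outputs"]

log = logging.getLogger(__name__)

CUTOFF_MIN, CUTOFF_MAX = 6.0, 8.0


@dataclass
class RunConfig:
    """Configuration of one analysis run."""

    input_path: str
    dssp_path: Optional[str] = None
    cutoff: float = DEFAULT_CUTOFF
    extension: int = 0
    internal_ss: bool = False
    output_dir: str = "."
    emit_text: bool = True
    emit_json: bool = False
    emit_csv: bool = False
    emit_pymol: bool = False
    emit_plots: bool = False
    force: bool = False
    min_helix_length: int = 7
    seed: int = 0  # reserved for randomized utilities; the pipeline is deterministic

    def validate(self) -> None:
        if not (CUTOFF_MIN <= self.cutoff <= CUTOFF_MAX) and not self.force:
            raise ValueError(
                f"packing cutoff {self.cutoff} outside [{CUTOFF_MIN}, "
                f"{CUTOFF_MAX}] A; pass force=True/--force to override")
        if self.extension < 0:
            raise ValueError("helix extension must be >= 0")


@dataclass
class RunResult:
    structure: Structure
    helices: list[HelixSegment]
    assemblies: list[CoiledCoilAssembly]
    axes: dict[int, Optional[HelixAxis]]
    config: RunConfig
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    manifest: list[str] = field(default_factory=list)

    @property
    def n_knobs(self) -> int:
        return sum(len(a.knobs()) for a in self.assemblies)


def run_pipeline(cfg: RunConfig, structure: Optional[Structure] = None) -> RunResult:
    """Execute the full analysis for one structure.

    ``structure`` may be supplied directly (e.g. a generated fixture);
    otherwise ``cfg.input_path`` is read.  Returns a :class:`RunResult`
    carrying the assemblies and the residue/pair/assembly tables; no
    files are written (see :func:`write_outputs`).
    """
    cfg.validate()
    s = structure if structure is not None else read_structure(cfg.input_path)
    if cfg.dssp_path and not cfg.internal_ss:
        ssmap = parse_dssp(cfg.dssp_path, s)
    else:
        ssmap = assign_helices_internal(s)
    helices = build_helices(ssmap, s, min_len=cfg.min_helix_length)
    helices = extend_helices(helices, s, cfg.extension)
    centers = compute_centers(helices)
    contacts = contact_map(helices, centers, cfg.cutoff)
    knobs = find_knobs(contacts, centers, cfg.cutoff)
    for k in knobs:
        classify_knob(k, centers, cfg.cutoff)
    interfaces = pair_interfaces(knobs)
    assemblies = assemble(interfaces, helices)
    axes = {h.helix_id: fit_helix_axis(h) for h in helices}
    for a in assemblies:
        annotate_assembly(a, axes)
    result = RunResult(structure=s, helices=helices, assemblies=assemblies,
                       axes=axes, config=cfg)
    result.tables = _build_tables(result)
    return result


def _build_tables(result: RunResult) -> dict[str, pd.DataFrame]:
    helix_by_id = {h.helix_id: h for h in result.helices}
    knob_keys = {}
    for a in result.assemblies:
        for k in a.knobs():
            knob_keys.setdefault(k.knob_residue.key, k)
    residue_rows = []
    for a in result.assemblies:
        for h in a.helices:
            for r in h.residues:
                k = knob_keys.get(r.key)
                residue_rows.append({
                    "cc_id": a.cc_id, "helix_id": h.helix_id,
                    "chain": r.chain_id, "residue": r.label, "name": r.name,
                    "parent_name": r.parent_name,
                    "register": a.register_of(r.key),
                    "is_knob": k is not None,
                    "knob_type": k.knob_type if k else 0,
                })
    pair_rows = []
    for a in result.assemblies:
        for iface in a.interfaces:
            key = (iface.helix_a, iface.helix_b)
            ha, hb = helix_by_id[iface.helix_a], helix_by_id[iface.helix_b]
            pair_rows.append({
                "cc_id": a.cc_id, "helix_a": iface.helix_a,
                "helix_b": iface.helix_b,
                "chain_a": ha.chain_id, "chain_b": hb.chain_id,
                "orientation": a.orientations.get(key, "unassigned"),
                "interhelix_angle": a.pair_angles.get(key),
                "n_knobs": iface.n_knobs,
                "n_complementary": len(iface.complementary_pairs),
            })
    assembly_rows = [{
        "cc_id": a.cc_id, "order": a.order, "topology": a.topology,
        "n_knobs": len(a.knobs()),
        "helices": ";".join(f"{h.chain_id}:{h.first.label}-{h.last.label}"
                            for h in a.helices),
    } for a in result.assemblies]
    knob_tables = [knob_packing_angles(a) for a in result.assemblies]
    knob_df = (pd.concat(knob_tables, ignore_index=True) if knob_tables
               else pd.DataFrame(columns=[
                   "cc_id", "chain", "residue", "name", "knob_helix",
                   "hole_helix", "packing_angle", "knob_type"]))
    return {
        "residues": pd.DataFrame(residue_rows, columns=[
            "cc_id", "helix_id", "chain", "residue", "name", "parent_name",
            "register", "is_knob", "knob_type"]),
        "pairs": pd.DataFrame(pair_rows, columns=[
            "cc_id", "helix_a", "helix_b", "chain_a", "chain_b", "orientation",
            "interhelix_angle", "n_knobs", "n_complementary"]),
        "assemblies": pd.DataFrame(assembly_rows, columns=[
            "cc_id", "order", "topology", "n_knobs", "helices"]),
        "knobs": knob_df,
    }


def render_text_report(result: RunResult) -> str:
    """Human-readable report: one block per assembly."""
    cfg = result.config
    lines = [
        f"kihscan {__version__} -- knobs-into-holes coiled-coil report",
        f"input: {Path(cfg.input_path).name}",
        f"packing cutoff: {cfg.cutoff:.1f} A | helix extension: {cfg.extension} | "
        f"ss source: {'internal' if (cfg.internal_ss or not cfg.dssp_path) else 'dssp'}",
        f"helices found: {len(result.helices)} | "
        f"coiled coils found: {len(result.assemblies)}",
        "",
    ]
    if not result.helices:
        lines.append("no α-helices found; nothing to analyze.")
        return "\n".join(lines) + "\n"
    if not result.assemblies:
        lines.append("zero coiled-coil assemblies detected.")
        return "\n".join(lines) + "\n"
    helix_by_id = {h.helix_id: h for h in result.helices}
    for a in result.assemblies:
        topo = "cyclic (α-helical barrel)" if a.topology == "cyclic" else "open"
        lines.append(f"== coiled coil {a.cc_id}: order {a.order}, topology {topo} ==")
        for h in a.helices:
            lines.append(f"  helix {h.helix_id}: chain {h.chain_id} "
                         f"residues {h.first.label}-{h.last.label} ({len(h)} res)")
        for iface in a.interfaces:
            key = (iface.helix_a, iface.helix_b)
            angle = a.pair_angles.get(key)
            lines.append(
                f"  pair {iface.helix_a}-{iface.helix_b}: "
                f"{a.orientations.get(key, 'unassigned')}"
                + (f", crossing angle {angle:.1f} deg" if angle is not None else "")
                + f", {iface.n_knobs} knobs, "
                  f"{len(iface.complementary_pairs)} complementary")
        for h in a.helices:
            seq = "".join(r.one_letter() for r in h.residues)
            reg = "".join(a.register_of(r.key) or "-" for r in h.residues)
            lines.append(f"  helix {h.helix_id} sequence  {seq}")
            lines.append(f"  helix {h.helix_id} register  {reg}")
        for k in a.knobs():
            r = k.knob_residue
            hole = ",".join(f"{hr.chain_id}{hr.label}" for hr in k.hole_residues)
            angle = (f"{k.packing_angle:.1f}" if k.packing_angle is not None
                     else "n/a")
            lines.append(
                f"  knob {r.chain_id}{r.label} {r.name} "
                f"(helix {k.knob_helix} -> {k.hole_helix}) type {k.knob_type} "
                f"angle {angle} hole [{hole}] "
                f"dmax {max(k.hole_distances):.2f} A")
        lines.append("")
    return "\n".join(lines) + "\n"


def render_pymol_script(result: RunResult) -> str:
    """PyMOL selections and styling for the detected coiled coils."""
    lines = [f"# kihscan {__version__} PyMOL script",
             f"# input: {Path(result.config.input_path).name}",
             f"# coiled coils: {len(result.assemblies)}"]
    if not result.assemblies:
        return "\n".join(lines) + "\n"
    palette = ["red", "orange", "yellow", "green", "cyan", "blue", "purple",
               "magenta", "salmon", "teal", "olive", "slate"]
    register_colors = {"a": "red", "b": "orange", "c": "yellow", "d": "green",
                       "e": "cyan", "f": "blue", "g": "purple"}
    lines.append("hide everything")
    lines.append("show cartoon")
    lines.append("color grey80")
    for a in result.assemblies:
        for i, h in enumerate(a.helices):
            sel = f"cc{a.cc_id}_helix{h.helix_id}"
            lines.append(f"select {sel}, chain {h.chain_id} and "
                         f"resi {h.first.label}-{h.last.label}")
            lines.append(f"color {palette[i % len(palette)]}, {sel}")
        knob_resis: dict[str, list[str]] = {}
        for k in a.knobs():
            knob_resis.setdefault(k.knob_residue.chain_id, []).append(
                k.knob_residue.label)
        parts = [f"(chain {c} and resi {'+'.join(dict.fromkeys(r))})"
                 for c, r in sorted(knob_resis.items())]
        if parts:
            lines.append(f"select cc{a.cc_id}_knobs, " + " or ".join(parts))
            lines.append(f"show sticks, cc{a.cc_id}_knobs")
        present: dict[str, dict[str, list[str]]] = {}
        for h in a.helices:
            for r in h.residues:
                letter = a.register_of(r.key)
                if letter:
                    present.setdefault(letter, {}).setdefault(
                        r.chain_id, []).append(r.label)
        for letter in sorted(present):
            parts = [f"(chain {c} and resi {'+'.join(rs)})"
                     for c, rs in sorted(present[letter].items())]
            sel = f"cc{a.cc_id}_reg_{letter}"
            lines.append(f"select {sel}, " + " or ".join(parts))
            lines.append(f"color {register_colors[letter]}, {sel}")
    lines.append("deselect")
    return "\n".join(lines) + "\n"


def _json_safe(value):
    if pd.isna(value):
        return None
    if hasattr(value, "item"):
        return value.item()
    return value


def render_tables(result: RunResult) -> tuple[str, dict[str, str]]:
    """JSON document and per-table CSV texts with identical content."""
    doc = {
        "kihscan_version": __version__,
        "input": Path(result.config.input_path).name,
        "cutoff": result.config.cutoff,
        "extension": result.config.extension,
        "n_helices": len(result.helices),
        "n_coiled_coils": len(result.assemblies),
    }
    csvs = {}
    for name, df in result.tables.items():
        doc[name] = [{k: _json_safe(v) for k, v in row.items()}
                     for row in df.to_dict(orient="records")]
        csvs[name] = df.to_csv(index=False, float_format="%.1f",
                               lineterminator="\n")
    return json.dumps(doc, indent=2) + "\n", csvs


def render_plots(result: RunResult, outdir: Path) -> list[Path]:
    """Histograms of pair crossing angles and knob packing angles (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    pairs = result.tables["pairs"]["interhelix_angle"].dropna()
    knobs = result.tables["knobs"]["packing_angle"].dropna()
    for series, fname, xlabel in (
            (pairs, "interhelix_angles.png", "interhelix angle (deg)"),
            (knobs, "packing_angles.png", "knob packing angle (deg)")):
        if series.empty:
            continue
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.hist(series, bins=18, range=(0, 180), color="#4878a8",
                edgecolor="black")
        ax.set_xlabel(xlabel)
        ax.set_ylabel("count")
        fig.tight_layout()
        path = outdir / fname
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written


def write_outputs(result: RunResult) -> list[Path]:
    """Write the enabled artifacts into the configured output directory."""
    cfg = result.config
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = Path(cfg.input_path).stem or "kihscan"
    written: list[Path] = []

    def emit(name: str, text: str) -> None:
        path = outdir / name
        path.write_text(text)
        written.append(path)

    if cfg.emit_text:
        emit(f"{stem}.kih.txt", render_text_report(result))
    if cfg.emit_json or cfg.emit_csv:
        json_text, csvs = render_tables(result)
        if cfg.emit_json:
            emit(f"{stem}.kih.json", json_text)
        if cfg.emit_csv:
            for table, text in csvs.items():
                emit(f"{stem}.{table}.csv", text)
    if cfg.emit_pymol:
        emit(f"{stem}.kih.pml", render_pymol_script(result))
    if cfg.emit_plots:
        written.extend(render_plots(result, outdir))
    result.manifest = [str(p) for p in written]
    return written
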