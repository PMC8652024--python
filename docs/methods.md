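# Methods

This note records the models, conventions and numerical choices behind
`kihscan`, in the order the pipeline applies them, together with what
the synthetic fixtures do and do not establish about real structures.

## Structure ingestion

Coordinates are read with gemmi from PDB or mmCIF and reduced to a
minimal chain → residue → heavy-atom model. Policies, applied
identically to both formats:

- **One model.** The first model's coordinates are used; multi-model
  (NMR) handling is deliberately out of scope.
- **Altlocs.** Per atom name, the highest-occupancy conformer is kept;
  ties break by altloc label, so `A` beats `B`. Deterministic and
  matches common practice.
- **Hydrogens** are stripped on ingest, which makes side-chain centers
  (below) independent of whether a file was protonated.
- **Waters and ligands** (anything without a Cα) are dropped: they
  cannot take part in knobs-into-holes packing between helices.
- **Modified residues.** MODRES records (PDB), the
  `pdbx_struct_mod_residue` category (mmCIF) and a built-in table of
  common modifications (MSE→MET, SEP→SER, …) set a residue's
  `parent_name`; unmatched non-standard residues get `UNK`. This
  annotation feeds reports and register tables only — all geometry is
  computed from the atoms actually present, which is what makes
  nonnatural side chains first-class citizens of the detector.

The package writes PDB and mmCIF through its own minimal emitters
(fixture output and round-trip tests); parsing always goes through
gemmi.

## Helix assignment

Two interchangeable sources produce the per-residue secondary-structure
map:

- **Classic DSSP files** (fixed-column layout). Only the chain, residue
  number and summary code are read; `!` chain-break markers are honoured
  so segments never span them. The mmCIF DSSP dialect is rejected with
  guidance.
- **Internal assigner.** The Kabsch–Sander electrostatic model scores
  each candidate CO(i)···HN(i+4) pair,

  E = 27.888 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)  kcal/mol,

  with the amide hydrogen reconstructed 1 Å from N opposite the
  preceding carbonyl C=O direction. A bond is called below
  −0.5 kcal/mol; a residue is labelled H inside two consecutive
  4-turns, the standard DSSP α-helix convention. On ideal helices the
  i→i+4 energies come out near −2.5 kcal/mol, comfortably past the
  threshold, so the assignment is robust to the ~0.2 Å coordinate noise
  the fixtures can add. Distances are floored at 0.5 Å so clashing
  coordinates degrade to "no bond" instead of overflowing.

Only code H seeds helix segments by default (flags admit G and I): the
target of the analysis is α-helical coiled coils, and 3₁₀/π stretches
would blur register arithmetic. The minimum segment length is 7 — one
heptad; a shorter helix cannot carry a meaningful coiled-coil repeat.
The *helix extension* parameter (default 0) grows segments by up to
that many residues per end, never across chain breaks, never absorbing
residues of another segment, and never merging segments, so helix
identity is stable under parameter sweeps.

## Knobs-into-holes detection

The packing unit is the **side-chain center**: the unweighted centroid
of a residue's heavy side-chain atoms (Cβ outward), the Cα for glycine
or any residue with no side-chain heavy atoms. Unweighted rather than
mass-weighted keeps the definition element-table-free (it works for
arbitrary nonnatural residues) and differs from mass weighting by under
0.2 Å for standard side chains, far below the cutoff scale.

A **contact** is an inter-helix pair of centers within the packing
cutoff (default 7.0 Å, boundary inclusive; the CLI constrains the dial
to 6.0–8.0 Å unless forced). Contacts are found with a k-d tree but are
defined — and tested — as identical to the all-pairs computation. A
residue with ≥ 4 contacts on one target helix is a **knob** into that
helix; its **hole** is the 4 nearest contacted residues, distance ties
broken by ascending residue number for full determinism. A residue may
be a knob into several helices, once per target.

Two knobs in opposite directions across a helix pair are
**complementary** when each is a member of the other's hole. A pair is
accepted as a coiled-coil interface when it has ≥ 1 complementary pair
and ≥ 3 knobs in total (both thresholds configurable); the second
condition suppresses interfaces built on a single incidental contact
cluster.

The **packing angle** of a knob is the angle at Cα between the
side-chain-center direction and the hole-center direction (the mean of
the 4 hole centers): 0° means the side chain points straight into the
hole. The 4-level knob type is: 4 when the Cα itself lies within the
cutoff of all four hole centers and the angle is < 45° (through-hole
insertion), 3 for < 45°, 2 for 45–90°, 1 otherwise (peripheral, and the
glycine/degenerate case where the angle is undefined). The 45°/90°
boundaries are package conventions, isolated in one function and
exposed as constants; they are a plausible operationalization of a
4-level insertion depth, not a calibrated reproduction of any legacy
tool's classes.

## Assembly, topology and register

Helices are nodes and accepted interfaces edges of an undirected graph;
every connected component with ≥ 2 nodes is one coiled-coil assembly.
Connected components — not cliques — are what make "any number of
helices" work: in an α-helical barrel each helix touches only its two
ring neighbours, so the component is the only structure that captures
the whole barrel. A component whose edge count reaches its node count
contains a cycle and is reported as **cyclic**; open bundles report
**open**. Assemblies are ordered by (smallest chain id, smallest first
residue) for stable, diffable output.

Pair orientation comes from fitted axes: crossing angle
arccos(d̂ₐ·d̂ᵦ) in [0°, 180°], parallel below 90° with the tie going to
parallel. Helix axes are the first principal component of the segment's
Cα coordinates, sign-fixed N→C. A finite helix with a fractional number
of turns biases this axis slightly (about 1.5° for a 21-residue straight
helix, shrinking with length); this is far inside the 5° tolerances
used for crossing-angle statements, and local-axis refinement is listed
as future work. The axis record carries a straightness diagnostic: the
RMS spread of Cα radial distances about their mean, ~0 for an ideal
helix.

The **register** is anchored on knob spacings only: consecutive knob
residues 3 apart read (a, d), 4 apart read (d, a); each anchor implies
a heptad phase and the majority phase wins (earliest anchor on ties),
with dissenters counted and reported as conflicts, never suppressed.
Spacings other than 3 or 4 are mod-7 ambiguous and contribute nothing;
with no usable anchor the register stays unassigned and renders as
gaps. Letters propagate over the whole segment by heptad arithmetic, so
letter(i+7) = letter(i) holds by construction wherever assigned. For
barrels this yields a single a–g register per helix; helices whose
knobs sit at barrel e/g-type positions can show conflicts, which is the
intended signal.

## Synthetic fixtures

All tests run on idealized coiled coils generated from the two-level
Crick parameterization: a minor α-helix of radius R1 wound on a
left-handed superhelix of radius R0 and pitch P. Defaults are canonical
dimer values from the coiled-coil literature: R0 = 4.9 Å, R1 = 2.26 Å,
3.62 residues per turn, P = 148 Å, rise 1.495 Å per residue along the
path, 28 residues per helix. With these values the minor-helix twist in
the superhelical rotating frame lands at ≈ 102.9°/residue — the
heptad-averaged 7/2 periodicity — which is exactly why knobs of the
ideal dimer fall on a/d positions.

Backbone N, C and O atoms take their cylindrical offsets relative to Cα
from a template α-helix built internally from ideal bond geometry and
(φ, ψ) = (−57.8°, −47.0°), transferred onto the local superhelical
frame. The pseudo side chain is a single CB atom on the local outward
bisector (the minor-helix radial through Cα) at the standard Cα–Cβ bond
length of 1.53 Å; for a center-based detector this stands in for a full
side chain and leaves ~1 Å of margin between the ideal dimer's
4th-nearest hole distance (≈ 6.0 Å) and the 7 Å cutoff, so 0.2 Å
jitter cannot flip detections. Conventions chosen once for the
generator: helix i of a Cn arrangement is phase-rotated by 2πi/n;
reversed (antiparallel) helices are shifted axially by two residue
rises so the up- and down-running core ladders interdigitate, as they
do in real antiparallel coiled coils; barrels pick R0 so ring
neighbours sit 9.2 Å apart and scale P with R0 to keep the superhelical
pitch angle at the dimer value. Gaussian coordinate jitter (seeded,
capped below 0.3 Å) provides perturbation replicates.

What the fixtures do **not** emulate: real rotamer diversity and
side-chain size variation, sequence-dependent packing, bent or kinked
helices, missing atoms and crystallographic noise beyond isotropic
jitter. Passing tests therefore establish the correctness of the
definitions and the detector's internal consistency (oracle
equivalence, monotonicity, symmetry, determinism) — not field accuracy
on deposited structures, which depends on how well 7 Å center-based
packing captures real interfaces. The brute-force oracle re-derives
knobs literally (all pairwise distances, threshold, 4-nearest) with no
spatial indexing, keeping it independent of the production path.

## Problem sizes and runtime

The test suite and the acceptance script use the study-scale fixtures
throughout: 28 residues per helix, bundles of 2–4, barrels of 5–9, 50
jittered replicates for oracle agreement. The whole suite runs in well
under a minute on one CPU; the acceptance script in a few seconds.

## Known limitations

- First-model-only ingestion; biological-assembly expansion is the
  user's responsibility (supply expanded coordinates).
- Classic DSSP format only; the mmCIF DSSP dialect is rejected.
- Unsigned crossing angles: handedness of the packing is not reported.
- Knob-type thresholds are package conventions (see above), and the
  register for barrels is a single a–g alphabet per helix with a
  conflict count rather than per-interface registers.
- No Crick-parameter fitting to detected coiled coils, no solvent
  accessibility, no β-layer packing.
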