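# Methods

This note documents the models and numerical choices behind quadfold in the
package's own terms: what is computed, under which assumptions, with which
defaults, and what the synthetic benchmarks do and do not demonstrate.

## Topology model

A quadruplex fold is described declaratively: stacked tetrad layers (top to
bottom), each an ordered quartet of guanine positions whose list order is
the Hoogsteen hydrogen-bond cycle (member *k* donates N1–H1···O6 and
N2–H21···N7 to member *k+1*); a syn/anti glycosidic state per guanine;
strands, loops, grooves, bulges; and capping pairs/triples declared by
their explicit donor/acceptor atoms.

Strand orientations are derivable rather than free: with the rotational
sense of each layer fixed by its quartet order, a guanine's base-normal
direction follows from the layer sense, and strand polarity follows from
(normal, glycosidic state) — anti on a "sense-positive" layer runs one way,
syn the other.  Orientations are reported relative to the first strand,
which is always labelled "up".  Inconsistent combinations (a strand whose
guanines imply both directions) are rejected.

Loop types follow the corner geometry of the strands they connect:
same-orientation neighbours give propeller loops, antiparallel neighbours
edgewise loops, opposite corners diagonal loops.  Groove widths: parallel
neighbours flank medium grooves; for antiparallel neighbours the top-tetrad
donor disambiguates — the groove crossed by a syn donor is narrow, by an
anti donor wide.  This convention reproduces the wide/medium/narrow/medium
pattern of the TP3-T6 fold with the TCC edgewise loop across the wide
groove and the CG edgewise loop across the narrow groove, and it swaps
wide/narrow when the hydrogen-bond cycle is reversed.

## Restraint system

Calibration constants (all configurable through `RestraintParameters`):

| family | values |
|---|---|
| NOE non-exchangeable | strong 2.7±0.8, medium 3.8±0.9, weak 5.5±1.7 Å |
| NOE exchangeable | strong 3.6±0.9, medium 4.8±1.2, weak 5.5±1.7 Å |
| Hoogsteen H-bonds | H21–N7, H1–O6: 2.0±0.2 Å; N2–N7, N1–O6: 2.9±0.3 Å |
| glycosidic χ | syn 60°, anti 240°; halfwidth 70° (outer) / 40° (inner tetrad) |
| planarity | 1 kcal·mol⁻¹·Å⁻² per group |
| repulsion | lower bound 3.5 Å |

Counting conventions: hydrogen-bond restraints are kept per *directed*
tetrad edge (16 per tetrad); an ambiguously assigned donor contributes a
single counted restraint with OR semantics (effective distance = minimum
over alternatives); duplicate peaks across mixing times collapse to the
tightest class.  The capping guanine G14, whose glycosidic state is not
fixed spectroscopically, defaults to anti (it extends an anti tract and
yields the 13-row dihedral tally); this is configurable.

## Energy model

Idealized and deliberately minimal — restraints, not physics, do the work:

* harmonic bonds (300 kcal·mol⁻¹·Å⁻²), angles (80), impropers (40) and
  furanose ring torsions (15 kcal·mol⁻¹·rad⁻²) at template ideal values;
  the ring-torsion terms fix the sugar pucker, which the model does not
  otherwise sample;
* signed-volume chirality wells for sugar stereocentres (including the
  prochiral CH2 groups, so named geminal protons cannot swap faces);
* flat-bottom wells for distance and dihedral restraints; planarity as the
  smallest eigenvalue of the group scatter matrix (its exact gradient is
  the fixed-normal formula);
* soft-sphere repulsion (quartic + quadratic) on 0.85× summed van der
  Waals radii, with 1-2/1-3/1-4 and hydrogen-bond-restrained pairs
  excluded;
* no electrostatics, solvent or ions — the central K⁺ coordination is not
  modelled; tetrad geometry is maintained by hydrogen-bond and planarity
  restraints alone.

Residue templates (ideal coordinates, connectivity, hydrogens) come from
the chemical component dictionary bundled with biotite, normalised to
in-chain polymer form.  Amino protons are renamed where necessary so H21 /
H41 / H61 is the proton cis to the ring nitrogen, matching the naming the
restraint tables use.  Terminal hydroxyl protons are not modelled.

## Folding protocol

Each of `n_start` independent runs:

1. **Distance geometry.** Bounds matrix with covalent 1-2/1-3 distances
   fixed (±0.01 Å; covalent geometry dominates restraints on the same
   pair), restraint bounds merged tighter-wins, upper bounds
   triangle-smoothed to the shortest-path fixed point; random metrization
   (1000 pairs) and Gram-matrix eigen-embedding; the mirror image is
   resolved by the template chirality score.
2. **Rigid-unit assembly.** Each nucleotide is a rigid body at its
   restrained χ; simulated annealing on the 6 rigid degrees of freedom per
   residue with forces from the distance restraints, backbone-link springs
   and a quadratic steric floor (30 000 steps, exponential cooling).  This
   stage crosses the topological barriers that defeat all-atom dynamics:
   distance information alone cannot re-thread a chain, but rigid chiral
   units under a specific hydrogen-bond "glue" can.  Roughly a third to a
   half of runs assemble the correct fold; the rest land in misfolded
   basins with conspicuously higher energy and are eliminated by the
   lowest-energy selection.
3. **All-atom refinement.** Restrained velocity-Verlet dynamics (2 fs
   steps, hydrogen masses floored at 12 amu, velocity-rescaling thermostat
   every 50 steps — deterministic, no stochastic forces) over an annealing
   schedule, then minimization.  The published-style refinement schedule
   (heat 300→1000 K/14 ps, equilibrate, ramp the NOE constants 2→16/8
   kcal·mol⁻¹·Å⁻², cool to 300 K, average the last 10 ps) is encoded as
   `AnnealingSchedule.refinement_protocol()`; the default for routine runs
   is the same staging compressed in time (`quick(0.05)`), since the full
   150 ps protocol is a refinement schedule for near-final structures, not
   an assembly device for this restraint-only potential.  Stages may ramp
   the van der Waals scale (reduced radii while hot), the standard trick
   that lets frustrated segments pass through each other.
4. **Regularization.** Restraint-weight continuation: repeated
   minimization while geometrically ramping the distance force constants
   (×4 … ×1024), then scoring with the protocol constants.  This drives
   the kept models to zero distance-restraint violations when the
   restraint set is internally consistent.  Runs still showing >120
   violations after refinement are scored without this stage — they rank
   last regardless.

Determinism: all run seeds derive from the master seed via
`numpy.random.SeedSequence`; identical inputs and seed give bit-identical
ensembles.

## Structure analysis

Hydrogen bonds are detected geometrically (donor–acceptor heavy-atom
distance < 3.5 Å, donor–H···acceptor angle > 120°), consistent with the
2.0/2.9 Å restraint targets.  Tetrads are directed 4-cycles of the
N1→O6 + N2→N7 Hoogsteen graph; layers stack by centroid ordering along the
principal axis, with the layer containing the smallest residue position
listed first.  syn/anti classification uses a ±90° window around χ = 60°;
borderline residues are still classified and χ is always reported.
Groove widths are measured as mean phosphate separations of cycle-adjacent
guanines and mapped with thresholds calibrated once on the ideal generator
and frozen (narrow < 13 Å, wide > 17 Å).  Pair modes distinguish Hoogsteen
from reverse-Hoogsteen by the cis/trans arrangement of the two glycosidic
bonds about the pairing axis.  Ensemble statistics use heavy atoms only;
the "tetrad core" RMSD selection is the tetrad guanines (configurable).

## NOESY prediction and inversion

Peaks are predicted for proton pairs below 5.5 Å (the weak-class ceiling)
and binned at the midpoints of the calibration targets (non-exchangeable
3.0/4.5 Å; exchangeable 4.2/5.15 Å).  Geminal pairs (fixed separations)
are never emitted, and amino-proton peaks are excluded by default: their
intensities do not calibrate reliably to distances, and their structural
information enters through the hydrogen-bond restraints instead.

Inverting connectivities into tetrads uses H1(a)–H8(b) peaks with two
guards that mirror spectroscopic practice: sequence-adjacent pairs are
ignored (trivial stacking contacts), and when the peak list contains
imino–imino information each edge must be corroborated by an H1(a)–H1(b)
peak — the same H1–H1 confirmation used to establish tetrad alignments
experimentally.  Without the corroboration guard, a capping guanine that
stacks on the outer tetrad (G2 in TP3-T6) can impersonate a cycle member.
Only vertex-disjoint 4-cycles are returned; conflicting cycles raise an
ambiguity error listing the candidates.

## Melting model

Unimolecular two-state unfolding: θ(T) = 1/(1 + exp[(ΔH_vH/R)(1/Tm −
1/T)]), signal = θ·(folded baseline) + (1−θ)·(unfolded baseline), both
baselines linear.  Temperatures are °C externally, Kelvin internally;
R = 1.987×10⁻³ kcal·mol⁻¹·K⁻¹.  Fitting emulates the manual two-baseline
construction: the coolest/hottest 15% of points initialise the baselines,
then all six parameters are refined by least squares; a curve whose
detrended curvature amplitude is below 3× the baseline noise raises a
fit-failure error.  ΔH is van't Hoff, not calorimetric; simulations
default to 45 kcal·mol⁻¹, a typical value for a three-tetrad
intramolecular quadruplex, as a documented free synthetic parameter (no
measured enthalpy is reproduced).  Strand-concentration dependence and
kinetic (scan-rate) effects are out of scope; equilibrium simulations
always satisfy the <2 °C heating/cooling consistency criterion.

## Synthetic generator

`build_ideal_structure` realises a topology as an all-atom model: a
canonical in-plane guanine pose is solved once by least squares so that
all four Hoogsteen distances fall inside their restraint wells (the
H-proton targets and heavy-atom targets cannot be hit simultaneously at
their centres; landing inside the flat-bottom wells is the design
criterion), layers stack at rise 3.3 Å and twist 30° (literature-typical
defaults, right-handed progression, never asserted against any measured
structure), capping bases are posed in-plane from their declared bonds
with donor-linearity and steric hinge terms, and loop/bulge/flank residues
are placed on arcs and closed by restrained minimization with all
structured bases pinned.  Glycosidic torsions are initialised at 60°/240°
and held by tight wells during closure; they relax by a few degrees but
stay well inside the classification windows.

What the generator does *not* emulate: physically realistic loop
conformational ensembles, ion coordination, chemical shifts or intensity
noise in peak lists, or the deposited coordinates themselves.  Passing the
round-trip and fold-recovery benchmarks therefore demonstrates internal
consistency of the pipeline at realistic geometry, not agreement with
experimental data.

## Problem sizes and defaults used in the benchmarks

The test suite runs the fold-recovery benchmark at n_start = 20 /
n_keep = 5 with the compressed annealing schedule and a 30 000-step rigid
stage — the scaled-down analogue of the 100-computed / 10-kept production
default.  Melting recovery uses 100 replicates per condition at noise
sd 0.002 on a unit-range signal over a 15–95 °C, 0.5 °C grid.

## Known limitations

* The restraint-only potential cannot rank conformers physically; energies
  are restraint-satisfaction scores plus idealized covalent strain.
* The rigid-assembly stage's temperature scale is dimensionless and tuned
  for 20-30-nt systems; much larger systems would need re-tuning.
* Groove thresholds and hydrogen-bond cutoffs are calibrated on the
  idealized generator; strongly distorted experimental structures may need
  adjusted cutoffs.
* Inversion of peak lists assumes resonance assignment is given (peaks are
  identified by proton identity, not chemical shift).
* The all-parallel and 2+2 antiparallel generator fixtures are idealized
  architectures for testing the classifiers, not models of specific
  experimental structures.
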