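# Methods

## Sequence comparison and the A-RISC index

The index for a pair of mature allergen sequences is the arithmetic mean
of their pairwise identity and similarity fractions, categorized with
inclusive lower bounds at 0.75 / 0.50 / 0.25 (high, medium-high,
medium-low; below 0.25 low). The category function is therefore a
piecewise-constant, monotone non-decreasing function of the index, and the
index is symmetric in its two arguments because the pair is ordered
canonically by identifier before alignment.

Published percent-identity servers rarely state their conventions, so this
package makes all three explicit and embeds them in every output:

* **Alignment.** Global Needleman–Wunsch with affine gaps (Gotoh
  three-state recursion), default BLOSUM62 with gap open 10 and extend
  0.5; a gap of length L costs `open + (L−1)·extend`, end gaps included.
  The dynamic program runs in integer half-units so traceback comparisons
  are exact, and ties are broken deterministically: residue pair over gap
  in the first sequence over gap in the second. With that convention the
  emitted alignment is reproducible across platforms; when co-optimal
  alignments exist, swapping the inputs can select a different (equally
  optimal, equal-score) alignment, which is why symmetry of the index is
  enforced by canonical ordering rather than assumed. Alternatively a
  precomputed MSA (aligned FASTA or Clustal) can be supplied; the induced
  pairwise alignment drops columns gapped in both rows.
* **Denominator.** `shorter-sequence` (default), `mean-length`, or
  `alignment-length`. The default makes identity insensitive to C-terminal
  extensions in the partner, which suits allergen families with ragged
  termini.
* **Similarity.** `group-based` (default): same class under the partition
  GAVLI / FYW / CM / ST / KRH / DENQ / P, which covers all 20 residues;
  identical residues are always similar. `matrix-positive`: positive
  substitution-matrix score. The same scheme drives the surface
  conservation classes, so profile plots and structure maps cannot
  diverge.

These defaults are a declared convention, not a claim about what any
particular server does; reproducibility requires stating one.

## Physicochemistry

Average (isotope-weighted) mass is the sum of residue average masses plus
one water (computed via Biopython's residue tables); each disulfide bridge
removes two hydrogens, 2.01588 Da. ε280 uses the Pace coefficients
5500 (Trp), 1490 (Tyr) and 125 per cystine, with cystines counted as
⌊nCys/2⌋ under the all-cystine assumption and 0 otherwise. Masses are kept
at full precision internally; rounding to the nearest Da happens only in
reports.

## Structure model

gemmi parses PDB and mmCIF. Model 1 is used (with a warning if more
exist). Alternate conformations are resolved at load time to the
highest-occupancy altloc, ties to the alphabetically first — applied
before any geometry, so all downstream operations see one atom per name.
Waters and heteroatoms are parsed but flagged, and excluded from protein
operations (SASA, cavities, sequences, disulfides) by default; both study
systems are apo proteins, so this is neutral for them. SEQRES sequences
are retained per chain when declared. Residue numbering follows the
deposited mature-protein 1-based convention.

**Disulfides.** Cysteine SG atoms within 2.5 Å are paired greedily,
nearest first, each SG in at most one bridge. The threshold sits well
above the ~2.05 Å covalent bond and below van der Waals contact, so it
tolerates refinement variance without inventing bridges.

**Superposition.** Least-squares (Kabsch) fit via scipy's constrained SVD
(`Rotation.align_vectors`), which always returns a proper rotation;
degenerate inputs (fewer than three points, collinear or coincident sets)
are rejected by a singular-value check. RMSD matrices pair atoms by
residue number within a crystal form (chains there are
sequence-identical); across homologous proteins, pairing by global
sequence alignment of the coordinate-derived sequences is available.

## Surface geometry

**SASA** is Shrake–Rupley with a deterministic golden-spiral point set
(default 960 points, probe 1.4 Å) and Bondi element radii (C 1.70, N 1.55,
O 1.52, S 1.80 Å; the table name is recorded in every result). A sample
point survives if it lies on or outside every neighbouring expanded
sphere; occlusion is strict interior containment, so two exactly tangent
spheres do not occlude each other. Doubling the point count changes
fixture totals by under 1%, and totals agree with an independent
implementation (biotite) to ~0.1% at equal radii.

**Interfaces.** Buried area between disjoint chain groups is
`SASA(A) + SASA(B) − SASA(A∪B)` from three evaluations with identical
parameters; the reported interface area is half of that (PISA convention),
and the monomer/homodimer call compares the half-ΔSASA against the 856 Å²
discrimination cutoff, the same convention under which that cutoff was
proposed.

**Cavities.** A cubic grid (default 0.5 Å) over the padded bounding box
marks cells within `r_atom + probe` of any atom as occupied; flood fill
from the box boundary through empty cells (face connectivity) labels the
exterior, and every remaining empty component is a cavity with volume
`n_cells · grid³`. This measures the volume accessible to probe centres.
It is deliberately *not* a reimplementation of alpha-shape pocket
programs (CASTp and kin measure differently and report mouths), so cavity
volumes are compared against those programs only qualitatively
(presence/absence, bounded magnitude), never numerically. A configurable
cell budget guards memory; grid refinement from 0.5 to 0.25 Å moves the
fixture cavity volume by under 5%.

## Surface conservation mapping

Each modeled residue of a chain receives its alignment column's class
(identical / similar / different / unaligned) and a relative SASA —
residue SASA over the Tien et al. (2013) theoretical maximum for that
residue type. Residues at relative SASA ≥ 0.25 count as surface (the
threshold is configurable and logged; no published criterion exists for
this family, and 0.25 is a common surface-exposure convention). Summary
fractions are taken over surface residues only, since those are the
epitope-relevant population; they sum to one across the four classes.
A painted copy of the structure encodes the classes as B-factors
(2 / 1 / 0 / −1) for molecular-graphics rendering. Spatial clustering of
conserved patches is deliberately out of scope — no quantitative patch
definition exists to validate against.

## Synthetic fixtures

Each generator draws from its own seeded `numpy.random.Generator`;
identical parameters give byte-identical output, and each fixture's
parameters are recoverable by the analysis it feeds:

* **Ideal helix** (rise 1.5 Å, twist 100°, radius 2.3 Å, Cα only):
  consecutive Cα–Cα distances ≈ 3.8 Å; one-turn (i, i+3) contacts closer
  than (i, i+2), the helical contact signature used in the geometry tests.
* **Perturbed copy**: random rigid transform plus iid Gaussian coordinate
  noise; expected recovered RMSD is σ√3 (≈ 0.346 Å at σ = 0.2).
* **Hollow shell** (default radius 8 Å, 500 carbon atoms on a golden
  spiral): encloses one probe-inaccessible cavity with analytic
  probe-centre volume 4/3·π·(R − r_atom − probe)³ = 492.8 Å³ at defaults;
  the generator rejects shells sparse enough for the probe to enter.
* **Two-body assembly**: two single-carbon chains at a set separation,
  spanning tangent contact (interface area given by the spherical-cap
  closed form) to full separation (zero).
* **Mutated family**: per-site substitution with probability `rate`;
  replacements drawn within the similarity group with probability
  `within_group_fraction`, otherwise outside it, and always different from
  the original. Expected identity is 1 − rate and expected similarity
  1 − rate·(1 − within_group_fraction). Residues whose class has no
  alternative member (proline) fall back to out-of-group replacement, so
  the similarity expectation is exact only for ancestors avoiding proline;
  the tests use a proline-free ancestor alphabet.

What the fixtures do **not** emulate: real side-chain packing, hydrogen
bonding, sequence composition bias, indel evolution (the family generator
is substitution-only), or crystallographic artefacts (altloc disorder,
missing loops). Passing the recovery suite therefore shows the geometry
and counting machinery is correct, not that any biological conclusion
transfers; conclusions about real allergens come from running the same
operations on deposited structures.

## Problem sizes and verification

The recovery suite runs at the study conditions: 200-site families,
100-residue helices at σ = 0.2 Å, an 8 Å shell with 500 atoms, 960 SASA
sphere points, 0.5 Å cavity grids. Sequence-family checks use a
3-binomial-SD acceptance band around the generator expectation; geometric
checks use 10% (Monte-Carlo and discretization-limited quantities), 2%
(cap-formula interface), and 1% (closed-form isolated-atom SASA).
`scripts/acceptance.py` recomputes all of these from scratch from a single
seed. The checks against the deposited crystal structures (PDB 7KSB/7KSC:
chain counts and lengths, disulfide pairings, 0.3/0.9 Å chain RMSDs,
sub-cutoff interfaces, SEQRES-derived masses and ε280, 45%/97%
identities, bounded cavity volumes) run whenever those published files are
placed under `data/`; the package does not redistribute them.

## Known limitations

* The aligner is O(n·m) pure Python; fine for allergen-sized sequences
  (≤ a few hundred residues), not for genome-scale work.
* SASA is O(n·k) per atom with KD-tree neighbour lookup; thousands of
  atoms are comfortable, very large assemblies are not the target.
* Cavity volumes depend on the radii table and grid registration; only
  cross-parameter trends and bounded comparisons are meaningful.
* Disulfide detection assumes resolved SG coordinates; it does not model
  disorder beyond altloc resolution.
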