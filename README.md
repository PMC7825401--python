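# arisc

Cross-reactivity scoring and structural characterization of plant
non-specific lipid transfer protein (nsLTP) allergens.

nsLTPs are small (7–9 kDa), heat- and digestion-resistant α-helical plant
proteins stabilized by four disulfide bridges, and one of the most
clinically important families of plant food allergens. Because IgE
antibodies raised against one family member often recognize homologues
from other plants, a central practical question is: *given a newly
characterized allergen, which other nsLTPs is a patient likely to
cross-react with?* This package implements the sequence index used to
answer that question together with the structure-derived measurements that
support it, for structural allergologists and anyone curating allergen
panels.

## The A-RISC index

For two mature allergen sequences (signal and pro-peptides removed), let
*I* be their pairwise sequence identity and *S* their similarity, both as
fractions of the shorter sequence length (the denominator convention is
configurable and recorded in every output). The Allergens'-Relative
Identity, Similarity and Cross-reactivity index is

    A-RISC = (I + S) / 2

binned into risk categories with inclusive lower bounds:

| A-RISC | category |
|---|---|
| ≥ 0.75 | high |
| 0.50 – 0.75 | medium-high |
| 0.25 – 0.50 | medium-low |
| < 0.25 | low |

Identity and similarity come from an optimal global (Needleman–Wunsch,
affine-gap) alignment under BLOSUM62 (gap open 10, extend 0.5) or from a
user-supplied multiple sequence alignment; "similar" means same
amino-acid class under the partition `GAVLI / FYW / CM / ST / KRH / DENQ /
P` (or positive matrix score, if selected).

## Structure analysis

From a PDB/mmCIF file the package computes, per chain and assembly:

* disulfide connectivity (greedy nearest-first SG–SG pairing, 2.5 Å cutoff);
* Cα RMSD matrices from least-squares (Kabsch) superposition, with
  residue-number or sequence-alignment pairing;
* Shrake–Rupley solvent-accessible surface area (probe 1.4 Å, 960 sphere
  points, Bondi radii), interface buried area between chain groups
  (half-ΔSASA, PISA convention) and a monomer/homodimer call against the
  856 Å² discrimination cutoff;
* internal cavity volumes by probe-aware grid flood fill (0.5 Å grid);
* surface conservation maps: each residue of a chain classified
  identical/similar/different/unaligned against a homologue and flagged as
  surface-exposed at relative SASA ≥ 0.25;
* sequence-derived average mass (with −2.016 Da per disulfide) and ε280
  (5500·W + 1490·Y + 125·cystine).

## Worked example

Generate a synthetic allergen family with per-site substitution rates
0.1/0.3/0.6 from a 200-residue ancestor, then profile the ancestor against
it:

```
$ arisc fixtures family -o family.fasta --seed 7
$ python - <<'PY'
from arisc import read_fasta, arisc_profile
records = read_fasta("family.fasta")
profile = arisc_profile(records[0], records[1:])
print(profile.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
PY
              id             name  identity  similarity  arisc    category
anc_200_7_r0.1_0 anc_200_7_r0.1_0     0.910       0.960  0.935        high
anc_200_7_r0.3_1 anc_200_7_r0.3_1     0.755       0.900  0.828        high
anc_200_7_r0.6_2 anc_200_7_r0.6_2     0.390       0.715  0.552 medium-high
```

The measured identities track the generator's expected values (1 − rate =
0.9 / 0.7 / 0.4 within binomial noise), similarity always exceeds
identity, and the risk ordering follows the mutation rates.

The structure pipeline runs the same way on any PDB/mmCIF file; on the
hollow-shell fixture (shell radius 8 Å, carbon atoms), whose only cavity
has analytic probe-centre volume 492.8 Å³:

```
$ arisc fixtures shell -o shell.pdb --radius 8 --n-atoms 500
$ arisc structure-report shell.pdb -o report.json
$ python -c "import json; print(json.load(open('report.json'))['chains']['A']['cavities'])"
[{'volume_A3': 501.0, 'centroid': [-0.002, -0.01, -0.003], 'n_cells': 4008}]
```

`arisc compare A.pdb B.pdb` superposes two structures and writes a
per-residue surface-conservation CSV plus a B-factor-painted PDB
(identical = 2, similar = 1, different = 0) for rendering.

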