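"""Deterministic synthetic sequences and structures with known ground truth.

Every generator takes an explicit integer seed and draws from its own
``numpy.random.Generator`` stream, so identical parameters always produce
identical output and no global random state is touched.  The fixtures are
designed so each analysis operation can recover the generating parameters:

* ideal α-helices (rise 1.5 Å, 100° twist, radius 2.3 Å) give known
  Cα-Cα geometry and well-conditioned inputs for superposition;
* rigid-transformed, Gaussian-perturbed copies have expected RMSD
  ``sigma * sqrt(3)`` for per-coordinate noise of sd ``sigma``;
* hollow atomic shells enclose a probe-inaccessible cavity whose
  probe-centre volume is the analytic shrunken-sphere volume
  ``4/3 * pi * (R - r_atom - probe)^3``;
* two-body assemblies span the touching-to-separated interface regimes;
* mutated sequence families have expected identity ``1 - rate`` and
  expected similarity ``1 - rate * (1 - within_group_fraction)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .sequences import (
    AMINO_ACIDS,
    DEFAULT_SIMILARITY_GROUPS,
    ProteinSequence,
)
from .structures import Atom, Chain, Residue, Structure

HELIX_RISE = 1.5  # Å per residue
HELIX_TWIST = 100.0  # degrees per residue
HELIX_RADIUS = 2.3  # Å


def make_helix(n_res: int, residue_name: str = "ALA", chain_label: str = "A") -> Structure:
    """Ideal α-helix of Cα atoms (poly-alanine by default)."""
    if n_res < 4:
        raise ValueError("a helix fixture needs at least 4 residues")
    chain = Chain(label=chain_label)
    for i in range(n_res):
        theta = math.radians(HELIX_TWIST * i)
        pos = np.array(
            [HELIX_RADIUS * math.cos(theta), HELIX_RADIUS * math.sin(theta), HELIX_RISE * i]
        )
        chain.residues.append(
            Residue(
                number=i + 1,
                icode="",
                name=residue_name,
                atoms=[Atom(name="CA", element="C", pos=pos)],
            )
        )
    return Structure(id=f"helix{n_res}", chains=[chain])


@dataclass(frozen=True)
class RigidTransform:
    rotation: np.ndarray
    translation: np.ndarray


def perturb(
    structure: Structure,
    sigma: float = 0.0,
    seed: int = 0,
    rotation: np.ndarray | None = None,
    translation: np.ndarray | None = None,
) -> tuple[Structure, RigidTransform]:
    """Rigidly transform a copy of *structure*, then add iid Gaussian noise
    of sd *sigma* per coordinate; the ground-truth transform is returned."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    if rotation is None:
        rotation = Rotation.random(rng=rng).as_matrix()
    else:
        rotation = np.asarray(rotation, dtype=float)
    if translation is None:
        translation = rng.uniform(-10.0, 10.0, size=3)
    else:
        translation = np.asarray(translation, dtype=float)
    chains = []
    for ch in structure.chains:
        new_chain = Chain(label=ch.label)
        for res in ch.residues:
            atoms = []
            for a in res.atoms:
                pos = rotation @ a.pos + translation
                if sigma > 0:
                    pos = pos + rng.normal(0.0, sigma, size=3)
                atoms.append(Atom(name=a.name, element=a.element, pos=pos,
                                  occupancy=a.occupancy, b_factor=a.b_factor))
            new_chain.residues.append(
                Residue(number=res.number, icode=res.icode, name=res.name,
                        atoms=atoms, is_protein=res.is_protein, is_water=res.is_water)
            )
        chains.append(new_chain)
    out = Structure(id=f"{structure.id}_perturbed", chains=chains, seqres=dict(structure.seqres))
    return out, RigidTransform(rotation=rotation, translation=translation)


def hollow_shell(
    radius: float = 8.0,
    n_atoms: int = 500,
    atom_radius: float = 1.7,
    probe: float = 1.4,
    chain_label: str = "A",
) -> Structure:
    """Spherical shell of carbon pseudo-residues enclosing a cavity.

    The shell must be dense enough that the probe cannot slip between
    neighbouring atoms; the expected inter-atom gap is checked against the
    probe diameter.  The enclosed probe-centre cavity has analytic volume
    ``4/3 * pi * (radius - atom_radius - probe)^3``
    (see :func:`shell_cavity_volume`).
    """
    if radius <= atom_radius + probe:
        raise ValueError("shell radius leaves no interior cavity")
    spacing = math.sqrt(4.0 * math.pi * radius * radius / n_atoms)
    if spacing - 2.0 * atom_radius >= 2.0 * probe:
        raise ValueError(
            f"shell undersampled: estimated atom spacing {spacing:.2f} Å leaves "
            f"gaps the {probe:.2f} Å probe can pass; increase n_atoms"
        )
    i = np.arange(n_atoms) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n_atoms)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    xyz = radius * np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )
    chain = Chain(label=chain_label)
    for k, pos in enumerate(xyz):
        chain.residues.append(
            Residue(number=k + 1, icode="", name="ALA",
                    atoms=[Atom(name="CA", element="C", pos=np.array(pos))])
        )
    return Structure(id=f"shell_r{radius:g}", chains=[chain])


def shell_cavity_volume(radius: float, atom_radius: float = 1.7, probe: float = 1.4) -> float:
    """Analytic probe-centre cavity volume of an ideal hollow shell."""
    r_int = radius - atom_radius - probe
    return 4.0 / 3.0 * math.pi * r_int ** 3


def two_body(separation: float, chain_labels: tuple[str, str] = ("A", "B")) -> Structure:
    """Two single-carbon chains *separation* Å apart along x, for interface
    tests from tangent contact to full separation."""
    chains = []
    for label, x in zip(chain_labels, (0.0, separation)):
        chains.append(
            Chain(
                label=label,
                residues=[
                    Residue(number=1, icode="", name="ALA",
                            atoms=[Atom(name="CA", element="C", pos=np.array([x, 0.0, 0.0]))])
                ],
            )
        )
    return Structure(id=f"two_body_{separation:g}", chains=chains)


def random_sequence(n: int, seed: int = 0, alphabet: str = AMINO_ACIDS) -> ProteinSequence:
    rng = np.random.default_rng(seed)
    letters = rng.choice(list(alphabet), size=n)
    return ProteinSequence(id=f"anc_{n}_{seed}", residues="".join(letters), source="synthetic")


def mutate_family(
    ancestor: ProteinSequence,
    rates: list[float],
    within_group_fraction: float = 0.5,
    seed: int = 0,
    groups: tuple[str, ...] = DEFAULT_SIMILARITY_GROUPS,
) -> list[ProteinSequence]:
    """Derive one mutated copy of *ancestor* per substitution rate.

    Each site mutates independently with probability ``rate``; the
    replacement (always a different residue) is drawn from the site's
    similarity group with probability *within_group_fraction*, otherwise
    from outside the group.  A residue whose group has no alternative
    member (e.g. proline) falls back to an out-of-group replacement.
    """
    for rate in rates:
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"substitution rate {rate} outside [0, 1]")
    if not 0.0 <= within_group_fraction <= 1.0:
        raise ValueError("within_group_fraction must lie in [0, 1]")
    group_of = {aa: g for g in groups for aa in g}
    rng = np.random.default_rng(seed)
    out = []
    for k, rate in enumerate(rates):
        letters = []
        for aa in ancestor.residues:
            if rng.random() >= rate:
                letters.append(aa)
                continue
            group = group_of.get(aa, aa)
            within = [c for c in group if c != aa]
            outside = [c for c in AMINO_ACIDS if c not in group]
            if within and rng.random() < within_group_fraction:
                letters.append(str(rng.choice(within)))
            else:
                letters.append(str(rng.choice(outside)))
        out.append(
            ProteinSequence(
                id=f"{ancestor.id}_r{rate:g}_{k}",
                residues="".join(letters),
                source=f"synthetic (rate={rate:g}, within_group={within_group_fraction:g}, seed={seed})",
            )
        )
    return out
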