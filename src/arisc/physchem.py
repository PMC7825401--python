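"""Sequence-derived physicochemistry: average mass and molar extinction.

The average (isotope-weighted) molecular mass of a polypeptide is the sum
of residue masses plus one water.  Each disulfide bridge removes two
hydrogen atoms (2 x 1.00794 Da), so the oxidized mass is

    mass_oxidized = mass_reduced - n_disulfides * 2.01588 Da.

The molar extinction coefficient at 280 nm uses the Pace coefficients

    epsilon = 5500 * nTrp + 1490 * nTyr + 125 * nCystine   [M^-1 cm^-1]

where nCystine = floor(nCys / 2) under the all-cystine assumption and 0
when all cysteines are assumed free.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.SeqUtils import molecular_weight

from .sequences import ProteinSequence

#: Average mass of a hydrogen atom (IUPAC), Da.
HYDROGEN_MASS = 1.00794
#: Mass removed per disulfide bridge (two hydrogens), Da.
DISULFIDE_MASS_LOSS = 2 * HYDROGEN_MASS

EPS_TRP = 5500.0
EPS_TYR = 1490.0
EPS_CYSTINE = 125.0


@dataclass(frozen=True)
class PhyschemResult:
    sequence_id: str
    n_residues: int
    n_cys: int
    n_disulfides: int
    mass_reduced: float
    mass_oxidized: float
    epsilon_280_cystines: float
    epsilon_280_reduced: float

    def to_dict(self) -> dict:
        return {
            "sequence_id": self.sequence_id,
            "n_residues": self.n_residues,
            "n_cys": self.n_cys,
            "n_disulfides": self.n_disulfides,
            "mass_reduced_da": self.mass_reduced,
            "mass_reduced_da_rounded": round(self.mass_reduced),
            "mass_oxidized_da": self.mass_oxidized,
            "mass_oxidized_da_rounded": round(self.mass_oxidized),
            "epsilon_280_cystines": self.epsilon_280_cystines,
            "epsilon_280_reduced": self.epsilon_280_reduced,
        }


def average_mass(seq: ProteinSequence, n_disulfides: int = 0) -> float:
    """Average molecular mass in Da of *seq* with *n_disulfides* bridges."""
    n_cys = seq.residues.count("C")
    if n_disulfides < 0 or n_disulfides > n_cys // 2:
        raise ValueError(
            f"{seq.id}: {n_disulfides} disulfides impossible with {n_cys} cysteines"
        )
    reduced = molecular_weight(seq.residues, seq_type="protein")
    return reduced - n_disulfides * DISULFIDE_MASS_LOSS


def extinction_280(seq: ProteinSequence, assume_cystines: bool = True) -> float:
    """Molar extinction coefficient at 280 nm (M^-1 cm^-1)."""
    n_trp = seq.residues.count("W")
    n_tyr = seq.residues.count("Y")
    n_cystine = seq.residues.count("C") // 2 if assume_cystines else 0
    return EPS_TRP * n_trp + EPS_TYR * n_tyr + EPS_CYSTINE * n_cystine


def physchem_report(seq: ProteinSequence, n_disulfides: int | None = None) -> PhyschemResult:
    """Mass and extinction summary; bridges default to the all-cystine
    assumption (floor(nCys/2))."""
    n_cys = seq.residues.count("C")
    if n_disulfides is None:
        n_disulfides = n_cys // 2
    reduced = average_mass(seq, 0)
    return PhyschemResult(
        sequence_id=seq.id,
        n_residues=len(seq),
        n_cys=n_cys,
        n_disulfides=n_disulfides,
        mass_reduced=reduced,
        mass_oxidized=average_mass(seq, n_disulfides),
        epsilon_280_cystines=extinction_280(seq, True),
        epsilon_280_reduced=extinction_280(seq, False),
    )
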