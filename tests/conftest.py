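from pathlib import Path

import numpy as np
import pytest

from arisc import ProteinSequence, ScoringScheme
from arisc.structures import Atom, Chain, Residue, Structure

REPO_ROOT = Path(__file__).resolve().parents[1]
#: Location where users may place deposited PDB entries and external
#: allergen sequences for the full reproduction checks.
DATA_DIR = REPO_ROOT / "data"


@pytest.fixture(scope="session")
def scheme() -> ScoringScheme:
    return ScoringScheme()


@pytest.fixture()
def toy_seqs() -> dict[str, ProteinSequence]:
    return {
        "acde": ProteinSequence("acde", "ACDE"),
        "ace": ProteinSequence("ace", "ACE"),
        "acdf": ProteinSequence("acdf", "ACDF"),
    }


def single_atom_residue(
    number: int,
    pos,
    name: str = "ALA",
    atom_name: str = "CA",
    element: str = "C",
) -> Residue:
    return Residue(
        number=number,
        icode="",
        name=name,
        atoms=[Atom(name=atom_name, element=element, pos=np.asarray(pos, dtype=float))],
    )


def chain_of_points(points, label: str = "A", name: str = "ALA") -> Chain:
    return Chain(
        label=label,
        residues=[single_atom_residue(i + 1, p, name=name) for i, p in enumerate(points)],
    )


def structure_of_points(points, structure_id: str = "toy") -> Structure:
    return Structure(id=structure_id, chains=[chain_of_points(points)])


def deposited_path(name: str) -> Path:
    """Path of a deposited coordinate or sequence file, or fail the test.

    The deposited crystal structures (PDB 7KSB, 7KSC) and external allergen
    sequences are not distributed with this package; users who want the
    full reproduction checks place them under data/pdb/ and
    data/sequences/.
    """
    candidates = [
        DATA_DIR / "pdb" / f"{name}.pdb",
        DATA_DIR / "pdb" / f"{name}.cif",
        DATA_DIR / "sequences" / f"{name}.fasta",
    ]
    for path in candidates:
        if path.exists():
            return path
    pytest.fail(
        f"deposited input {name!r} not available: place the file at "
        f"{candidates[0]} (or .cif / data/sequences/{name}.fasta). These "
        "published inputs are not distributed with the package."
    )
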