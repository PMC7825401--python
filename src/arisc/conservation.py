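"""Map pairwise sequence conservation onto a structure's surface.

Each modeled residue of a chain receives the class of its alignment column
(identical / similar / different / unaligned, using the same similarity
scheme as the A-RISC computation), its relative SASA (residue SASA divided
by a theoretical maximum for that residue type), and a surface flag
(relative SASA at or above a threshold, default 0.25).  The summary
fractions are taken over surface residues only — the population visible to
an antibody.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .sequences import GAP, PairwiseAlignment, ScoringScheme
from .structures import Structure, chain_sequence
from .surface import SasaResult

DEFAULT_SURFACE_THRESHOLD = 0.25

#: Theoretical maximum SASA per residue type, Å² (Tien et al. 2013,
#: theoretical values); used to normalise per-residue SASA.
MAX_SASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLU": 223.0, "GLN": 225.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

CLASSES = ("identical", "similar", "different", "unaligned")

#: B-factor codes written into painted PDB files for molecular graphics.
CLASS_BFACTOR = {"identical": 2.0, "similar": 1.0, "different": 0.0, "unaligned": -1.0}


@dataclass
class ConservationMap:
    structure_id: str
    chain: str
    surface_threshold: float
    residues: pd.DataFrame  # number, resname, partner, cls, sasa, rel_sasa, surface
    summary: dict

    def to_csv(self, path) -> None:
        self.residues.to_csv(path, index=False)


def map_alignment_to_structure(
    aln: PairwiseAlignment,
    structure: Structure,
    chain: str,
    scheme: ScoringScheme | None = None,
    row: str = "a",
) -> list[dict]:
    """Per-residue conservation classes for a chain of *structure*.

    The designated alignment row (``"a"`` or ``"b"``) must match the
    chain's coordinate-derived sequence exactly.
    """
    scheme = scheme or ScoringScheme()
    if row not in ("a", "b"):
        raise ValueError("row must be 'a' or 'b'")
    own = aln.aligned_a if row == "a" else aln.aligned_b
    other = aln.aligned_b if row == "a" else aln.aligned_a
    seq = chain_sequence(structure, chain, source="coordinates")
    ungapped = own.replace(GAP, "")
    if ungapped != seq.residues:
        first_bad = next(
            (k for k, (x, y) in enumerate(zip(ungapped, seq.residues)) if x != y),
            min(len(ungapped), len(seq.residues)),
        )
        raise ValueError(
            f"alignment row {row!r} does not match chain {chain!r} sequence "
            f"(first mismatch at position {first_bad + 1})"
        )
    residues = structure.chain(chain).protein_residues()
    out = []
    idx = 0
    for x, y in zip(own, other):
        if x == GAP:
            continue
        res = residues[idx]
        idx += 1
        if y == GAP:
            cls, partner = "unaligned", None
        elif x == y:
            cls, partner = "identical", y
        elif scheme.is_similar(x, y):
            cls, partner = "similar", y
        else:
            cls, partner = "different", y
        out.append(
            {
                "number": res.number,
                "resname": res.name,
                "own": x,
                "partner": partner,
                "cls": cls,
            }
        )
    return out


def surface_conservation(
    mapping: list[dict],
    sasa_result: SasaResult,
    structure: Structure,
    chain: str,
    rel_threshold: float = DEFAULT_SURFACE_THRESHOLD,
) -> ConservationMap:
    """Combine a conservation mapping with per-residue SASA into a surface
    conservation map and its class summary."""
    per_res = sasa_result.per_residue()
    per_res = per_res[per_res["chain"] == chain]
    sasa_by_number = dict(zip(per_res["resnum"], per_res["sasa"]))
    rows = []
    for entry in mapping:
        resname = entry["resname"]
        if resname not in MAX_SASA:
            raise ValueError(f"no reference maximum SASA for residue {resname!r}")
        value = float(sasa_by_number.get(entry["number"], 0.0))
        rel = value / MAX_SASA[resname]
        rows.append(
            {
                **entry,
                "sasa": value,
                "rel_sasa": rel,
                "surface": rel >= rel_threshold,
            }
        )
    frame = pd.DataFrame(rows)
    surf = frame[frame["surface"]]
    counts = {cls: int((surf["cls"] == cls).sum()) for cls in CLASSES}
    n_surface = len(surf)
    summary = {
        "n_residues": len(frame),
        "n_surface": n_surface,
        "counts": counts,
        "fractions": {
            cls: (counts[cls] / n_surface if n_surface else 0.0) for cls in CLASSES
        },
    }
    return ConservationMap(
        structure_id=structure.id,
        chain=chain,
        surface_threshold=rel_threshold,
        residues=frame,
        summary=summary,
    )


def paint_structure(structure: Structure, chain: str, mapping: list[dict]) -> Structure:
    """Copy of *structure* with conservation classes coded into B-factors
    (identical=2, similar=1, different=0, unaligned=-1) for rendering."""
    import copy

    painted = copy.deepcopy(structure)
    codes = {m["number"]: CLASS_BFACTOR[m["cls"]] for m in mapping}
    for res in painted.chain(chain).residues:
        if res.number in codes:
            for atom in res.atoms:
                atom.b_factor = codes[res.number]
    return painted
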