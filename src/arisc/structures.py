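"""Structure I/O, disulfide detection and least-squares superposition.

Structures are parsed with gemmi (PDB and mmCIF) into a small chain ->
residue -> atom container.  Alternate conformations are resolved at load
time to the highest-occupancy altloc (ties broken alphabetically), waters
and other heteroatoms are kept but flagged so protein-only operations can
skip them, and the declared SEQRES sequence is retained per chain when the
file provides one.

Superposition is the classical least-squares (Kabsch) fit, computed via
scipy's constrained SVD solution, so the returned rotation is always a
proper rotation (no reflections).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .sequences import AMINO_ACIDS, ProteinSequence, ScoringScheme, align_pair

#: SG-SG distance threshold for calling a disulfide bridge, in Å.  A typical
#: S-S bond is ~2.05 Å; 2.5 Å tolerates refinement variance while excluding
#: mere van der Waals contacts.
DEFAULT_SG_DISTANCE = 2.5


@dataclass
class Atom:
    name: str
    element: str
    pos: np.ndarray  # shape (3,), Å
    occupancy: float = 1.0
    b_factor: float = 0.0
    altloc: str = ""


@dataclass
class Residue:
    number: int
    icode: str
    name: str
    atoms: list[Atom] = field(default_factory=list)
    is_protein: bool = True
    is_water: bool = False

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def key(self) -> tuple[int, str]:
        return (self.number, self.icode)


@dataclass
class Chain:
    label: str
    residues: list[Residue] = field(default_factory=list)

    def protein_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.is_protein]

    def residue(self, number: int, icode: str = "") -> Residue | None:
        for r in self.residues:
            if r.number == number and r.icode == icode:
                return r
        return None


@dataclass
class Structure:
    id: str
    chains: list[Chain] = field(default_factory=list)
    seqres: dict[str, list[str]] = field(default_factory=dict)

    @property
    def chain_labels(self) -> list[str]:
        return [c.label for c in self.chains]

    def chain(self, label: str) -> Chain:
        for c in self.chains:
            if c.label == label:
                return c
        raise KeyError(f"structure {self.id!r} has no chain {label!r} "
                       f"(chains: {self.chain_labels})")

    def iter_atoms(
        self,
        chains: Sequence[str] | None = None,
        include_hydrogens: bool = False,
        include_het: bool = False,
    ):
        """Yield (chain, residue, atom) with the default protein-heavy-atom
        filtering applied."""
        wanted = set(chains) if chains is not None else None
        for ch in self.chains:
            if wanted is not None and ch.label not in wanted:
                continue
            for res in ch.residues:
                if res.is_water:
                    continue
                if not res.is_protein and not include_het:
                    continue
                for atom in res.atoms:
                    if not include_hydrogens and atom.element in ("H", "D"):
                        continue
                    yield ch, res, atom

    def coords(self, **kwargs) -> np.ndarray:
        pts = [a.pos for _, _, a in self.iter_atoms(**kwargs)]
        if not pts:
            raise ValueError(f"structure {self.id!r}: empty atom selection")
        return np.asarray(pts, dtype=float)


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one atom per name: highest occupancy, ties to the alphabetically
    first altloc."""
    by_name: dict[str, list[Atom]] = {}
    for a in atoms:
        by_name.setdefault(a.name, []).append(a)
    kept = []
    for name, group in by_name.items():
        group.sort(key=lambda a: (-a.occupancy, a.altloc))
        kept.append(group[0])
    return kept


def _residue_kind(name: str) -> tuple[bool, bool]:
    info = gemmi.find_tabulated_residue(name)
    if info is None:
        return False, False
    return info.is_amino_acid(), info.is_water()


def read_structure(path: str | Path, structure_id: str | None = None) -> Structure:
    """Parse a PDB or mmCIF file into a Structure (model 1 only)."""
    path = Path(path)
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no models in file")
    if len(st) > 1:
        warnings.warn(f"{path}: {len(st)} models present; using model 1")
    st.setup_entities()

    subchain_seq: dict[str, list[str]] = {}
    for ent in st.entities:
        if ent.full_sequence:
            seq = [item.split(",")[0] for item in ent.full_sequence]
            for sub in ent.subchains:
                subchain_seq[sub] = seq

    model = st[0]
    out = Structure(id=structure_id or (st.name or path.stem))
    for gch in model:
        chain = Chain(label=gch.name)
        for gres in gch:
            is_aa, is_water = _residue_kind(gres.name)
            res = Residue(
                number=gres.seqid.num,
                icode=(gres.seqid.icode or "").strip(),
                name=gres.name,
                is_protein=is_aa,
                is_water=is_water,
            )
            atoms = [
                Atom(
                    name=ga.name,
                    element=ga.element.name.upper(),
                    pos=np.array([ga.pos.x, ga.pos.y, ga.pos.z], dtype=float),
                    occupancy=ga.occ,
                    b_factor=ga.b_iso,
                    altloc="" if ga.altloc == "\x00" else ga.altloc,
                )
                for ga in gres
            ]
            res.atoms = _resolve_altlocs(atoms)
            chain.residues.append(res)
            if res.is_protein and chain.label not in out.seqres:
                sub = gres.subchain
                if sub in subchain_seq:
                    out.seqres[chain.label] = subchain_seq[sub]
        if chain.residues:
            out.chains.append(chain)
    if not out.chains:
        raise ValueError(f"{path}: empty model")
    return out


def to_gemmi(structure: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.id
    model = gemmi.Model("1")
    for ch in structure.chains:
        gch = gemmi.Chain(ch.label)
        for res in ch.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.number, res.icode or " ")
            gres.het_flag = "A" if res.is_protein else "H"
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.pos)
                ga.occ = a.occupancy
                ga.b_iso = a.b_factor
                gres.add_atom(ga)
            gch.add_residue(gres)
        model.add_chain(gch)
    st.add_model(model)
    st.setup_entities()
    return st


def write_pdb(structure: Structure, path: str | Path) -> None:
    to_gemmi(structure).write_pdb(str(path))


# ---------------------------------------------------------------------------
# Chain sequences
# ---------------------------------------------------------------------------


def three_to_one(name: str, permissive: bool = False) -> str | None:
    info = gemmi.find_tabulated_residue(name)
    code = info.one_letter_code.upper() if info is not None else " "
    if code not in AMINO_ACIDS:
        if permissive:
            return None
        raise ValueError(f"unknown residue name {name!r}")
    return code


def chain_sequence(
    structure: Structure,
    chain: str,
    source: str = "coordinates",
    permissive: bool = False,
) -> ProteinSequence:
    """One-letter sequence of a chain, from coordinates or SEQRES."""
    if source == "seqres":
        if chain not in structure.seqres:
            raise ValueError(f"structure {structure.id!r}: no SEQRES for chain {chain!r}")
        names = structure.seqres[chain]
        origin = "seqres"
    elif source == "coordinates":
        names = [r.name for r in structure.chain(chain).protein_residues()]
        origin = "coordinates"
    else:
        raise ValueError(f"unknown sequence source {source!r}")
    letters = []
    for name in names:
        code = three_to_one(name, permissive=permissive)
        if code is not None:
            letters.append(code)
    if not letters:
        raise ValueError(f"structure {structure.id!r} chain {chain!r}: no residues")
    return ProteinSequence(
        id=f"{structure.id}_{chain}",
        residues="".join(letters),
        source=f"{structure.id} chain {chain} ({origin})",
    )


def numbering_gaps(structure: Structure, chain: str) -> list[tuple[int, int]]:
    """Breaks in residue numbering of the modeled chain, as (before, after)
    residue-number pairs."""
    nums = [r.number for r in structure.chain(chain).protein_residues()]
    return [(a, b) for a, b in zip(nums, nums[1:]) if b > a + 1]


# ---------------------------------------------------------------------------
# Disulfides
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DisulfideBridge:
    partner_a: tuple[str, int]  # (chain, residue number)
    partner_b: tuple[str, int]
    sg_distance: float
    interchain: bool


def detect_disulfides(
    structure: Structure, max_sg_distance: float = DEFAULT_SG_DISTANCE
) -> list[DisulfideBridge]:
    """Greedy nearest-first pairing of cysteine SG atoms within the distance
    threshold; each SG joins at most one bridge."""
    sgs = []
    for ch in structure.chains:
        for res in ch.protein_residues():
            if res.name == "CYS":
                atom = res.atom("SG")
                if atom is not None:
                    sgs.append((ch.label, res.number, atom.pos))
    candidates = []
    for i in range(len(sgs)):
        for j in range(i + 1, len(sgs)):
            d = float(np.linalg.norm(sgs[i][2] - sgs[j][2]))
            if d <= max_sg_distance:
                candidates.append((d, i, j))
    candidates.sort()
    used: set[int] = set()
    bridges = []
    for d, i, j in candidates:
        if i in used or j in used:
            continue
        used.update((i, j))
        pa = (sgs[i][0], sgs[i][1])
        pb = (sgs[j][0], sgs[j][1])
        pa, pb = sorted((pa, pb))
        bridges.append(
            DisulfideBridge(partner_a=pa, partner_b=pb, sg_distance=d,
                            interchain=pa[0] != pb[0])
        )
    bridges.sort(key=lambda b: (b.partner_a, b.partner_b))
    return bridges


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray  # 3x3 proper rotation mapping b onto a
    translation: np.ndarray  # Å
    rmsd: float
    n_matched: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Transform coordinates from frame b into frame a."""
        return coords @ self.rotation.T + self.translation


def superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of *coords_b* onto *coords_a*.

    Both inputs are (n, 3) arrays with matching order; n >= 3 and the point
    sets must not be collinear or coincident.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"expected matching (n, 3) arrays, got {a.shape} and {b.shape}")
    n = a.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 paired points")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    ac, bc = a - ca, b - cb
    for label, pts in (("a", ac), ("b", bc)):
        sv = np.linalg.svd(pts, compute_uv=False)
        if sv[1] < 1e-8:
            raise ValueError(f"point set {label} is degenerate (collinear or coincident)")
    rot, rssd = Rotation.align_vectors(ac, bc)
    rmsd = float(rssd) / np.sqrt(n)
    R = rot.as_matrix()
    return SuperpositionResult(
        rotation=R, translation=ca - R @ cb, rmsd=rmsd, n_matched=n
    )


def _paired_coords_by_number(
    chain_a: Chain, chain_b: Chain, atom_name: str
) -> tuple[np.ndarray, np.ndarray, int]:
    map_a = {r.key: r.atom(atom_name) for r in chain_a.protein_residues()}
    map_b = {r.key: r.atom(atom_name) for r in chain_b.protein_residues()}
    shared = sorted(
        k for k in map_a.keys() & map_b.keys()
        if map_a[k] is not None and map_b[k] is not None
    )
    pa = np.array([map_a[k].pos for k in shared], dtype=float)
    pb = np.array([map_b[k].pos for k in shared], dtype=float)
    return pa, pb, len(shared)


def chain_rmsd_matrix(
    structure: Structure,
    atom_name: str = "CA",
    chains: Sequence[str] | None = None,
) -> pd.DataFrame:
    """All-vs-all Cα (by default) RMSD between chains, paired by residue
    number."""
    labels = list(chains) if chains is not None else structure.chain_labels
    labels = [lb for lb in labels if structure.chain(lb).protein_residues()]
    if len(labels) < 2:
        raise ValueError("need at least two protein chains")
    mat = pd.DataFrame(0.0, index=labels, columns=labels)
    for i, la in enumerate(labels):
        for lb in labels[i + 1 :]:
            pa, pb, n = _paired_coords_by_number(
                structure.chain(la), structure.chain(lb), atom_name
            )
            if n < 3:
                raise ValueError(f"chains {la}/{lb}: only {n} shared {atom_name} atoms")
            r = superpose(pa, pb).rmsd
            mat.loc[la, lb] = mat.loc[lb, la] = r
    return mat


def superpose_chains(
    struct_a: Structure,
    chain_a: str,
    struct_b: Structure,
    chain_b: str,
    pairing: str = "number",
    atom_name: str = "CA",
    scheme: ScoringScheme | None = None,
) -> SuperpositionResult:
    """Superpose one chain onto another.

    ``pairing="number"`` pairs residues sharing a residue number (suitable
    within one crystal form); ``pairing="alignment"`` pairs residues via a
    global sequence alignment of the two coordinate-derived sequences
    (suitable across homologous proteins).
    """
    ca, cb = struct_a.chain(chain_a), struct_b.chain(chain_b)
    if pairing == "number":
        pa, pb, n = _paired_coords_by_number(ca, cb, atom_name)
        if n < 3:
            raise ValueError(f"only {n} shared {atom_name} atoms")
        return superpose(pa, pb)
    if pairing != "alignment":
        raise ValueError(f"unknown pairing mode {pairing!r}")
    seq_a = chain_sequence(struct_a, chain_a)
    seq_b = chain_sequence(struct_b, chain_b)
    aln = align_pair(seq_a, seq_b, scheme)
    res_a = [r for r in ca.protein_residues()]
    res_b = [r for r in cb.protein_residues()]
    ia = ib = 0
    pts_a, pts_b = [], []
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x != "-" and y != "-":
            atom_1 = res_a[ia].atom(atom_name)
            atom_2 = res_b[ib].atom(atom_name)
            if atom_1 is not None and atom_2 is not None:
                pts_a.append(atom_1.pos)
                pts_b.append(atom_2.pos)
        if x != "-":
            ia += 1
        if y != "-":
            ib += 1
    if len(pts_a) < 3:
        raise ValueError("fewer than 3 aligned residue pairs with coordinates")
    return superpose(np.asarray(pts_a), np.asarray(pts_b))
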