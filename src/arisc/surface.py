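"""Solvent-accessible surface area, interface area and internal cavities.

SASA uses the Shrake-Rupley sphere-sampling construction: each atom's
van der Waals sphere is expanded by the probe radius (default 1.4 Å, a
water molecule) and sampled with a deterministic golden-spiral point set;
the accessible area is the sampled fraction not occluded by any
neighbouring expanded sphere, scaled by 4*pi*(r + probe)^2.

Interface (buried) area between two chain groups follows the PISA
convention: buried = SASA(A) + SASA(B) - SASA(A u B), and the reported
interface area is half of that.  A half-ΔSASA at or above 856 Å² is
classified as consistent with a homodimer, below it as consistent with a
monomer (Ponstingl-style cutoff).

Internal cavities are measured on a cubic grid: cells whose centre lies
within (r_atom + probe) of any atom are occupied, the exterior is marked by
flood fill from the grid boundary through empty cells, and each remaining
connected empty component is a cavity.  Cavity volume is therefore the
volume swept by probe centres, which for an ideal hollow shell equals the
probe-shrunken interior volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .structures import Structure

DEFAULT_PROBE = 1.4  # Å, water
DEFAULT_N_POINTS = 960
DEFAULT_GRID = 0.5  # Å
DEFAULT_INTERFACE_CUTOFF = 856.0  # Å², homodimer/monomer discrimination
DEFAULT_CELL_BUDGET = 120_000_000

#: Element-based van der Waals radii in Å (Bondi), with a generic fallback
#: for elements not listed.  The table name is recorded in every result.
VDW_RADII = {
    "bondi": {
        "H": 1.20, "D": 1.20, "C": 1.70, "N": 1.55, "O": 1.52,
        "S": 1.80, "P": 1.80, "SE": 1.90, "F": 1.47, "CL": 1.75,
        "BR": 1.85, "I": 1.98, "_default": 1.70,
    },
}


def vdw_radius(element: str, radii_set: str = "bondi") -> float:
    table = VDW_RADII[radii_set]
    return table.get(element.upper(), table["_default"])


def sphere_points(n: int) -> np.ndarray:
    """Deterministic, nearly uniform points on the unit sphere (golden
    spiral)."""
    if n < 1:
        raise ValueError("need at least one sphere point")
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


@dataclass
class SasaResult:
    structure_id: str
    chains: tuple[str, ...]
    probe_radius: float
    n_sphere_points: int
    radii_set: str
    atom_keys: list[tuple[str, int, str, str]]  # (chain, resnum, resname, atom)
    per_atom: np.ndarray  # Å²

    @property
    def total(self) -> float:
        return float(self.per_atom.sum())

    def per_residue(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.atom_keys, columns=["chain", "resnum", "resname", "atom"]
        )
        frame["sasa"] = self.per_atom
        out = (
            frame.groupby(["chain", "resnum", "resname"], sort=True)["sasa"]
            .sum()
            .reset_index()
        )
        return out


def sasa_coords(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> np.ndarray:
    """Per-atom Shrake-Rupley SASA for bare coordinates and radii."""
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or len(radii) != len(coords):
        raise ValueError("coords must be (n, 3) with matching radii")
    n = len(coords)
    pts = sphere_points(n_points)
    expanded = radii + probe
    tree = cKDTree(coords)
    out = np.empty(n)
    r_max = expanded.max()
    for i in range(n):
        ri = expanded[i]
        sample = coords[i] + ri * pts
        free = np.ones(n_points, dtype=bool)
        for j in tree.query_ball_point(coords[i], ri + r_max):
            if j == i:
                continue
            rj = expanded[j]
            if np.linalg.norm(coords[i] - coords[j]) >= ri + rj:
                continue
            d2 = np.einsum("ij,ij->i", sample - coords[j], sample - coords[j])
            free &= d2 >= rj * rj
        out[i] = 4.0 * np.pi * ri * ri * free.mean()
    return out


def _selection(
    structure: Structure,
    chains: Sequence[str] | None,
    radii_set: str,
    include_hydrogens: bool,
    include_het: bool,
):
    keys, coords, radii = [], [], []
    for ch, res, atom in structure.iter_atoms(
        chains=chains, include_hydrogens=include_hydrogens, include_het=include_het
    ):
        keys.append((ch.label, res.number, res.name, atom.name))
        coords.append(atom.pos)
        radii.append(vdw_radius(atom.element, radii_set))
    if not coords:
        raise ValueError("empty atom selection for SASA")
    return keys, np.asarray(coords), np.asarray(radii)


def sasa(
    structure: Structure,
    chains: Sequence[str] | None = None,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    radii_set: str = "bondi",
    include_hydrogens: bool = False,
    include_het: bool = False,
) -> SasaResult:
    """Shrake-Rupley SASA of a structure (waters and hydrogens excluded by
    default)."""
    keys, coords, radii = _selection(
        structure, chains, radii_set, include_hydrogens, include_het
    )
    per_atom = sasa_coords(coords, radii, probe=probe, n_points=n_points)
    return SasaResult(
        structure_id=structure.id,
        chains=tuple(chains) if chains is not None else tuple(structure.chain_labels),
        probe_radius=probe,
        n_sphere_points=n_points,
        radii_set=radii_set,
        atom_keys=keys,
        per_atom=per_atom,
    )


# ---------------------------------------------------------------------------
# Interfaces
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InterfaceResult:
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    sasa_a: float
    sasa_b: float
    sasa_complex: float
    buried_area_total: float  # ΔSASA, Å²
    interface_area: float  # half-ΔSASA, Å²
    cutoff: float
    classification: str  # consistent-with-monomer / consistent-with-homodimer


def interface_area(
    structure: Structure,
    group_a: Sequence[str],
    group_b: Sequence[str],
    cutoff: float = DEFAULT_INTERFACE_CUTOFF,
    **sasa_kwargs,
) -> InterfaceResult:
    """Buried area between two disjoint chain groups and the
    monomer/homodimer call against *cutoff* (applied to half-ΔSASA)."""
    ga, gb = tuple(group_a), tuple(group_b)
    if not ga or not gb:
        raise ValueError("both chain groups must be non-empty")
    if set(ga) & set(gb):
        raise ValueError(f"chain groups overlap: {sorted(set(ga) & set(gb))}")
    s_a = sasa(structure, chains=ga, **sasa_kwargs).total
    s_b = sasa(structure, chains=gb, **sasa_kwargs).total
    s_ab = sasa(structure, chains=ga + gb, **sasa_kwargs).total
    buried = max(0.0, s_a + s_b - s_ab)
    half = buried / 2.0
    return InterfaceResult(
        group_a=ga,
        group_b=gb,
        sasa_a=s_a,
        sasa_b=s_b,
        sasa_complex=s_ab,
        buried_area_total=buried,
        interface_area=half,
        cutoff=cutoff,
        classification=(
            "consistent-with-homodimer" if half >= cutoff else "consistent-with-monomer"
        ),
    )


# ---------------------------------------------------------------------------
# Cavities
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Cavity:
    volume: float  # Å³
    centroid: tuple[float, float, float]
    n_grid_cells: int


@dataclass(frozen=True)
class CavityResult:
    structure_id: str
    chains: tuple[str, ...]
    grid_spacing: float
    probe_radius: float
    radii_set: str
    cavities: tuple[Cavity, ...]  # sorted by volume, largest first

    @property
    def largest_volume(self) -> float:
        return self.cavities[0].volume if self.cavities else 0.0


def cavity_volumes(
    structure: Structure,
    chains: Sequence[str] | None = None,
    grid: float = DEFAULT_GRID,
    probe: float = DEFAULT_PROBE,
    radii_set: str = "bondi",
    include_hydrogens: bool = False,
    include_het: bool = False,
    cell_budget: int = DEFAULT_CELL_BUDGET,
) -> CavityResult:
    """Probe-inaccessible internal cavities by grid flood fill."""
    if grid <= 0:
        raise ValueError("grid spacing must be positive")
    _, coords, radii = _selection(
        structure, chains, radii_set, include_hydrogens, include_het
    )
    expanded = radii + probe
    pad = expanded.max() + 2 * grid
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    shape = np.ceil((hi - lo) / grid).astype(int) + 1
    if int(np.prod(shape)) > cell_budget:
        raise ValueError(
            f"cavity grid of {int(np.prod(shape))} cells exceeds the budget of "
            f"{cell_budget}; increase grid spacing or the budget"
        )
    occupied = np.zeros(shape, dtype=bool)
    # Stamp each atom's expanded sphere onto the grid via a local sub-box.
    for center, r in zip(coords, expanded):
        idx_lo = np.floor((center - r - lo) / grid).astype(int)
        idx_hi = np.ceil((center + r - lo) / grid).astype(int) + 1
        idx_lo = np.maximum(idx_lo, 0)
        idx_hi = np.minimum(idx_hi, shape)
        axes = [np.arange(idx_lo[k], idx_hi[k]) * grid + lo[k] for k in range(3)]
        dx2 = (axes[0] - center[0]) ** 2
        dy2 = (axes[1] - center[1]) ** 2
        dz2 = (axes[2] - center[2]) ** 2
        ball = (
            dx2[:, None, None] + dy2[None, :, None] + dz2[None, None, :]
        ) <= r * r
        occupied[
            idx_lo[0] : idx_hi[0], idx_lo[1] : idx_hi[1], idx_lo[2] : idx_hi[2]
        ] |= ball

    empty = ~occupied
    labels, n_labels = ndimage.label(empty)  # face connectivity
    if n_labels == 0:
        cavities: list[Cavity] = []
    else:
        boundary_labels = set()
        for axis in range(3):
            for sl in (0, -1):
                face = np.take(labels, sl, axis=axis)
                boundary_labels.update(np.unique(face[face > 0]).tolist())
        cavities = []
        cell_volume = grid ** 3
        for lab in range(1, n_labels + 1):
            if lab in boundary_labels:
                continue
            mask = labels == lab
            n_cells = int(mask.sum())
            centers = np.argwhere(mask) * grid + lo
            cavities.append(
                Cavity(
                    volume=n_cells * cell_volume,
                    centroid=tuple(np.round(centers.mean(axis=0), 3)),
                    n_grid_cells=n_cells,
                )
            )
        cavities.sort(key=lambda c: -c.volume)
    return CavityResult(
        structure_id=structure.id,
        chains=tuple(chains) if chains is not None else tuple(structure.chain_labels),
        grid_spacing=grid,
        probe_radius=probe,
        radii_set=radii_set,
        cavities=tuple(cavities),
    )
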