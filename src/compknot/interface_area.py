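"""Solvent-accessible surface areas and buried dimer interface area.

The buried interface area of a two-partner complex is

    B = SASA1 + SASA2 - SASA12,

where the first two terms are the solvent-accessible surface areas of
the partners in isolation and the third is that of the binary complex.
SASA is computed numerically by Shrake–Rupley sphere sampling: each atom
is covered with a deterministic quasi-uniform point set at radius
(r_atom + r_probe), and the accessible fraction is the share of points
outside every neighbouring atom's expanded sphere.  The point set is
fixed (no RNG), so areas are exactly reproducible; areas change by well
under 0.1% under rigid motions at the default sampling density.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "AtomSet",
    "InterfaceResult",
    "VDW_RADII",
    "sasa",
    "interface_B",
    "atoms_from_structure",
]

#: NACCESS-style van der Waals radii, Å (fallback for unlisted elements)
VDW_RADII = {
    "C": 1.87, "N": 1.65, "O": 1.40, "S": 1.85, "P": 1.80, "H": 1.00,
}
DEFAULT_RADIUS = 1.80

DEFAULT_PROBE = 1.4
DEFAULT_N_POINTS = 960

#: numerical tolerance on the buried area of non-contacting partners, Å²
BURIED_EPS = 0.5


@dataclass(frozen=True)
class AtomSet:
    """Atoms of one interface partner: elements, coordinates (Å), radii."""

    elements: tuple[str, ...]
    coords: np.ndarray  # (n, 3)
    radii: np.ndarray  # (n,)
    partner_tag: int = 1

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        radii = np.asarray(self.radii, dtype=float)
        if len(coords) == 0:
            raise ValueError("AtomSet needs at least one atom")
        if coords.ndim != 2 or coords.shape[1] != 3 or len(radii) != len(coords):
            raise ValueError("coords must be (n, 3) with parallel radii")
        if (radii <= 0).any():
            raise ValueError("all radii must be positive")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "radii", radii)
        object.__setattr__(self, "elements", tuple(self.elements))

    def __len__(self) -> int:
        return len(self.coords)

    @classmethod
    def from_coords(cls, coords, elements: Optional[Sequence[str]] = None,
                    partner_tag: int = 1) -> "AtomSet":
        coords = np.asarray(coords, dtype=float)
        if elements is None:
            elements = ["C"] * len(coords)
        radii = np.array([VDW_RADII.get(e.upper(), DEFAULT_RADIUS) for e in elements])
        return cls(tuple(elements), coords, radii, partner_tag)

    def merged_with(self, other: "AtomSet") -> "AtomSet":
        return AtomSet(
            self.elements + other.elements,
            np.vstack([self.coords, other.coords]),
            np.concatenate([self.radii, other.radii]),
            self.partner_tag,
        )


@dataclass(frozen=True)
class InterfaceResult:
    """The three SASA terms (Å²) and the buried interface area B."""

    sasa1: float
    sasa2: float
    sasa12: float

    @property
    def buried_B(self) -> float:
        return self.sasa1 + self.sasa2 - self.sasa12

    def __post_init__(self):
        if min(self.sasa1, self.sasa2, self.sasa12) < 0:
            raise ValueError("SASA terms must be nonnegative")
        if self.buried_B < -BURIED_EPS:
            raise ValueError(
                f"buried area {self.buried_B:.2f} below -{BURIED_EPS} Å²: "
                "the complex SASA exceeds the sum of the parts"
            )


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (Fibonacci lattice)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack([
        np.cos(theta) * np.sin(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(phi),
    ])


def sasa(atoms: AtomSet, probe_radius: float = DEFAULT_PROBE,
         n_points: int = DEFAULT_N_POINTS) -> tuple[float, np.ndarray]:
    """Total and per-atom solvent-accessible surface area, Å².

    Shrake–Rupley: sample ``n_points`` fixed lattice points on each
    atom's expanded sphere of radius (r + probe); a point is accessible
    when outside every neighbour's expanded sphere.  Per-atom area is
    the accessible fraction times 4π(r + probe)².
    """
    if probe_radius < 0:
        raise ValueError("probe_radius must be >= 0")
    if n_points < 100:
        raise ValueError("n_points must be >= 100 for a meaningful area")
    coords = atoms.coords
    expanded = atoms.radii + probe_radius
    n = len(atoms)
    if n > 1:
        d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1) if n <= 200 else None
        if d is not None:
            np.fill_diagonal(d, np.inf)
            if (d < 1e-6).any():
                warnings.warn("overlapping identical atoms; area computed as-is",
                              stacklevel=2)
    unit = _sphere_points(n_points)
    tree = cKDTree(coords)
    max_reach = 2 * expanded.max()
    areas = np.empty(n)
    for i in range(n):
        pts = coords[i] + expanded[i] * unit
        neigh = [j for j in tree.query_ball_point(coords[i], expanded[i] + expanded.max())
                 if j != i and np.linalg.norm(coords[j] - coords[i]) < expanded[i] + expanded[j]]
        if neigh:
            nb = np.asarray(neigh)
            d2 = ((pts[:, None, :] - coords[nb][None, :, :]) ** 2).sum(-1)
            buried = (d2 < (expanded[nb] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * expanded[i] ** 2
    # fsum: the total must not depend on atom enumeration order, so that
    # swapping interface partners is exactly symmetric
    import math

    return float(math.fsum(areas)), areas


def interface_B(partner1: AtomSet, partner2: AtomSet,
                probe_radius: float = DEFAULT_PROBE,
                n_points: int = DEFAULT_N_POINTS) -> InterfaceResult:
    """Buried interface area B = SASA1 + SASA2 - SASA12 of a complex.

    Symmetric in its partners by construction; B -> 0 as the partners
    separate.
    """
    s1, _ = sasa(partner1, probe_radius, n_points)
    s2, _ = sasa(partner2, probe_radius, n_points)
    s12, _ = sasa(partner1.merged_with(partner2), probe_radius, n_points)
    return InterfaceResult(s1, s2, s12)


def atoms_from_structure(path, chains: Sequence[str],
                         include_hetero: bool = False,
                         partner_tag: int = 1) -> AtomSet:
    """All (heavy and H) atoms of the named chains of a PDB/mmCIF file.

    Waters are always excluded; other hetero-compounds only when
    ``include_hetero`` is set.  Hydrogens are included when present.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if len(st) == 0:
        raise IOError(f"{path}: no models")
    elements, coords = [], []
    wanted = set(chains)
    for chain in st[0]:
        if chain.name not in wanted:
            continue
        for residue in chain:
            if residue.is_water():
                continue
            if not include_hetero and residue.het_flag == "H":
                info = gemmi.find_tabulated_residue(residue.name)
                if info is None or not info.is_amino_acid():
                    continue
            for atom in residue:
                if atom.altloc not in ("", "\x00", "A"):
                    continue
                elements.append(atom.element.name)
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
    if not coords:
        raise ValueError(f"{path}: no atoms in chains {sorted(wanted)}")
    return AtomSet.from_coords(np.asarray(coords), elements, partner_tag)
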