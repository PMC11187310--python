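"""Read protein structures into per-chain Cα polylines.

All topology operations in this package act on :class:`Polyline3D`, an
ordered Cα trace.  Structures are read with gemmi (PDB and mmCIF); predicted
models carry a per-residue confidence score (pLDDT, 0-100) in the B-factor
column, which is surfaced on :class:`ChainTrace` so that low-confidence
models can be refused before any topology call.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ChainTrace",
    "StructureModel",
    "Polyline3D",
    "LowConfidenceError",
    "EmptyModelError",
    "read_structure",
    "chain_to_polyline",
    "write_pseudo_pdb",
]

#: minimum number of points for any topology operation
MIN_POINTS = 3


class EmptyModelError(ValueError):
    """Raised when a structure file contains no polymer chain with Cα atoms."""


class LowConfidenceError(ValueError):
    """Raised when a chain's mean confidence falls below the requested gate.

    Carries the offending mean pLDDT in :attr:`mean_confidence`.
    """

    def __init__(self, chain_id: str, mean_confidence: float, threshold: float):
        self.chain_id = chain_id
        self.mean_confidence = float(mean_confidence)
        self.threshold = float(threshold)
        super().__init__(
            f"chain {chain_id}: mean confidence {mean_confidence:.1f} "
            f"below threshold {threshold:.1f}"
        )


@dataclass(frozen=True)
class Polyline3D:
    """An open or closed 3D polygonal curve (Å), optionally residue-labelled."""

    points: np.ndarray  # (n, 3) float
    labels: Optional[np.ndarray] = None  # parallel residue indices

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array")
        if not np.isfinite(pts).all():
            raise ValueError("points must be finite")
        object.__setattr__(self, "points", pts)
        if self.labels is not None:
            lab = np.asarray(self.labels)
            if len(lab) != len(pts):
                raise ValueError("labels must parallel points")
            object.__setattr__(self, "labels", lab)

    def __len__(self) -> int:
        return len(self.points)

    def subchain(self, start: int, stop: int) -> "Polyline3D":
        """Return the sub-polyline over the 0-based half-open index interval."""
        if not (0 <= start < stop <= len(self)):
            raise ValueError(f"bad subchain [{start}, {stop}) for length {len(self)}")
        lab = self.labels[start:stop] if self.labels is not None else None
        return Polyline3D(self.points[start:stop], lab)


@dataclass
class ChainTrace:
    """Ordered Cα trace of one chain with author residue numbering."""

    chain_id: str
    residue_ids: np.ndarray  # strictly increasing ints
    coords: np.ndarray  # (n, 3) Å
    confidence: Optional[np.ndarray] = None  # pLDDT 0-100, one per residue

    def __post_init__(self):
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        if len(self.residue_ids) != len(self.coords):
            raise ValueError("residue_ids and coords must be parallel")
        if len(self.residue_ids) > 1 and not (np.diff(self.residue_ids) > 0).all():
            raise ValueError("residue_ids must be strictly increasing")
        if len(self.coords) > 1:
            same = (np.diff(self.coords, axis=0) == 0).all(axis=1)
            if same.any():
                raise ValueError("two consecutive Cα positions are identical")
        if self.confidence is not None:
            self.confidence = np.asarray(self.confidence, dtype=float)
            if len(self.confidence) != len(self.coords):
                raise ValueError("confidence must parallel coords")

    def __len__(self) -> int:
        return len(self.coords)


@dataclass
class StructureModel:
    """One model of a structure file: a set of Cα chain traces."""

    model_id: str
    chains: list[ChainTrace]
    source_format: str  # pdb | mmcif | synthetic

    def __post_init__(self):
        if not self.chains:
            raise EmptyModelError(f"model {self.model_id} has no chains")
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise ValueError("chain IDs must be unique within a model")

    def chain(self, chain_id: str) -> ChainTrace:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in model {self.model_id}")


def _detect_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = path.suffix.lower()
    if suffix in (".cif", ".mmcif"):
        return "mmcif"
    return "pdb"


def read_structure(path, format: Optional[str] = None) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel` of Cα traces.

    Only the first model is used.  Residues lacking a Cα atom are skipped
    (the gap is logged).  Altloc 'A' or blank only.  Confidence is filled
    from the B-factor column when every B-factor lies in [0, 100] (pLDDT
    convention); otherwise it is absent.
    """
    path = Path(path)
    fmt = _detect_format(path, format)
    try:
        if fmt == "mmcif":
            structure = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            structure = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError, SystemError) as exc:
        raise IOError(f"cannot read structure file {path}: {exc}") from exc
    structure.setup_entities()
    if len(structure) == 0:
        raise EmptyModelError(f"{path}: no models")
    model = structure[0]

    chains: list[ChainTrace] = []
    for chain in model:
        res_ids, coords, bfactors = [], [], []
        for residue in chain:
            ca = None
            for atom in residue:
                if atom.name == "CA" and atom.altloc in ("", "\x00", "A") and atom.element.name != "Ca":
                    ca = atom
                    break
            if ca is None:
                info = gemmi.find_tabulated_residue(residue.name)
                if info is not None and info.is_amino_acid():
                    logger.info(
                        "%s chain %s: residue %s %d lacks a Cα, gap recorded",
                        path.name, chain.name, residue.name, residue.seqid.num,
                    )
                continue
            res_ids.append(residue.seqid.num)
            coords.append([ca.pos.x, ca.pos.y, ca.pos.z])
            bfactors.append(ca.b_iso)
        if not res_ids:
            continue
        res_ids = np.asarray(res_ids)
        # author numbering can repeat across insertion codes; fall back to
        # file order in that case
        if len(res_ids) > 1 and not (np.diff(res_ids) > 0).all():
            logger.warning(
                "%s chain %s: residue numbering not strictly increasing, "
                "renumbering sequentially", path.name, chain.name,
            )
            res_ids = np.arange(1, len(res_ids) + 1)
        bf = np.asarray(bfactors)
        # pLDDT convention: all B-factors in [0, 100]; an all-zero column
        # is a placeholder (e.g. generated curves), not a confidence of 0
        confidence = bf if ((bf >= 0) & (bf <= 100)).all() and bf.any() else None
        chains.append(ChainTrace(chain.name, res_ids, np.asarray(coords), confidence))

    if not chains:
        raise EmptyModelError(f"{path}: no polymer chain with Cα atoms")
    return StructureModel(model_id=path.stem, chains=chains, source_format=fmt)


def chain_to_polyline(
    chain: ChainTrace,
    min_confidence: Optional[float] = None,
    force: bool = False,
) -> Polyline3D:
    """Convert a Cα trace to a polyline, optionally gated on mean pLDDT.

    The gate compares the chain's *mean* confidence to ``min_confidence``
    and raises :class:`LowConfidenceError` when it falls short, unless
    ``force`` is set.  A chain without confidence values passes with a
    warning (there is no basis to filter on).
    """
    if len(chain) == 0:
        raise ValueError("empty chain")
    if min_confidence is not None:
        if chain.confidence is None:
            warnings.warn(
                f"chain {chain.chain_id}: no confidence values, "
                "pLDDT gate not applied",
                stacklevel=2,
            )
        else:
            mean = float(np.mean(chain.confidence))
            if mean < min_confidence and not force:
                raise LowConfidenceError(chain.chain_id, mean, min_confidence)
    return Polyline3D(chain.coords.copy(), chain.residue_ids.copy())


def write_pseudo_pdb(polyline: Polyline3D, path) -> Path:
    """Write a polyline as a minimal PDB file of CA atoms (chain A, from 1).

    Coordinates survive a round trip through :func:`read_structure` to the
    PDB fixed-width precision of 10⁻³ Å.
    """
    if len(polyline) < MIN_POINTS:
        raise ValueError(f"polyline has {len(polyline)} points; minimum is {MIN_POINTS}")
    path = Path(path)
    lines = []
    for i, (x, y, z) in enumerate(polyline.points, start=1):
        if not (-999.999 < x < 9999.999 and -999.999 < y < 9999.999 and -999.999 < z < 9999.999):
            raise ValueError("coordinates exceed PDB fixed-width field range")
        lines.append(
            f"ATOM  {i % 100000:5d}  CA  ALA A{i % 10000:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("TER")
    lines.append("END")
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc
    return path
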