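"""Minimal structure handling: strict PDB ATOM ingestion and per-residue
solvent exposure (Shrake-Rupley SASA, with a neighbor-count fallback for
reduced representations and a default-exposed fallback for sequence-only
runs).

The reader is deliberately strict: a coordinate field that does not parse
raises with the offending line number rather than being coerced, because
downstream exposure values silently computed from a corrupt structure are
worse than a hard failure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
from Bio.SeqUtils import seq1

from .errors import DataError, PdbParseError
from ._tables import DEFAULT_VDW_RADIUS, MAX_SASA_TIEN, VDW_RADII

EXPOSURE_METHODS = ("shrake_rupley", "neighbor_count", "default_exposed")


@dataclass(frozen=True)
class Atom:
    chain_id: str
    res_index: int
    res_name: str  # three-letter code
    atom_name: str
    element: str
    x: float
    y: float
    z: float

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass(frozen=True)
class StructureModel:
    atoms: tuple[Atom, ...]
    # residue index -> 1-based ChainRecord position, per chain id;
    # identity mapping when omitted.
    chain_to_sequence_map: Optional[Mapping[str, Mapping[int, int]]] = None

    def __post_init__(self) -> None:
        for atom in self.atoms:
            if not all(np.isfinite([atom.x, atom.y, atom.z])):
                raise DataError(f"non-finite coordinates on atom {atom}")

    def coords(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.atoms])

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def residues(self, chain_id: str) -> list[tuple[int, str]]:
        """Ordered (res_index, res_name) pairs for one chain."""
        seen: dict[int, str] = {}
        for a in self.atoms:
            if a.chain_id == chain_id:
                seen.setdefault(a.res_index, a.res_name)
        return sorted(seen.items())

    def sequence_position(self, chain_id: str, res_index: int) -> int:
        if self.chain_to_sequence_map is None:
            return res_index
        return self.chain_to_sequence_map[chain_id][res_index]


@dataclass(frozen=True)
class ExposureProfile:
    """Per-residue exposure for one chain, indexed by sequence position."""

    chain: str
    relative: tuple[float, ...]  # clamped to [0, 1]
    sasa: Optional[tuple[float, ...]] = None  # A^2, when SASA-derived
    method: str = "default_exposed"

    def __post_init__(self) -> None:
        if self.method not in EXPOSURE_METHODS:
            raise DataError(f"unknown exposure method {self.method!r}")
        if any(not 0.0 <= r <= 1.0 for r in self.relative):
            raise DataError("relative exposure outside [0, 1]")


def default_exposure(length: int, chain: str = "unknown") -> ExposureProfile:
    """Sequence-only fallback: every residue treated as fully exposed
    (conservative over-reporting for liability gating)."""
    return ExposureProfile(chain=chain, relative=(1.0,) * length, method="default_exposed")


def _infer_element(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        raise PdbParseError(f"cannot infer element from atom name {atom_name!r}")
    return stripped[0].upper()


def read_pdb(path: str | Path) -> StructureModel:
    """Parse ATOM/HETATM records from a PDB file.

    Keeps altLoc blank or 'A'; skips waters (HOH/WAT); infers the element
    from the atom name when the element column is blank. Any ATOM line
    whose fixed columns fail to parse raises PdbParseError with the line
    number.
    """
    atoms: list[Atom] = []
    path = Path(path)
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        record = line[0:6].strip()
        if record not in ("ATOM", "HETATM"):
            continue
        try:
            atom_name = line[12:16].strip()
            altloc = line[16]
            res_name = line[17:20].strip()
            chain_id = line[21].strip() or "A"
            res_index = int(line[22:26])
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except (ValueError, IndexError) as exc:
            raise PdbParseError(f"{path}:{lineno}: unparseable ATOM record") from exc
        if altloc not in (" ", "A"):
            continue
        if res_name in ("HOH", "WAT"):
            continue
        element = line[76:78].strip() if len(line) >= 78 else ""
        if not element:
            element = _infer_element(atom_name)
        atoms.append(Atom(chain_id, res_index, res_name, atom_name, element.upper(), x, y, z))
    return StructureModel(atoms=tuple(atoms))


def write_pdb(model: StructureModel, path: str | Path) -> None:
    lines = []
    for i, a in enumerate(model.atoms, start=1):
        name = a.atom_name if len(a.atom_name) == 4 else f" {a.atom_name:<3s}"
        lines.append(
            f"ATOM  {i:5d} {name:<4s} {a.res_name:<3s} {a.chain_id}{a.res_index:4d}    "
            f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}  1.00  0.00          {a.element:>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere points by the golden-spiral construction."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def sasa(model: StructureModel, probe_radius: float = 1.4, n_points: int = 960) -> np.ndarray:
    """Shrake-Rupley per-atom solvent-accessible surface area (A^2).

    For each atom, sphere points at radius r_vdw + probe are tested
    against every other atom's expanded sphere (points on or inside the
    sphere count as occluded, so coincident identical atoms fully occlude
    each other); the accessible fraction scales the expanded-sphere area.
    """
    if not model.atoms:
        raise DataError("cannot compute SASA of an empty structure")
    coords = model.coords()
    radii = np.array(
        [VDW_RADII.get(a.element, DEFAULT_VDW_RADIUS) + probe_radius for a in model.atoms]
    )
    unit = _sphere_points(n_points)
    n = len(model.atoms)
    out = np.zeros(n)
    for i in range(n):
        pts = coords[i] + radii[i] * unit
        accessible = np.ones(n_points, dtype=bool)
        # neighbours whose expanded sphere can reach atom i's shell
        d = np.linalg.norm(coords - coords[i], axis=1)
        near = np.nonzero((d < radii + radii[i]) & (np.arange(n) != i))[0]
        for j in near:
            dist2 = np.sum((pts - coords[j]) ** 2, axis=1)
            # tiny relative slack so points lying exactly on a neighbour's
            # surface count as occluded despite rounding
            accessible &= dist2 > radii[j] ** 2 * (1.0 + 1e-9)
        out[i] = accessible.mean() * 4.0 * np.pi * radii[i] ** 2
    return out


def residue_sasa(model: StructureModel, atom_sasa: np.ndarray) -> dict[tuple[str, int], float]:
    """Sum atom SASA into per-residue totals keyed by (chain, res_index)."""
    totals: dict[tuple[str, int], float] = {}
    for atom, value in zip(model.atoms, atom_sasa):
        key = (atom.chain_id, atom.res_index)
        totals[key] = totals.get(key, 0.0) + float(value)
    return totals


def relative_exposure(
    model: StructureModel,
    res_sasa: Mapping[tuple[str, int], float],
    reference: Mapping[str, float] = MAX_SASA_TIEN,
) -> dict[str, ExposureProfile]:
    """Normalise per-residue SASA by per-type maxima, clamped to [0, 1].

    Returns one profile per chain id, indexed by mapped sequence position.
    """
    profiles: dict[str, ExposureProfile] = {}
    for chain_id in model.chains():
        entries = []
        for res_index, res_name in model.residues(chain_id):
            one = seq1(res_name.capitalize())
            if one not in reference:
                raise DataError(f"no reference SASA for residue {res_name!r}")
            value = res_sasa.get((chain_id, res_index), 0.0)
            rel = min(1.0, max(0.0, value / reference[one]))
            entries.append((model.sequence_position(chain_id, res_index), value, rel))
        entries.sort()
        profiles[chain_id] = ExposureProfile(
            chain=chain_id,
            relative=tuple(e[2] for e in entries),
            sasa=tuple(e[1] for e in entries),
            method="shrake_rupley",
        )
    return profiles


def compute_exposure(
    model: StructureModel, probe_radius: float = 1.4, n_points: int = 960
) -> dict[str, ExposureProfile]:
    """Convenience: Shrake-Rupley SASA -> relative exposure per chain."""
    atom_areas = sasa(model, probe_radius=probe_radius, n_points=n_points)
    return relative_exposure(model, residue_sasa(model, atom_areas))


def _representative_atoms(model: StructureModel) -> list[tuple[str, int, np.ndarray]]:
    """Cbeta per residue (Calpha for Gly / Cbeta-less residues)."""
    by_res: dict[tuple[str, int], dict[str, np.ndarray]] = {}
    for a in model.atoms:
        by_res.setdefault((a.chain_id, a.res_index), {})[a.atom_name] = a.xyz
    out = []
    for (chain_id, res_index), atoms in by_res.items():
        if "CB" in atoms:
            out.append((chain_id, res_index, atoms["CB"]))
        elif "CA" in atoms:
            out.append((chain_id, res_index, atoms["CA"]))
        else:
            warnings.warn(
                f"residue {chain_id}{res_index} lacks CB/CA; skipped in neighbor exposure"
            )
    return out


def neighbor_exposure(
    model: StructureModel, radius: float = 10.0, n_max: int = 20
) -> dict[str, ExposureProfile]:
    """Packing-based exposure surrogate: exposure = 1 - n_neighbors/n_max.

    Neighbors are representative atoms (Cbeta, Calpha for Gly) within
    ``radius``; counts at or above ``n_max`` give exposure 0. Residues
    without a representative atom default to fully exposed (warned).
    """
    reps = _representative_atoms(model)
    coords = np.array([r[2] for r in reps]) if reps else np.zeros((0, 3))
    values: dict[tuple[str, int], float] = {}
    for i, (chain_id, res_index, xyz) in enumerate(reps):
        d = np.linalg.norm(coords - xyz, axis=1)
        n_neighbors = int(np.sum(d <= radius)) - 1  # exclude self
        values[(chain_id, res_index)] = max(0.0, 1.0 - n_neighbors / n_max)
    profiles: dict[str, ExposureProfile] = {}
    for chain_id in model.chains():
        entries = []
        for res_index, _ in model.residues(chain_id):
            rel = values.get((chain_id, res_index), 1.0)
            entries.append((model.sequence_position(chain_id, res_index), rel))
        entries.sort()
        profiles[chain_id] = ExposureProfile(
            chain=chain_id,
            relative=tuple(e[1] for e in entries),
            method="neighbor_count",
        )
    return profiles
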