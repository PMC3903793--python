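"""Solvent-accessible surface area (Shrake-Rupley) and derived filters.

The sphere sampling uses a deterministic golden-section spiral so results
are reproducible without a seed and converge to analytic values as the
point count grows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from piface.structure_io import Residue

#: Reference maximum ASA per residue type (Å², Ala-X-Ala style tripeptide
#: maxima, Tien et al. 2013 theoretical values). Swappable.
MAX_ASA: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

DEFAULT_PROBE_RADIUS = 1.4
DEFAULT_SPHERE_POINTS = 960


@dataclass
class AsaResult:
    """Per-atom and (optionally) per-residue accessible surface areas."""

    per_atom_asa: np.ndarray
    total_asa: float
    per_residue_asa: dict[tuple[str, int, str], float] | None = None


def sphere_points(n: int) -> np.ndarray:
    """``n`` points on the unit sphere from a golden-section spiral."""
    if n < 2:
        raise ValueError("need at least 2 sphere points")
    k = np.arange(n, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = 2.0 * np.pi * k / phi
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def compute_asa(
    atoms: Sequence,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_SPHERE_POINTS,
    residue_keys: Sequence[tuple[str, int, str]] | None = None,
) -> AsaResult:
    """Shrake-Rupley ASA of a set of atoms.

    ``atoms`` is a sequence of objects with ``coord`` and ``vdw_radius``
    (:class:`piface.structure_io.Atom`). If ``residue_keys`` (parallel to
    ``atoms``) is given, per-residue sums are returned as well.

    Coincident atoms of equal radius mutually occlude each other: a test
    point lying exactly on a neighbour's solvent-extended sphere counts
    as buried.
    """
    if len(atoms) == 0:
        raise ValueError("compute_asa requires at least one atom")
    if probe_radius <= 0:
        raise ValueError("probe_radius must be positive")
    coords = np.array([a.coord for a in atoms], dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite atom coordinates")
    radii = np.array([a.vdw_radius for a in atoms], dtype=float) + probe_radius

    unit = sphere_points(n_sphere_points)
    tree = cKDTree(coords)
    max_r = radii.max()
    per_atom = np.zeros(len(atoms))
    eps = 1e-10
    for i in range(len(atoms)):
        ri = radii[i]
        neighbours = [j for j in tree.query_ball_point(coords[i], ri + max_r) if j != i]
        pts = coords[i] + ri * unit
        if neighbours:
            nb = np.array(neighbours)
            # keep only true overlaps
            d = np.linalg.norm(coords[nb] - coords[i], axis=1)
            nb = nb[d < ri + radii[nb]]
            accessible = np.ones(len(pts), dtype=bool)
            for j in nb:
                dj = np.linalg.norm(pts - coords[j], axis=1)
                accessible &= dj > radii[j] + eps  # points on the neighbour surface count as buried
            frac = accessible.mean()
        else:
            frac = 1.0
        per_atom[i] = frac * 4.0 * np.pi * ri * ri

    per_residue = None
    if residue_keys is not None:
        if len(residue_keys) != len(atoms):
            raise ValueError("residue_keys must parallel atoms")
        per_residue = {}
        for key, area in zip(residue_keys, per_atom):
            per_residue[key] = per_residue.get(key, 0.0) + float(area)
    return AsaResult(per_atom_asa=per_atom, total_asa=float(per_atom.sum()), per_residue_asa=per_residue)


def _flatten(residues: Iterable[Residue]):
    atoms, keys = [], []
    for res in residues:
        for a in res.atoms:
            atoms.append(a)
            keys.append(res.key)
    return atoms, keys


def compute_residue_asa(
    residues: Iterable[Residue],
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_SPHERE_POINTS,
) -> AsaResult:
    """ASA of a residue collection, with per-residue sums."""
    atoms, keys = _flatten(residues)
    return compute_asa(atoms, probe_radius, n_sphere_points, residue_keys=keys)


def buried_area(
    chain_a: Sequence[Residue],
    chain_b: Sequence[Residue],
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_SPHERE_POINTS,
) -> float:
    """Interface area: ASA(a) + ASA(b) − ASA(a∪b), in Å².

    Computed with the pair isolated from any other chains; symmetric in
    its arguments by construction.
    """
    if not chain_a or not chain_b:
        raise ValueError("both chains must be non-empty")
    a, b = list(chain_a), list(chain_b)
    if b and a and b[0].key < a[0].key:
        a, b = b, a  # canonical order => exact argument symmetry
    asa_a = compute_residue_asa(a, probe_radius, n_sphere_points).total_asa
    asa_b = compute_residue_asa(b, probe_radius, n_sphere_points).total_asa
    asa_ab = compute_residue_asa(a + b, probe_radius, n_sphere_points).total_asa
    return asa_a + asa_b - asa_ab


def candidate_prefilter(
    chain_a: Sequence[Residue],
    chain_b: Sequence[Residue],
    threshold: float = 1.0,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_SPHERE_POINTS,
) -> bool:
    """True iff the pair buries more than ``threshold`` Å² (default 1 Å²)."""
    return buried_area(chain_a, chain_b, probe_radius, n_sphere_points) > threshold


def relative_asa(
    residue_asa: float,
    aa_type: str,
    table: Mapping[str, float] | None = None,
) -> float:
    """Residue ASA as percent of its reference maximum exposure.

    May exceed 100 for extended termini.
    """
    table = MAX_ASA if table is None else table
    if aa_type not in table:
        raise KeyError(f"no reference ASA for residue type {aa_type!r}")
    return 100.0 * residue_asa / table[aa_type]
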