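"""Coordinate I/O, chain/residue filtering and chain-pair enumeration.

Parsing is delegated to Bio.PDB; the parsed entities are converted into
plain dataclasses carrying van der Waals radii so that every downstream
rule (contacts, SASA, alignment) operates on one in-memory model.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

logger = logging.getLogger(__name__)

# Bondi-style van der Waals radii (Å), configurable per call.
DEFAULT_VDW_RADII: dict[str, float] = {
    "H": 1.20, "D": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
    "ZN": 1.39, "FE": 1.40, "MG": 1.73, "CA": 1.74, "MN": 1.73, "CU": 1.40,
    "NA": 2.27, "K": 2.75, "NI": 1.63, "CO": 1.40, "CD": 1.58, "HG": 1.55,
}
DEFAULT_RADIUS = 1.70

STANDARD_AA = frozenset({
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
})

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}

NUCLEIC_RESNAMES = frozenset({
    "A", "C", "G", "U", "I", "N",
    "DA", "DC", "DG", "DT", "DU", "DI", "DN",
})

WATER_RESNAMES = frozenset({"HOH", "DOD", "WAT"})


class StructureParseError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


@dataclass(frozen=True)
class Atom:
    """A heavy atom with coordinates and a van der Waals radius."""

    name: str
    element: str
    coord: tuple[float, float, float]
    vdw_radius: float

    def __post_init__(self) -> None:
        if self.vdw_radius <= 0:
            raise ValueError(f"vdw_radius must be positive, got {self.vdw_radius}")
        if not all(np.isfinite(self.coord)):
            raise ValueError(f"non-finite coordinate for atom {self.name}: {self.coord}")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coord, dtype=float)


@dataclass(frozen=True)
class Residue:
    """One residue: identity triple plus its atoms."""

    chain_id: str
    seq_id: int
    icode: str
    aa_type: str
    atoms: tuple[Atom, ...]

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_id, self.icode)

    @property
    def ca_coord(self) -> np.ndarray | None:
        for a in self.atoms:
            if a.name == "CA":
                return a.xyz
        return None

    def atom_coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)

    def atom_radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)


@dataclass
class Structure:
    """A coordinate model: pdb_id plus per-model chain → residue lists.

    ``chains`` exposes the residues of ``model_index``; all parsed models
    are retained until :func:`filter_structure` drops everything but the
    first.
    """

    pdb_id: str
    models: dict[int, dict[str, list[Residue]]] = field(default_factory=dict)
    model_index: int = 0
    filtered: bool = False

    @property
    def chains(self) -> dict[str, list[Residue]]:
        if not self.models:
            return {}
        return self.models[self.model_index]

    @property
    def chain_ids(self) -> list[str]:
        return sorted(self.chains)

    def n_residues(self) -> int:
        return sum(len(r) for r in self.chains.values())

    def chain_sequence(self, chain_id: str) -> str:
        return "".join(THREE_TO_ONE.get(r.aa_type, "X") for r in self.chains[chain_id])

    def all_residues(self) -> list[Residue]:
        return [r for cid in self.chain_ids for r in self.chains[cid]]


def _pick_altloc(bio_atom):
    """Highest-occupancy conformer; ties broken by altloc letter order."""
    if not bio_atom.is_disordered():
        return bio_atom
    children = sorted(
        bio_atom.disordered_get_list(),
        key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()),
    )
    return children[0]


def _element_radius(element: str, name: str, radii: Mapping[str, float], default: float) -> float:
    el = element.strip().upper()
    if not el:
        # Infer from the atom name's first alphabetic character.
        el = next((ch for ch in name if ch.isalpha()), "C").upper()
    if el in radii:
        return radii[el]
    logger.warning("unknown element %r (atom %s): using default radius %.2f", element, name, default)
    return default


def load_structure(
    path: str | Path,
    format: str = "pdb",
    radii: Mapping[str, float] | None = None,
    default_radius: float = DEFAULT_RADIUS,
    include_hydrogens: bool = False,
) -> Structure:
    """Parse a PDB or mmCIF file into a :class:`Structure` (no filtering).

    Hydrogens are dropped by default; each atom is annotated with a van
    der Waals radius from ``radii`` (unknown elements fall back to
    ``default_radius`` with a logged warning).
    """
    from Bio.PDB import MMCIFParser, PDBParser

    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"file not found: {path}")
    if format not in ("pdb", "mmcif"):
        raise ValueError(f"unknown format {format!r}; expected 'pdb' or 'mmcif'")
    radii = DEFAULT_VDW_RADII if radii is None else radii

    parser = PDBParser(QUIET=True) if format == "pdb" else MMCIFParser(QUIET=True)
    pdb_id = path.stem[:4].upper()
    try:
        bio_structure = parser.get_structure(pdb_id, str(path))
    except Exception as exc:  # Bio.PDB raises assorted exception types
        raise StructureParseError(f"cannot parse {path} as {format}: {exc}") from exc

    models: dict[int, dict[str, list[Residue]]] = {}
    for mi, bio_model in enumerate(bio_structure):
        chains: dict[str, list[Residue]] = {}
        for bio_chain in bio_model:
            residues: list[Residue] = []
            for bio_res in bio_chain:
                atoms = []
                for bio_atom in bio_res:
                    a = _pick_altloc(bio_atom)
                    element = (a.element or "").strip().upper()
                    if not include_hydrogens and element in ("H", "D"):
                        continue
                    coord = a.get_coord()
                    if not np.all(np.isfinite(coord)):
                        raise StructureParseError(
                            f"non-finite coordinates for atom {a.get_full_id()} in {path}"
                        )
                    atoms.append(Atom(
                        name=a.get_name(),
                        element=element,
                        coord=(float(coord[0]), float(coord[1]), float(coord[2])),
                        vdw_radius=_element_radius(element, a.get_name(), radii, default_radius),
                    ))
                if not atoms:
                    continue
                hetfield, seq_id, icode = bio_res.get_id()
                residues.append(Residue(
                    chain_id=bio_chain.get_id(),
                    seq_id=int(seq_id),
                    icode=icode.strip(),
                    aa_type=bio_res.get_resname().strip(),
                    atoms=tuple(atoms),
                ))
            if residues:
                chains[bio_chain.get_id()] = residues
        if chains:
            models[mi] = chains
    first = min(models) if models else 0
    return Structure(pdb_id=pdb_id, models=models, model_index=first)


def _is_water(res: Residue) -> bool:
    return res.aa_type in WATER_RESNAMES


def _is_nucleic(res: Residue) -> bool:
    return res.aa_type in NUCLEIC_RESNAMES and res.ca_coord is None


def _has_ca(res: Residue) -> bool:
    return res.ca_coord is not None


def filter_structure(s: Structure) -> Structure:
    """Apply the chain/residue elimination rules.

    Keeps only the first model; drops waters; strips non-amino ligands
    (hetero residues without a CA atom); drops nucleic-acid chains and
    any chain containing an amino-acid-like residue outside the 20
    standard types (e.g. selenomethionine). Idempotent.
    """
    if not s.models:
        return Structure(pdb_id=s.pdb_id, models={}, model_index=0, filtered=True)
    first = min(s.models)
    chains: dict[str, list[Residue]] = {}
    for cid in sorted(s.models[first]):
        residues = [r for r in s.models[first][cid] if not _is_water(r)]
        if any(_is_nucleic(r) for r in residues):
            continue
        # Ligands: hetero residues with no alpha carbon.
        polymer = [r for r in residues if _has_ca(r)]
        if not polymer:
            continue
        if any(r.aa_type not in STANDARD_AA for r in polymer):
            continue  # nonstandard amino acid somewhere -> whole chain out
        chains[cid] = polymer
    return Structure(pdb_id=s.pdb_id, models={first: chains} if chains else {}, model_index=first, filtered=True)


def enumerate_chain_pairs(s: Structure) -> list[tuple[str, str]]:
    """All unordered chain pairs in deterministic lexicographic order."""
    return list(itertools.combinations(s.chain_ids, 2))


# ---------------------------------------------------------------------------
# PDB serialization (for filtered structures and interface files)

_PDB_ATOM = (
    "ATOM  {serial:>5d} {name:<4s}{altloc:1s}{resname:>3s} {chain:1s}"
    "{resseq:>4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
    "          {element:>2s}\n"
)


def _format_atom_name(name: str, element: str) -> str:
    # Columns 13-16: element right-justified in 13-14 for 1-letter elements.
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1 or (not element and len(name) <= 3):
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(residues: Iterable[Residue], path: str | Path, pdb_id: str = "XXXX") -> None:
    """Serialize residues (grouped by chain, input order) as PDB ATOM records."""
    path = Path(path)
    serial = 1
    lines = [f"HEADER    PIFACE INTERFACE/STRUCTURE FILE       {pdb_id:<4s}\n"]
    residues = list(residues)
    last_chain = None
    for res in residues:
        if last_chain is not None and res.chain_id != last_chain:
            lines.append("TER\n")
        last_chain = res.chain_id
        for atom in res.atoms:
            lines.append(_PDB_ATOM.format(
                serial=serial,
                name=_format_atom_name(atom.name, atom.element),
                altloc=" ",
                resname=res.aa_type,
                chain=res.chain_id,
                resseq=res.seq_id,
                icode=res.icode or " ",
                x=atom.coord[0], y=atom.coord[1], z=atom.coord[2],
                occ=1.0, b=0.0,
                element=atom.element[:2],
            ))
            serial += 1
    lines.append("TER\nEND\n")
    path.write_text("".join(lines))


def write_structure(s: Structure, path: str | Path) -> None:
    """Write the current model of a Structure as a PDB file."""
    write_pdb(s.all_residues(), path, pdb_id=s.pdb_id)
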