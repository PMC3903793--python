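"""Contact/nearby residue identification and interface construction.

Contact rule: two residues on different chains are in contact when any
pair of their heavy atoms is closer than the sum of the atoms' van der
Waals radii plus 0.5 Å. Nearby residues support the interface
architecture: non-contact residues whose alpha carbon lies within 6 Å of
a contact residue's alpha carbon on the same chain.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from piface.structure_io import Residue, Structure, write_pdb

logger = logging.getLogger(__name__)

CONTACT_SLACK = 0.5  # Å added to the vdW radius sum
NEARBY_CUTOFF = 6.0  # Å, CA-CA
MIN_CONTACTS_PER_SIDE = 5

ResKey = tuple[str, int, str]


@dataclass
class InterfaceSide:
    """One chain's share of an interface."""

    chain_id: str
    contact: list[Residue]
    nearby: list[Residue]

    @property
    def n_contact(self) -> int:
        return len(self.contact)

    @property
    def n_total(self) -> int:
        return len(self.contact) + len(self.nearby)

    def residues(self) -> list[Residue]:
        return list(self.contact) + list(self.nearby)

    def contact_keys(self) -> set[ResKey]:
        return {r.key for r in self.contact}


@dataclass
class Interface:
    """A named chain-pair interface: contact plus nearby residues per side."""

    name: str
    pdb_id: str
    side_a: InterfaceSide
    side_b: InterfaceSide

    @property
    def n_contact(self) -> int:
        """Contact residues summed over both sides (Table-1 convention)."""
        return self.side_a.n_contact + self.side_b.n_contact

    @property
    def n_total(self) -> int:
        return self.side_a.n_total + self.side_b.n_total

    def residues(self) -> list[Residue]:
        return self.side_a.residues() + self.side_b.residues()

    def ca_coords(self) -> tuple[list[ResKey], np.ndarray]:
        """Sorted (by residue key) CA coordinates of all interface residues."""
        pairs = sorted(
            ((r.key, r.ca_coord) for r in self.residues() if r.ca_coord is not None),
            key=lambda kv: kv[0],
        )
        keys = [k for k, _ in pairs]
        coords = np.array([c for _, c in pairs], dtype=float)
        return keys, coords

    def to_dict(self) -> dict:
        def side(s: InterfaceSide) -> dict:
            return {
                "chain": s.chain_id,
                "contact": [list(r.key) for r in s.contact],
                "nearby": [list(r.key) for r in s.nearby],
                "n_contact": s.n_contact,
                "n_total": s.n_total,
            }
        return {
            "name": self.name,
            "pdb_id": self.pdb_id,
            "side_a": side(self.side_a),
            "side_b": side(self.side_b),
            "n_contact": self.n_contact,
            "n_total": self.n_total,
        }


def contact_residues(
    chain_a: Sequence[Residue],
    chain_b: Sequence[Residue],
    slack: float = CONTACT_SLACK,
) -> set[tuple[ResKey, ResKey]]:
    """Residue pairs (one per chain) with any atoms closer than vdW sum + slack."""
    if not chain_a or not chain_b:
        return set()
    coords_a, radii_a, owner_a = _flatten(chain_a)
    coords_b, radii_b, owner_b = _flatten(chain_b)
    max_cut = radii_a.max() + radii_b.max() + slack
    tree_b = cKDTree(coords_b)
    pairs: set[tuple[ResKey, ResKey]] = set()
    hits = tree_b.query_ball_point(coords_a, max_cut)
    for ia, js in enumerate(hits):
        if not js:
            continue
        js = np.asarray(js)
        d = np.linalg.norm(coords_b[js] - coords_a[ia], axis=1)
        close = js[d < radii_a[ia] + radii_b[js] + slack]
        for jb in close:
            pairs.add((owner_a[ia], owner_b[jb]))
    return pairs


def _flatten(chain: Sequence[Residue]):
    coords, radii, owner = [], [], []
    for res in chain:
        for a in res.atoms:
            coords.append(a.coord)
            radii.append(a.vdw_radius)
            owner.append(res.key)
    return np.array(coords, dtype=float), np.array(radii, dtype=float), owner


def nearby_residues(
    chain: Sequence[Residue],
    contact_keys: set[ResKey],
    cutoff: float = NEARBY_CUTOFF,
) -> set[ResKey]:
    """Non-contact residues with a CA within ``cutoff`` of a contact CA."""
    if not contact_keys:
        return set()
    contact_cas = []
    for res in chain:
        if res.key in contact_keys:
            if res.ca_coord is None:
                logger.warning("contact residue %s lacks a CA atom; skipped for nearby search", res.key)
                continue
            contact_cas.append(res.ca_coord)
    if not contact_cas:
        return set()
    tree = cKDTree(np.array(contact_cas))
    out: set[ResKey] = set()
    for res in chain:
        if res.key in contact_keys:
            continue
        if res.ca_coord is None:
            logger.warning("residue %s lacks a CA atom; skipped for nearby search", res.key)
            continue
        d, _ = tree.query(res.ca_coord)
        if d < cutoff:
            out.add(res.key)
    return out


def extract_interface(
    s: Structure,
    a: str,
    b: str,
    min_contacts: int = MIN_CONTACTS_PER_SIDE,
    slack: float = CONTACT_SLACK,
    nearby_cutoff: float = NEARBY_CUTOFF,
    min_contacts_basis: str = "contact",
) -> Interface | None:
    """Build the interface of chains ``a`` and ``b``, or None if too small.

    Each side must have at least ``min_contacts`` contact residues
    (``min_contacts_basis="total"`` counts contact+nearby instead).
    """
    for cid in (a, b):
        if cid not in s.chains:
            raise KeyError(f"chain {cid!r} not in structure {s.pdb_id}")
    chain_a, chain_b = s.chains[a], s.chains[b]
    pairs = contact_residues(chain_a, chain_b, slack)
    keys_a = {p[0] for p in pairs}
    keys_b = {p[1] for p in pairs}
    near_a = nearby_residues(chain_a, keys_a, nearby_cutoff)
    near_b = nearby_residues(chain_b, keys_b, nearby_cutoff)

    side_a = InterfaceSide(
        chain_id=a,
        contact=[r for r in chain_a if r.key in keys_a],
        nearby=[r for r in chain_a if r.key in near_a],
    )
    side_b = InterfaceSide(
        chain_id=b,
        contact=[r for r in chain_b if r.key in keys_b],
        nearby=[r for r in chain_b if r.key in near_b],
    )
    if min_contacts_basis == "total":
        sizes = (side_a.n_total, side_b.n_total)
    else:
        sizes = (side_a.n_contact, side_b.n_contact)
    if min(sizes) < min_contacts:
        return None
    return Interface(name=f"{s.pdb_id}{a}{b}", pdb_id=s.pdb_id, side_a=side_a, side_b=side_b)


def write_interface(iface: Interface, path: str | Path, sidecar: bool = True) -> None:
    """Write interface residues as a PDB file plus a JSON sidecar."""
    if not iface.side_a.contact or not iface.side_b.contact:
        raise ValueError(f"interface {iface.name} has an empty contact side")
    path = Path(path)
    write_pdb(iface.residues(), path, pdb_id=iface.pdb_id)
    if sidecar:
        path.with_suffix(".json").write_text(json.dumps(iface.to_dict(), indent=1))


def read_interface(path: str | Path) -> Interface:
    """Reload an interface written by :func:`write_interface`.

    Requires the JSON sidecar next to the PDB file to recover the
    contact/nearby partition.
    """
    from piface.structure_io import load_structure

    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    s = load_structure(path, format="pdb")
    by_key: dict[ResKey, Residue] = {r.key: r for c in s.chains.values() for r in c}

    def side(d: dict) -> InterfaceSide:
        contact = [by_key[tuple(k)] for k in d["contact"]]
        nearby = [by_key[tuple(k)] for k in d["nearby"]]
        return InterfaceSide(chain_id=d["chain"], contact=contact, nearby=nearby)

    return Interface(
        name=meta["name"], pdb_id=meta["pdb_id"],
        side_a=side(meta["side_a"]), side_b=side(meta["side_b"]),
    )
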