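"""Desk-scale synthetic inputs: toy two-chain complexes with controllable
contact geometry, perturbed interface copies, and similarity networks with
planted community structure.

Toy chains are backbone-only (N, CA, C, O) alanine strands: enough for
every pipeline rule (vdW contacts, CA distances, SASA) while staying
tiny. All randomness flows from the spec's integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from piface.interface_network import InterfaceNetwork
from piface.structure_io import DEFAULT_VDW_RADII, Atom, Residue, Structure

CA_SPACING = 3.8        # Å between consecutive CA along the strand
SPLAY_OFFSET = 8.0      # Å added to the gap for residues outside the span
CONTACT_FEASIBLE_GAP = 2 * DEFAULT_VDW_RADII["C"] + 0.5  # CA-CA contact limit


class InfeasibleGeometryError(ValueError):
    """Requested contacts cannot form with the requested gap."""


@dataclass(frozen=True)
class ToyComplexSpec:
    n_residues_per_chain: int = 12
    inter_chain_gap: float = 3.6
    contact_span: tuple[int, int] = (2, 10)  # half-open residue index range
    perturbation_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.inter_chain_gap <= 0:
            raise InfeasibleGeometryError(f"gap must be positive, got {self.inter_chain_gap}")
        lo, hi = self.contact_span
        if not (0 <= lo <= hi <= self.n_residues_per_chain):
            raise InfeasibleGeometryError(
                f"contact_span {self.contact_span} outside chain of {self.n_residues_per_chain}"
            )


@dataclass(frozen=True)
class PlantedGraphSpec:
    block_sizes: tuple[int, ...] = (6, 6)
    p_in: float = 1.0
    p_out: float = 0.0
    w_in: tuple[float, float] = (0.85, 1.0)
    w_out: tuple[float, float] = (0.75, 0.80)
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.p_out < self.p_in <= 1.0) and not (self.p_in == self.p_out == 0):
            if not (0.0 <= self.p_out <= self.p_in <= 1.0):
                raise ValueError("need 0 <= p_out <= p_in <= 1")
        for lo, hi in (self.w_in, self.w_out):
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError("weight ranges must lie within [0, 1]")


def _backbone(x: float, y: float, z: float, flip: float) -> tuple[Atom, ...]:
    """Backbone atoms of one residue; ``flip`` mirrors offsets away from the partner."""
    r_c = DEFAULT_VDW_RADII["C"]
    r_n = DEFAULT_VDW_RADII["N"]
    r_o = DEFAULT_VDW_RADII["O"]

    def at(name, el, r, dx, dy, dz):
        return Atom(name=name, element=el, coord=(x + dx, y + flip * dy, z + dz), vdw_radius=r)

    return (
        at("N", "N", r_n, -1.2, 0.4, -0.3),
        at("CA", "C", r_c, 0.0, 0.0, 0.0),
        at("C", "C", r_c, 1.2, 0.4, 0.3),
        at("O", "O", r_o, 1.8, 1.3, 0.3),
    )


def make_toy_complex(spec: ToyComplexSpec, require_contacts: bool = False) -> Structure:
    """Two facing alanine strands; residues in ``contact_span`` satisfy the
    vdW+0.5 Å contact rule when the gap allows, others splay apart.

    ``require_contacts=True`` raises :class:`InfeasibleGeometryError` when
    the gap is too large for any contact to form across the span.
    """
    lo, hi = spec.contact_span
    span = range(lo, hi)
    if require_contacts:
        if not span:
            raise InfeasibleGeometryError("empty contact span but contacts required")
        if spec.inter_chain_gap >= CONTACT_FEASIBLE_GAP:
            raise InfeasibleGeometryError(
                f"gap {spec.inter_chain_gap} Å >= contact limit {CONTACT_FEASIBLE_GAP} Å"
            )
    rng = np.random.default_rng(spec.seed)

    def splay(i: int) -> float:
        # ramped splay: span residues flat, d=1 neighbours stay CA-near
        # (within the 6 Å nearby rule), farther residues fully apart
        if i in span:
            return 0.0
        if not span:
            return SPLAY_OFFSET
        d = lo - i if i < lo else i - hi + 1
        return SPLAY_OFFSET * min(1.0, d / 3.0)

    chains: dict[str, list[Residue]] = {}
    for chain_id, base_y, flip in (("A", 0.0, -1.0), ("B", spec.inter_chain_gap, 1.0)):
        residues = []
        for i in range(spec.n_residues_per_chain):
            y = base_y + flip * splay(i)
            atoms = _backbone(i * CA_SPACING, y, 0.0, flip)
            if spec.perturbation_sigma > 0:
                noisy = []
                for a in atoms:
                    d = rng.normal(0.0, spec.perturbation_sigma, 3)
                    noisy.append(Atom(a.name, a.element,
                                      (a.coord[0] + d[0], a.coord[1] + d[1], a.coord[2] + d[2]),
                                      a.vdw_radius))
                atoms = tuple(noisy)
            residues.append(Residue(chain_id=chain_id, seq_id=i + 1, icode="",
                                    aa_type="ALA", atoms=tuple(atoms)))
        chains[chain_id] = residues
    return Structure(pdb_id="TOY0", models={0: chains}, model_index=0, filtered=True)


def perturb_interface(
    s: Structure,
    sigma: float,
    fraction_displaced: float = 1.0,
    seed: int = 0,
    residue_keys: set | None = None,
) -> Structure:
    """Gaussian-displace a fraction of residues (their atoms) of a structure.

    ``residue_keys`` restricts the candidate set (e.g. to interface
    residues); sigma 0 returns an identical copy.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    candidates = sorted(
        r.key for c in s.chains.values() for r in c
        if residue_keys is None or r.key in residue_keys
    )
    n_pick = int(round(fraction_displaced * len(candidates)))
    order = rng.permutation(len(candidates))
    picked = {candidates[i] for i in order[:n_pick]}

    chains: dict[str, list[Residue]] = {}
    for cid in s.chain_ids:
        new_res = []
        for r in s.chains[cid]:
            if sigma > 0 and r.key in picked:
                atoms = tuple(
                    Atom(a.name, a.element, tuple(np.asarray(a.coord) + rng.normal(0, sigma, 3)), a.vdw_radius)
                    for a in r.atoms
                )
            else:
                atoms = r.atoms
            new_res.append(Residue(r.chain_id, r.seq_id, r.icode, r.aa_type, atoms))
        chains[cid] = new_res
    return Structure(pdb_id=s.pdb_id, models={s.model_index: chains},
                     model_index=s.model_index, filtered=s.filtered)


def rigid_transform(s: Structure, rotation: np.ndarray, translation: np.ndarray) -> Structure:
    """Apply a rigid-body transform to every atom (test helper)."""
    R = np.asarray(rotation, dtype=float)
    t = np.asarray(translation, dtype=float)
    chains: dict[str, list[Residue]] = {}
    for cid in s.chain_ids:
        chains[cid] = [
            Residue(r.chain_id, r.seq_id, r.icode, r.aa_type, tuple(
                Atom(a.name, a.element, tuple(R @ np.asarray(a.coord) + t), a.vdw_radius)
                for a in r.atoms
            ))
            for r in s.chains[cid]
        ]
    return Structure(pdb_id=s.pdb_id, models={s.model_index: chains},
                     model_index=s.model_index, filtered=s.filtered)


def bend_structure(s: Structure, amplitude: float, frequency: float) -> Structure:
    """Smooth non-rigid deformation: z += amplitude * sin(frequency * x).

    Distinct (amplitude, frequency) values produce families of interfaces
    that rigid alignment cannot superpose onto each other, while members
    of one family remain mutually alignable.
    """
    chains: dict[str, list[Residue]] = {}
    for cid in s.chain_ids:
        chains[cid] = [
            Residue(r.chain_id, r.seq_id, r.icode, r.aa_type, tuple(
                Atom(a.name, a.element,
                     (a.coord[0], a.coord[1],
                      a.coord[2] + amplitude * float(np.sin(frequency * a.coord[0]))),
                     a.vdw_radius)
                for a in r.atoms
            ))
            for r in s.chains[cid]
        ]
    return Structure(pdb_id=s.pdb_id, models={s.model_index: chains},
                     model_index=s.model_index, filtered=s.filtered)


def planted_partition_graph(spec: PlantedGraphSpec) -> tuple[InterfaceNetwork, dict[str, int]]:
    """Bernoulli block-model network plus the ground-truth block labels."""
    rng = np.random.default_rng(spec.seed)
    labels: dict[str, int] = {}
    node_id = 0
    for bi, size in enumerate(spec.block_sizes):
        for _ in range(size):
            labels[f"v{node_id:03d}"] = bi
            node_id += 1
    names = sorted(labels)
    g = nx.Graph()
    g.add_nodes_from((n, {"members": (n,)}) for n in names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            same = labels[a] == labels[b]
            p = spec.p_in if same else spec.p_out
            lo, hi = spec.w_in if same else spec.w_out
            if rng.random() < p:
                g.add_edge(a, b, weight=float(lo + (hi - lo) * rng.random()))
    return InterfaceNetwork(graph=g), labels
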