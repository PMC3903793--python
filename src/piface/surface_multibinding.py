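"""Surface-residue extraction by RASA cutoff and multi-interface binding
detection for 100%-identical protein pairs.

Pair labels follow the "<seqclusterA>_<seqclusterB>" convention with the
smaller cluster id first, so (A,B) and (B,A) label identically. A pair
binds through multiple interface architectures when its interfaces span
more than one structural cluster; within such a profile, interface pairs
whose contact footprints on the common monomer overlap by at least half
of the smaller footprint share a binding site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from piface.interface_extract import Interface
from piface.sasa import MAX_ASA, AsaResult, relative_asa
from piface.structure_io import Structure

DEFAULT_RASA_CUTOFF = 40.0
JONES_THORNTON_CUTOFF = 5.0
SHARED_SITE_OVERLAP = 0.5


@dataclass
class SurfaceSet:
    """Residues whose relative exposure exceeds the cutoff."""

    residues: dict[tuple[str, int, str], float]  # key -> rasa percent
    cutoff: float

    def __contains__(self, key) -> bool:
        return key in self.residues

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class PairBindingProfile:
    pair_label: str
    interfaces: list[str]
    structural_clusters: set[int]
    site_classes: dict[tuple[str, str], str] = field(default_factory=dict)
    sites: list[set[str]] = field(default_factory=list)

    @property
    def multi_interface(self) -> bool:
        return len(self.structural_clusters) > 1


def surface_residues(
    s: Structure,
    asa: AsaResult,
    cutoff: float = DEFAULT_RASA_CUTOFF,
    table: Mapping[str, float] | None = None,
) -> SurfaceSet:
    """Residues of the (monomer-computed) ASA result with RASA > cutoff."""
    if asa.per_residue_asa is None:
        raise ValueError("AsaResult lacks per-residue areas")
    table = MAX_ASA if table is None else table
    aa_by_key = {r.key: r.aa_type for c in s.chains.values() for r in c}
    out = {}
    for key, area in asa.per_residue_asa.items():
        rasa = relative_asa(area, aa_by_key[key], table)
        if rasa > cutoff:
            out[key] = rasa
    return SurfaceSet(residues=out, cutoff=cutoff)


def rasa_statistics(
    interface_rasa: Sequence[tuple[Interface, Mapping[tuple[str, int, str], float]]],
) -> tuple[float, float, float, float]:
    """Mean/SD across interfaces of per-interface average contact and
    nearby RASA.

    ``interface_rasa`` pairs each interface with a per-residue RASA map
    (monomer-based, keyed by residue key). Returns (contact_mean,
    contact_sd, nearby_mean, nearby_sd); population SD.
    """
    if not interface_rasa:
        raise ValueError("no interfaces")

    def per_iface_mean(iface, rasa_map, which) -> float | None:
        residues = [r for side in (iface.side_a, iface.side_b) for r in getattr(side, which)]
        vals = [rasa_map[r.key] for r in residues if r.key in rasa_map]
        return sum(vals) / len(vals) if vals else None

    contact_means = [m for iface, rm in interface_rasa if (m := per_iface_mean(iface, rm, "contact")) is not None]
    nearby_means = [m for iface, rm in interface_rasa if (m := per_iface_mean(iface, rm, "nearby")) is not None]

    def mean_sd(vals):
        if not vals:
            return (float("nan"), float("nan"))
        mu = sum(vals) / len(vals)
        var = sum((v - mu) ** 2 for v in vals) / len(vals)
        return (mu, math.sqrt(var))

    cm, cs = mean_sd(contact_means)
    nm, ns = mean_sd(nearby_means)
    return (cm, cs, nm, ns)


def sequence_identity_clusters(chains: Sequence[tuple[str, str]]) -> dict[str, int]:
    """Group chain ids by exact sequence identity; first-seen cluster ids."""
    clusters: dict[str, int] = {}
    by_seq: dict[str, int] = {}
    for chain_id, seq in chains:
        if not seq:
            raise ValueError(f"empty sequence for chain {chain_id!r}")
        if seq not in by_seq:
            by_seq[seq] = len(by_seq)
        clusters[chain_id] = by_seq[seq]
    return clusters


def _chain_key(pdb_id: str, chain_id: str) -> str:
    return f"{pdb_id}{chain_id}"


def pair_label(c1: int, c2: int) -> str:
    a, b = sorted((c1, c2))
    return f"{a}_{b}"


def detect_multi_interface_pairs(
    interfaces: Sequence[Interface],
    seq_clusters: Mapping[str, int],
    structural_clusters: Mapping[str, int],
) -> list[PairBindingProfile]:
    """Group interfaces by monomer-pair label; flag multi-cluster pairs.

    ``seq_clusters`` maps "<pdb_id><chain_id>" to a sequence cluster id;
    ``structural_clusters`` maps interface names to cluster ids.
    """
    by_label: dict[str, list[Interface]] = {}
    for iface in interfaces:
        c1 = seq_clusters[_chain_key(iface.pdb_id, iface.side_a.chain_id)]
        c2 = seq_clusters[_chain_key(iface.pdb_id, iface.side_b.chain_id)]
        by_label.setdefault(pair_label(c1, c2), []).append(iface)
    profiles = []
    for label in sorted(by_label):
        ifaces = sorted(by_label[label], key=lambda i: i.name)
        profiles.append(PairBindingProfile(
            pair_label=label,
            interfaces=[i.name for i in ifaces],
            structural_clusters={structural_clusters[i.name] for i in ifaces},
        ))
    return profiles


def _contact_positions(iface: Interface, side: str, chain_index: Mapping) -> set[int]:
    """Contact residues of one side as positions in their chain's residue list."""
    s = iface.side_a if side == "a" else iface.side_b
    idx = chain_index[_chain_key(iface.pdb_id, s.chain_id)]
    return {idx[r.key] for r in s.contact if r.key in idx}


def classify_binding_sites(
    profile: PairBindingProfile,
    interfaces: Mapping[str, Interface],
    seq_clusters: Mapping[str, int],
    chain_residue_index: Mapping[str, Mapping],
    overlap_threshold: float = SHARED_SITE_OVERLAP,
) -> PairBindingProfile:
    """Classify interface pairs of a profile as shared- or distinct-site.

    For every pair of interfaces, contact footprints on a common monomer
    (same sequence cluster) are compared as sequence-position sets;
    overlap = |intersection| / min(sizes). Homodimeric profiles test both
    side assignments and keep the best. Binding sites are the connected
    components of the shared-site relation. ``chain_residue_index`` maps
    "<pdb_id><chain_id>" to {residue key -> position in chain}.
    """
    names = profile.interfaces
    side_cluster = {}
    for name in names:
        iface = interfaces[name]
        side_cluster[name] = {
            "a": seq_clusters[_chain_key(iface.pdb_id, iface.side_a.chain_id)],
            "b": seq_clusters[_chain_key(iface.pdb_id, iface.side_b.chain_id)],
        }
    shared_edges = []
    site_classes = {}
    for i, n1 in enumerate(names):
        for n2 in names[i + 1:]:
            overlaps = []
            for s1 in ("a", "b"):
                for s2 in ("a", "b"):
                    if side_cluster[n1][s1] != side_cluster[n2][s2]:
                        continue
                    p1 = _contact_positions(interfaces[n1], s1, chain_residue_index)
                    p2 = _contact_positions(interfaces[n2], s2, chain_residue_index)
                    if not p1 or not p2:
                        continue
                    overlaps.append(len(p1 & p2) / min(len(p1), len(p2)))
            if not overlaps:
                raise ValueError(f"interfaces {n1} and {n2} share no common monomer")
            cls = "shared" if max(overlaps) >= overlap_threshold else "distinct"
            site_classes[(n1, n2)] = cls
            if cls == "shared":
                shared_edges.append((n1, n2))

    # connected components of the shared relation = binding sites
    import networkx as nx
    g = nx.Graph()
    g.add_nodes_from(names)
    g.add_edges_from(shared_edges)
    sites = sorted((set(c) for c in nx.connected_components(g)), key=lambda c: sorted(c)[0])

    profile.site_classes = site_classes
    profile.sites = sites
    return profile


def chain_residue_index(structures: Sequence[Structure]) -> dict[str, dict]:
    """Build the "<pdb_id><chain_id>" -> {residue key -> position} mapping."""
    out: dict[str, dict] = {}
    for s in structures:
        for cid, residues in s.chains.items():
            out[_chain_key(s.pdb_id, cid)] = {r.key: i for i, r in enumerate(residues)}
    return out
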