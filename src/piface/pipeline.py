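"""End-to-end orchestration: extract -> align -> cluster -> evaluate ->
surface/multibinding products, from a single configuration.

Every stage persists its output under the run directory so any stage can
be re-entered from its predecessor's files; ordering is deterministic
(sorted interface names) throughout.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from piface import evaluation, interface_extract, sasa, structural_align, structure_io, surface_multibinding
from piface.interface_network import build_network, cluster_interfaces

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    inputs: list[str] = field(default_factory=list)
    probe_radius: float = 1.4
    n_sphere_points: int = 960
    contact_slack: float = 0.5
    nearby_cutoff: float = 6.0
    min_contacts: int = 5
    asa_prefilter: float = 1.0
    rmsd_threshold: float = 3.0
    contact_size_factor: float = 1.25
    total_size_factor: float = 1.50
    edge_threshold: float = 0.75
    grouping_steps: tuple[float, ...] = (0.80, 0.85, 0.90, 0.95, 1.00)
    cc_stop: float = 1.0
    merge_mode: str = "max"
    min_cluster_size: int = 5
    rasa_cutoff: float = 40.0
    seed: int = 0

    def __post_init__(self):
        for name in ("probe_radius", "contact_slack", "nearby_cutoff", "asa_prefilter",
                     "rmsd_threshold", "edge_threshold", "rasa_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Flat key=value file; 'inputs' is comma-separated, steps likewise."""
        kwargs: dict = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key == "inputs":
                kwargs[key] = [v for v in value.split(",") if v]
            elif key == "grouping_steps":
                kwargs[key] = tuple(float(v) for v in value.split(",") if v)
            elif key in ("n_sphere_points", "min_contacts", "min_cluster_size", "seed"):
                kwargs[key] = int(value)
            elif key == "merge_mode":
                kwargs[key] = value
            else:
                kwargs[key] = float(value)
        return cls(**kwargs)


class StageError(RuntimeError):
    def __init__(self, stage: str, item: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on {item!r}: {cause}")
        self.stage = stage
        self.item = item


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> Path:
    """Execute all stages; returns the run directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    iface_dir = out / "interfaces"
    iface_dir.mkdir(exist_ok=True)

    # --- stage 1: load + filter ------------------------------------------
    structures = []
    for path in sorted(cfg.inputs):
        try:
            fmt = "mmcif" if str(path).endswith((".cif", ".mmcif")) else "pdb"
            s = structure_io.filter_structure(structure_io.load_structure(path, format=fmt))
        except Exception as exc:
            raise StageError("load", str(path), exc) from exc
        if s.chains:
            structures.append(s)
        else:
            logger.warning("no protein chains survive filtering in %s", path)
    if not cfg.inputs:
        logger.warning("empty input list; producing empty outputs")

    # --- stage 2: candidate pairs + interface extraction -----------------
    interfaces = []
    counts = {"pairs_enumerated": 0, "pairs_past_asa_filter": 0, "interfaces": 0}
    for s in structures:
        for a, b in structure_io.enumerate_chain_pairs(s):
            counts["pairs_enumerated"] += 1
            try:
                if not sasa.candidate_prefilter(
                        s.chains[a], s.chains[b], cfg.asa_prefilter,
                        cfg.probe_radius, cfg.n_sphere_points):
                    continue
                counts["pairs_past_asa_filter"] += 1
                iface = interface_extract.extract_interface(
                    s, a, b, cfg.min_contacts, cfg.contact_slack, cfg.nearby_cutoff)
            except Exception as exc:
                raise StageError("extract", f"{s.pdb_id}{a}{b}", exc) from exc
            if iface is not None:
                interfaces.append(iface)
                interface_extract.write_interface(iface, iface_dir / f"{iface.name}.pdb")
    counts["interfaces"] = len(interfaces)
    interfaces.sort(key=lambda i: i.name)

    # --- stage 3: pairwise similarity ------------------------------------
    try:
        table = structural_align.pairwise_similarity_matrix(
            interfaces, cfg.rmsd_threshold,
            contact_factor=cfg.contact_size_factor, total_factor=cfg.total_size_factor)
    except Exception as exc:
        raise StageError("align", "pairwise similarity", exc) from exc
    table.to_tsv(out / "similarity.tsv")

    # --- stage 4: network + clustering -----------------------------------
    net = build_network(table, cfg.edge_threshold)
    net.to_graphml(out / "network.graphml")
    clusters = cluster_interfaces(
        net, cfg.cc_stop, cfg.grouping_steps, cfg.merge_mode, cfg.min_cluster_size,
        sim_table=table)
    clusters.to_tsv(out / "clusters.tsv")

    # --- stage 5: silhouette ---------------------------------------------
    if clusters.n_clusters >= 2:
        sil = evaluation.silhouette(clusters, table)
        sil.to_tsv(out / "silhouette.tsv", clusters.labels())
        (out / "silhouette.json").write_text(json.dumps({"overall": sil.overall}))

    # --- stage 6: surface sets + multibinding ----------------------------
    surface_rows = ["pdb_id\tchain\tresnum\ticode\taa\tasa\trasa\tsurface\n"]
    rasa_maps: dict[str, dict] = {}
    for s in structures:
        for cid in s.chain_ids:
            res = s.chains[cid]
            asa_res = sasa.compute_residue_asa(res, cfg.probe_radius, cfg.n_sphere_points)
            aa_by_key = {r.key: r.aa_type for r in res}
            for key, area in sorted(asa_res.per_residue_asa.items()):
                rasa = sasa.relative_asa(area, aa_by_key[key], sasa.MAX_ASA)
                rasa_maps.setdefault(s.pdb_id, {})[key] = rasa
                surface_rows.append(
                    f"{s.pdb_id}\t{key[0]}\t{key[1]}\t{key[2] or '-'}\t{aa_by_key[key]}"
                    f"\t{area:.2f}\t{rasa:.2f}\t{int(rasa > cfg.rasa_cutoff)}\n")
    (out / "surface.tsv").write_text("".join(surface_rows))

    seq_clusters = surface_multibinding.sequence_identity_clusters([
        (f"{s.pdb_id}{cid}", s.chain_sequence(cid))
        for s in structures for cid in s.chain_ids
    ]) if structures else {}
    labels = clusters.labels()
    profiles = surface_multibinding.detect_multi_interface_pairs(interfaces, seq_clusters, labels) \
        if interfaces else []
    (out / "profiles.json").write_text(json.dumps([
        {
            "pair_label": p.pair_label,
            "interfaces": p.interfaces,
            "structural_clusters": sorted(p.structural_clusters),
            "multi_interface": p.multi_interface,
        } for p in profiles
    ], indent=1))

    manifest = {
        "config": dataclasses.asdict(cfg),
        "config_hash": cfg.config_hash(),
        "counts": counts,
        "n_clusters": clusters.n_clusters,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    logger.info("pipeline complete: %s", counts)
    return out
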