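"""Cluster validation: silhouette index, parameter-grid model selection,
and size distributions.

Dissimilarity is d(i,j) = 1 − similarity(i,j); pairs absent from the
similarity table (failed the size gate or fell below the edge threshold)
are treated as fully dissimilar (d = 1).
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

from piface.interface_network import ClusterSet, InterfaceNetwork, cluster_interfaces, param_tag
from piface.structural_align import SimilarityTable


@dataclass
class SilhouetteResult:
    per_interface_s: dict[str, float]
    a_values: dict[str, float]
    b_values: dict[str, float]
    overall: float

    def to_tsv(self, path, labels: dict[str, int]) -> None:
        lines = ["interface\tcluster\ta\tb\ts\n"]
        for name in sorted(self.per_interface_s):
            lines.append(
                f"{name}\t{labels[name]}\t{self.a_values[name]:.6f}"
                f"\t{self.b_values[name]:.6f}\t{self.per_interface_s[name]:.6f}\n"
            )
        Path(path).write_text("".join(lines))


def _dissim(sim_table: SimilarityTable, a: str, b: str) -> float:
    return 1.0 - sim_table.get(a, b, default=0.0)


def silhouette(clusters: ClusterSet, sim_table: SimilarityTable) -> SilhouetteResult:
    """Rousseeuw silhouette of a partition under 1−similarity dissimilarity.

    a(i): mean dissimilarity to own-cluster co-members; b(i): minimum
    over other clusters of the mean dissimilarity to that cluster;
    s(i) = (b−a)/max(a,b). Singleton clusters score 0. Raises on fewer
    than two clusters (b is undefined).
    """
    if clusters.n_clusters < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    member_lists = [sorted(c) for c in clusters.clusters]
    s_vals: dict[str, float] = {}
    a_vals: dict[str, float] = {}
    b_vals: dict[str, float] = {}
    for ci, members in enumerate(member_lists):
        for i in members:
            b = min(
                sum(_dissim(sim_table, i, j) for j in other) / len(other)
                for cj, other in enumerate(member_lists) if cj != ci
            )
            if len(members) == 1:
                a_vals[i] = 0.0
                b_vals[i] = b
                s_vals[i] = 0.0
                continue
            a = sum(_dissim(sim_table, i, j) for j in members if j != i) / (len(members) - 1)
            a_vals[i] = a
            b_vals[i] = b
            s_vals[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    overall = sum(s_vals.values()) / len(s_vals)
    return SilhouetteResult(per_interface_s=s_vals, a_values=a_vals, b_values=b_vals, overall=overall)


def parameter_grid_eval(
    net: InterfaceNetwork,
    sim_table: SimilarityTable,
    cc_stops: tuple[float, ...] = (1.0, 0.5),
    step_percents: tuple[int, ...] = (5,),
    merge_modes: tuple[str, ...] = ("max", "min"),
    min_size: int = 5,
) -> list[dict]:
    """Cluster under every parameter cell, score by silhouette, rank.

    Cells are ranked by overall silhouette (descending); ties resolve by
    cell tag. Cells whose clustering yields a single cluster get
    silhouette None and sort last.
    """
    rows = []
    for cc_stop in cc_stops:
        for step in step_percents:
            lo, n = 0.80, int(round(0.20 / (step / 100.0)))
            steps = tuple(round(lo + k * step / 100.0, 4) for k in range(n + 1))
            for mode in merge_modes:
                tag = param_tag(cc_stop, step, mode)
                cs = cluster_interfaces(net, cc_stop, steps, mode, min_size, sim_table=sim_table)
                try:
                    overall = silhouette(cs, sim_table).overall
                except ValueError:
                    overall = None
                rows.append({
                    "cell": tag, "cc_stop": cc_stop, "step": step, "merge_mode": mode,
                    "n_clusters": cs.n_clusters, "silhouette": overall, "clusters": cs,
                })
    rows.sort(key=lambda r: (r["silhouette"] is None,
                             -(r["silhouette"] or 0.0), r["cell"]))
    return rows


def grid_summary_json(rows: list[dict], path) -> None:
    payload = [{k: v for k, v in r.items() if k != "clusters"} for r in rows]
    Path(path).write_text(json.dumps(payload, indent=1))


def cluster_size_distribution(clusters: ClusterSet) -> dict[int, int]:
    """Histogram: cluster size -> number of clusters of that size."""
    return dict(sorted(Counter(len(c) for c in clusters.clusters).items()))
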