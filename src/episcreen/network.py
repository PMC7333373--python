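"""Epistasis network assembly and serialization.

Nodes carry the main-effect mutual information of each predictor, edges
the pairwise information gain, and hyperedges (stored separately, since
ordinary graphs have no 3-ary edges) the three-way information gain; all
carry permutation p-values and their Bonferroni significance class, so a
renderer can size nodes by MI, weight edges by IG and colour them by
verdict.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

__all__ = ["EpistasisNetwork", "build_network", "export_network", "load_network_json"]


@dataclass
class EpistasisNetwork:
    graph: nx.Graph
    hyperedges: list[dict] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "nodes": [{"name": n, **d} for n, d in sorted(self.graph.nodes(data=True))],
            "edges": [{"u": min(u, v), "v": max(u, v), **d}
                      for u, v, d in sorted(self.graph.edges(data=True),
                                            key=lambda e: (min(e[0], e[1]),
                                                           max(e[0], e[1])))],
            "hyperedges": self.hyperedges,
            "meta": self.meta,
        }


def _split_vars(label: str) -> tuple[str, ...]:
    return tuple(label.split(" x "))


def build_network(main_results: pd.DataFrame, pair_results: pd.DataFrame,
                  triple_results: pd.DataFrame | None = None) -> EpistasisNetwork:
    """Assemble the network from screen result tables (orders 1, 2, 3).

    Raises if an edge references a variable absent from the main-effect
    table.
    """
    g = nx.Graph()
    for _, row in main_results.iterrows():
        (name,) = _split_vars(row["variables"])
        g.add_node(name, mi_bits=float(row["bits"]), mi_pct=float(row["pct"]),
                   p_value=float(row["p_value"]), significance=str(row["significance"]))
    node_set = set(g.nodes)
    for _, row in pair_results.iterrows():
        u, v = _split_vars(row["variables"])
        if u not in node_set or v not in node_set:
            raise ValueError(f"edge ({u}, {v}) references unknown node")
        g.add_edge(u, v, ig_bits=float(row["bits"]), ig_pct=float(row["pct"]),
                   p_value=float(row["p_value"]), significance=str(row["significance"]))
    hyper = []
    if triple_results is not None:
        for _, row in triple_results.iterrows():
            trip = _split_vars(row["variables"])
            if not set(trip) <= node_set:
                raise ValueError(f"hyperedge {trip} references unknown node")
            hyper.append({"variables": list(trip), "ig_bits": float(row["bits"]),
                          "ig_pct": float(row["pct"]), "p_value": float(row["p_value"]),
                          "significance": str(row["significance"])})
    meta = {}
    if len(pair_results):
        meta["pairwise_thresholds"] = {
            "significant": float(pair_results["threshold_significant"].iloc[0]),
            "suggestive": float(pair_results["threshold_suggestive"].iloc[0])}
    return EpistasisNetwork(graph=g, hyperedges=hyper, meta=meta)


def export_network(net: EpistasisNetwork, path: str | Path, fmt: str = "JSON") -> None:
    """Serialize as round-trippable JSON, or as GraphML/DOT with weights
    and significance classes carried as attributes (hyperedges travel as a
    JSON-encoded graph attribute in GraphML)."""
    path = Path(path)
    fmt = fmt.upper()
    if fmt == "JSON":
        path.write_text(json.dumps(net.to_dict(), indent=2, sort_keys=True))
    elif fmt == "GRAPHML":
        g = net.graph.copy()
        g.graph["hyperedges"] = json.dumps(net.hyperedges)
        g.graph["meta"] = json.dumps(net.meta)
        nx.write_graphml(g, path)
    elif fmt == "DOT":
        lines = ["graph epistasis {"]
        for n, d in sorted(net.graph.nodes(data=True)):
            attrs = ", ".join(f'{k}="{v}"' for k, v in d.items())
            lines.append(f'  "{n}" [{attrs}];')
        for u, v, d in sorted(net.graph.edges(data=True)):
            attrs = ", ".join(f'{k}="{val}"' for k, val in d.items())
            lines.append(f'  "{u}" -- "{v}" [{attrs}];')
        lines.append("}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown export format: {fmt!r} (use JSON, GraphML or DOT)")


def load_network_json(path: str | Path) -> EpistasisNetwork:
    payload = json.loads(Path(path).read_text())
    g = nx.Graph()
    for node in payload["nodes"]:
        d = dict(node)
        g.add_node(d.pop("name"), **d)
    for edge in payload["edges"]:
        d = dict(edge)
        g.add_edge(d.pop("u"), d.pop("v"), **d)
    return EpistasisNetwork(graph=g, hyperedges=payload["hyperedges"],
                            meta=payload["meta"])
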