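"""Serialisation of networks, communities and diagnostics.

Networks go out as GraphML and as TSV edge lists
(``source  target  pcor  strong``); communities as JSON keyed by community
id; centrality as TSV; cross-validation diagnostics as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from .copula import CVPath, Edge, PartialCorrelationNetwork
from .linkcomm import CentralityTable, CommunityPartition

__all__ = [
    "write_network_graphml",
    "write_edge_tsv",
    "read_edge_tsv",
    "write_communities_json",
    "write_centrality_tsv",
    "write_cv_json",
]


def write_network_graphml(net: PartialCorrelationNetwork, path: str | Path,
                          partition: CommunityPartition | None = None) -> None:
    G = net.to_graph()
    if partition is not None:
        membership: dict[str, list[int]] = {n: [] for n in G.nodes}
        for c in partition.communities:
            for n in c.nodes:
                membership[n].append(c.index)
        for n in G.nodes:
            G.nodes[n]["communities"] = ",".join(map(str, membership.get(n, [])))
    nx.write_graphml(G, str(path))


def write_edge_tsv(net: PartialCorrelationNetwork, path: str | Path) -> None:
    lines = ["source\ttarget\tpcor\tstrong"]
    for e in sorted(net.edges, key=lambda e: (e.u, e.v)):
        lines.append(f"{e.u}\t{e.v}\t{e.pcor:.10g}\t{int(e.strong)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_edge_tsv(path: str | Path,
                  nodes: Sequence[str] | None = None) -> PartialCorrelationNetwork:
    """Rebuild a network from its exported edge list."""
    import networkx as nx

    rows = Path(path).read_text().strip().splitlines()
    header = rows[0].split("\t")
    if header[:3] != ["source", "target", "pcor"]:
        raise ValueError(f"unexpected edge TSV header in {path}")
    edges = []
    for line in rows[1:]:
        parts = line.split("\t")
        u, v, pcor = parts[0], parts[1], float(parts[2])
        strong = bool(int(parts[3])) if len(parts) > 3 else abs(pcor) >= 0.30
        if u > v:
            u, v = v, u
        edges.append(Edge(u, v, pcor, strong))
    if nodes is None:
        nodes = sorted({n for e in edges for n in (e.u, e.v)})
    nodes = tuple(nodes)
    idx = {n: k for k, n in enumerate(nodes)}
    pcor = np.eye(len(nodes))
    G = nx.Graph()
    G.add_nodes_from(nodes)
    for e in edges:
        pcor[idx[e.u], idx[e.v]] = pcor[idx[e.v], idx[e.u]] = e.pcor
        G.add_edge(e.u, e.v)
    components = tuple(frozenset(c) for c in
                       sorted(nx.connected_components(G), key=lambda c: sorted(c)[0]))
    networks = tuple(c for c in components if len(c) >= 3)
    return PartialCorrelationNetwork(nodes=nodes, pcor_matrix=pcor,
                                     edges=tuple(edges), components=components,
                                     networks=networks)


def write_communities_json(partition: CommunityPartition, path: str | Path) -> None:
    payload = {
        "partition_density": partition.partition_density_value,
        "cut_similarity": partition.cut_similarity,
        "n_edges": partition.n_edges,
        "unassigned_nodes": list(partition.unassigned_nodes),
        "communities": {
            str(c.index): {
                "nodes": sorted(c.nodes),
                "edges": [list(e) for e in c.edges],
                "density_contribution": c.density_contribution,
            }
            for c in partition.communities
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def write_centrality_tsv(table: CentralityTable, path: str | Path) -> None:
    lines = ["node\tn_communities\trank"]
    for rank, node in enumerate(table.ranking, start=1):
        lines.append(f"{node}\t{table.counts[node]}\t{rank}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_cv_json(cv: CVPath, path: str | Path) -> None:
    payload = {
        "lambdas": [float(x) for x in cv.lambdas],
        "mean_losses": [float(x) for x in cv.mean_losses],
        "lambda_star": cv.lambda_star,
        "lambda_min": cv.lambda_min,
        "selection_rule": cv.selection_rule,
        "n_folds": cv.n_folds,
        "seed": cv.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=1))
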