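"""Overlapping link communities by edge-similarity clustering.

Edges (not nodes) are clustered: the similarity of two edges sharing a node
is the Jaccard index of the inclusive neighborhoods of their non-shared
ends. Single-linkage agglomeration over edge pairs produces a dendrogram
that is cut at the level maximising the partition density D; clusters
spanning at least three nodes are reported as communities. A node inherits
membership of every community touching it, so communities may overlap and
nodes inside dyads or tree-like fringes remain unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

EdgePair = tuple[str, str]

__all__ = [
    "EdgeGraph",
    "LinkDendrogram",
    "Community",
    "CommunityPartition",
    "CentralityTable",
    "edge_similarity",
    "build_dendrogram",
    "partition_density",
    "cut_at_max_density",
    "community_centrality",
    "brute_force_communities",
    "exhaustive_partition_density",
    "detect_communities",
]


def _norm_edge(u: str, v: str) -> EdgePair:
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class EdgeGraph:
    """Undirected simple graph with inclusive neighborhoods n+(i)."""

    nodes: tuple[str, ...]
    edges: tuple[EdgePair, ...]

    def __post_init__(self) -> None:
        seen = set()
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop on {u!r}")
            if (u, v) != _norm_edge(u, v):
                raise ValueError(f"edge ({u!r}, {v!r}) not normalised")
            if (u, v) in seen:
                raise ValueError(f"duplicate edge ({u!r}, {v!r})")
            seen.add((u, v))
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge endpoint outside node set: ({u!r}, {v!r})")

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]],
                   nodes: Sequence[str] | None = None) -> "EdgeGraph":
        norm = tuple(sorted({_norm_edge(u, v) for u, v in edges}))
        if nodes is None:
            nodes = sorted({n for e in norm for n in e})
        return cls(tuple(nodes), norm)

    def inclusive_neighborhood(self, node: str) -> frozenset[str]:
        nb = {node}
        for u, v in self.edges:
            if u == node:
                nb.add(v)
            elif v == node:
                nb.add(u)
        return frozenset(nb)

    def neighborhoods(self) -> dict[str, frozenset[str]]:
        nb: dict[str, set[str]] = {n: {n} for n in self.nodes}
        for u, v in self.edges:
            nb[u].add(v)
            nb[v].add(u)
        return {n: frozenset(s) for n, s in nb.items()}


def edge_similarity(graph: EdgeGraph, e1: EdgePair, e2: EdgePair) -> float:
    """Jaccard similarity of the non-shared ends' inclusive neighborhoods.

    Edges sharing no node have similarity 0; for edges (i, k) and (j, k)
    the score is |n+(i) & n+(j)| / |n+(i) | n+(j)|.
    """
    e1, e2 = _norm_edge(*e1), _norm_edge(*e2)
    if e1 == e2:
        raise ValueError("similarity is defined for distinct edges")
    shared = set(e1) & set(e2)
    if not shared:
        return 0.0
    (i,) = set(e1) - shared
    (j,) = set(e2) - shared
    nb = graph.neighborhoods()
    ni, nj = nb[i], nb[j]
    return len(ni & nj) / len(ni | nj)


@dataclass
class LinkDendrogram:
    """Single-linkage merge structure over the edge set."""

    graph: EdgeGraph
    edges: tuple[EdgePair, ...]  # lexicographic order
    linkage_matrix: np.ndarray | None  # None when M == 1
    similarity: np.ndarray  # M x M pairwise edge similarities

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def merge_heights(self) -> np.ndarray:
        if self.linkage_matrix is None:
            return np.array([])
        return np.unique(self.linkage_matrix[:, 2])

    def clusters_at(self, height: float) -> tuple[tuple[EdgePair, ...], ...]:
        """Edge clusters at cut distance ``height`` (1 - similarity)."""
        if self.linkage_matrix is None or height < 0:
            labels = np.arange(self.n_edges)
        else:
            labels = fcluster(self.linkage_matrix, t=height, criterion="distance")
        groups: dict[int, list[EdgePair]] = {}
        for e, lab in zip(self.edges, labels):
            groups.setdefault(int(lab), []).append(e)
        return tuple(tuple(g) for _, g in sorted(groups.items(),
                                                 key=lambda kv: kv[1][0]))


def _similarity_matrix(graph: EdgeGraph, edges: tuple[EdgePair, ...]) -> np.ndarray:
    M = len(edges)
    nb = graph.neighborhoods()
    S = np.zeros((M, M))
    for a in range(M):
        for b in range(a + 1, M):
            e1, e2 = edges[a], edges[b]
            shared = set(e1) & set(e2)
            if shared:
                (i,) = set(e1) - shared
                (j,) = set(e2) - shared
                ni, nj = nb[i], nb[j]
                S[a, b] = S[b, a] = len(ni & nj) / len(ni | nj)
    np.fill_diagonal(S, 1.0)
    return S


def build_dendrogram(graph: EdgeGraph) -> LinkDendrogram:
    """Single-linkage agglomeration of edges in descending similarity."""
    edges = tuple(sorted(graph.edges))
    if not edges:
        raise ValueError("graph has no edges")
    S = _similarity_matrix(graph, edges)
    if len(edges) == 1:
        return LinkDendrogram(graph, edges, None, S)
    D = squareform(1.0 - S, checks=False)
    Z = linkage(D, method="single")
    return LinkDendrogram(graph, edges, Z, S)


def partition_density(clusters: Sequence[Sequence[EdgePair]], M: int) -> float:
    """D = (2/M) * sum_c m_c (m_c - n_c + 1) / ((n_c - 2)(n_c - 1)).

    A single-edge cluster (n_c = 2) contributes 0 by convention; tree-like
    clusters (m_c = n_c - 1) vanish through the numerator.
    """
    if M < 1:
        raise ValueError("M must be at least 1")
    total = 0.0
    for cl in clusters:
        m_c = len(cl)
        if m_c == 0:
            raise ValueError("empty edge cluster")
        n_c = len({n for e in cl for n in e})
        if n_c > 2:
            total += m_c * (m_c - n_c + 1) / ((n_c - 2) * (n_c - 1))
    return 2.0 * total / M


@dataclass(frozen=True)
class Community:
    index: int
    nodes: frozenset[str]
    edges: tuple[EdgePair, ...]

    @property
    def density_contribution(self) -> float:
        m_c, n_c = len(self.edges), len(self.nodes)
        if n_c <= 2:
            return 0.0
        return m_c * (m_c - n_c + 1) / ((n_c - 2) * (n_c - 1))


@dataclass
class CommunityPartition:
    """Edge partition at the chosen cut with the >= 3-node community filter."""

    edge_clusters: tuple[tuple[EdgePair, ...], ...]
    communities: tuple[Community, ...]
    partition_density_value: float
    cut_similarity: float
    nodes: tuple[str, ...]
    unassigned_nodes: tuple[str, ...]
    n_edges: int


def _make_partition(graph: EdgeGraph, clusters: tuple[tuple[EdgePair, ...], ...],
                    D: float, cut_similarity: float) -> CommunityPartition:
    comms = []
    for cl in clusters:
        nodes = frozenset(n for e in cl for n in e)
        if len(nodes) >= 3:
            comms.append(Community(len(comms), nodes, tuple(sorted(cl))))
    covered: set[str] = set()
    for c in comms:
        covered |= c.nodes
    unassigned = tuple(n for n in graph.nodes if n not in covered)
    return CommunityPartition(
        edge_clusters=clusters, communities=tuple(comms),
        partition_density_value=D, cut_similarity=cut_similarity,
        nodes=graph.nodes, unassigned_nodes=unassigned,
        n_edges=len(graph.edges),
    )


def cut_at_max_density(dendrogram: LinkDendrogram) -> CommunityPartition:
    """Cut the dendrogram where partition density peaks.

    Every merge level (plus the all-singletons level) is scored; ties break
    toward the higher-similarity (finer) cut.
    """
    graph = dendrogram.graph
    M = dendrogram.n_edges
    heights = [-1.0] + list(dendrogram.merge_heights())
    best_D, best_clusters, best_h = -np.inf, None, None
    for h in heights:  # ascending: first strict max favors the finer cut
        clusters = dendrogram.clusters_at(h)
        D = partition_density(clusters, M)
        if D > best_D + 1e-12:
            best_D, best_clusters, best_h = D, clusters, h
    return _make_partition(graph, best_clusters, best_D,
                           cut_similarity=1.0 - max(best_h, 0.0))


@dataclass
class CentralityTable:
    """Community-count centrality with deterministic ranking."""

    counts: dict[str, int]
    ranking: tuple[str, ...]  # descending count, ties alphabetical
    central_nodes: tuple[str, ...]  # count >= 2


def community_centrality(partition: CommunityPartition) -> CentralityTable:
    counts = {n: 0 for n in partition.nodes}
    for c in partition.communities:
        for n in c.nodes:
            counts[n] += 1
    ranking = tuple(sorted(counts, key=lambda n: (-counts[n], n)))
    central = tuple(n for n in ranking if counts[n] >= 2)
    return CentralityTable(counts=counts, ranking=ranking, central_nodes=central)


def brute_force_communities(graph: EdgeGraph, max_edges: int = 10
                            ) -> CommunityPartition:
    """Independent maximiser over all similarity thresholds (testing oracle).

    Clusters at threshold s are the connected components of the edge-pair
    graph restricted to similarities >= s — the flat clusters single
    linkage would produce — recomputed here from scratch without the
    dendrogram machinery.
    """
    edges = tuple(sorted(graph.edges))
    M = len(edges)
    if M > max_edges:
        raise ValueError(f"brute force limited to {max_edges} edges, got {M}")
    S = _similarity_matrix(graph, edges)
    levels = sorted({S[a, b] for a in range(M) for b in range(a + 1, M)},
                    reverse=True)
    candidates: list[float] = [np.inf] + levels  # inf = all singletons
    best_D, best_clusters, best_s = -np.inf, None, None
    for s in candidates:  # descending: first strict max is the finest
        parent = list(range(M))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a in range(M):
            for b in range(a + 1, M):
                if S[a, b] >= s:
                    parent[find(a)] = find(b)
        groups: dict[int, list[EdgePair]] = {}
        for idx, e in enumerate(edges):
            groups.setdefault(find(idx), []).append(e)
        clusters = tuple(tuple(g) for _, g in sorted(groups.items(),
                                                     key=lambda kv: kv[1][0]))
        D = partition_density(clusters, M)
        if D > best_D + 1e-12:
            best_D, best_clusters, best_s = D, clusters, s
    sim = 1.0 if best_s is np.inf else float(best_s)
    return _make_partition(graph, best_clusters, best_D, cut_similarity=sim)


def _set_partitions(items: tuple):
    """All set partitions (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def exhaustive_partition_density(graph: EdgeGraph, max_edges: int = 6) -> float:
    """Max D over ALL partitions of edges into connected clusters (M <= 6)."""
    edges = tuple(sorted(graph.edges))
    M = len(edges)
    if M > max_edges:
        raise ValueError(f"exhaustive search limited to {max_edges} edges")

    def connected(cluster: list[EdgePair]) -> bool:
        todo = [cluster[0]]
        seen_edges = {cluster[0]}
        nodes_reached = set(cluster[0])
        grew = True
        while grew:
            grew = False
            for e in cluster:
                if e not in seen_edges and (e[0] in nodes_reached or e[1] in nodes_reached):
                    seen_edges.add(e)
                    nodes_reached |= set(e)
                    grew = True
        return len(seen_edges) == len(cluster)

    best = -np.inf
    for part in _set_partitions(edges):
        if all(connected(cl) for cl in part):
            best = max(best, partition_density(part, M))
    return float(best)


def detect_communities(graph: EdgeGraph) -> tuple[CommunityPartition, CentralityTable]:
    """Dendrogram, max-density cut and centrality in one call."""
    partition = cut_at_max_density(build_dendrogram(graph))
    return partition, community_centrality(partition)
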