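"""Shared fixtures and independent oracles."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from mealnets.copula import Edge, PartialCorrelationNetwork
from mealnets.foods import OCCASIONS
from mealnets.synthetic import CohortSpec, GraphSpec, MarginSpec, generate_recalls


def make_network(edges, nodes=None) -> PartialCorrelationNetwork:
    """Build a PartialCorrelationNetwork directly from (u, v, pcor) triples."""
    if nodes is None:
        nodes = sorted({n for u, v, _ in edges for n in (u, v)})
    nodes = tuple(nodes)
    idx = {n: k for k, n in enumerate(nodes)}
    pcor = np.eye(len(nodes))
    out_edges = []
    G = nx.Graph()
    G.add_nodes_from(nodes)
    for u, v, val in edges:
        if u > v:
            u, v = v, u
        pcor[idx[u], idx[v]] = pcor[idx[v], idx[u]] = val
        out_edges.append(Edge(u, v, float(val), abs(val) >= 0.30))
        G.add_edge(u, v)
    components = tuple(frozenset(c) for c in
                       sorted(nx.connected_components(G), key=lambda c: sorted(c)[0]))
    return PartialCorrelationNetwork(
        nodes=nodes, pcor_matrix=pcor, edges=tuple(out_edges),
        components=components,
        networks=tuple(c for c in components if len(c) >= 3),
    )


def single_meal_cohort(graph: GraphSpec, n_obs: int, zero_probability: float,
                       seed: int, participant_effect_sd: float = 0.0,
                       meanlog: float = 3.0, sdlog: float = 0.8):
    """One-meal cohort: n_obs independent meal occurrences from the graph's
    copula with uniform zero inflation."""
    p = graph.n_nodes
    groups = tuple(f"g{i:02d}" for i in range(p))
    margins = MarginSpec(zero_probability=(zero_probability,) * p,
                         params=((meanlog, sdlog),) * p)
    cohort = CohortSpec(
        n_participants=n_obs, recalls_per_participant={1: 1.0},
        occasion_labels=OCCASIONS, main_meals=("lunch",),
        meal_graphs={"lunch": graph}, food_groups=groups,
        participant_effect_sd=participant_effect_sd, seed=seed,
    )
    return generate_recalls(cohort, margins), groups


def ista_glasso(S: np.ndarray, lam: float, max_iter: int = 50000,
                tol: float = 1e-12) -> np.ndarray:
    """Independent convex-optimisation oracle: proximal gradient with
    backtracking on tr(S O) - log det O + lam * ||O||_1,off."""
    p = len(S)
    O = np.linalg.inv(S + lam * np.eye(p))
    t = 1.0 / np.linalg.eigvalsh(S)[-1] ** 2
    off = ~np.eye(p, dtype=bool)

    def smooth(M):
        return np.trace(S @ M) - np.linalg.slogdet(M)[1]

    f_old = np.inf
    for _ in range(max_iter):
        G = S - np.linalg.inv(O)
        step = t
        while True:
            A = O - step * G
            Z = A.copy()
            Z[off] = np.sign(A[off]) * np.maximum(np.abs(A[off]) - step * lam, 0)
            Z = (Z + Z.T) / 2
            if np.linalg.eigvalsh(Z)[0] > 0:
                gap = smooth(O) + np.sum(G * (Z - O)) + np.sum((Z - O) ** 2) / (2 * step)
                if smooth(Z) <= gap + 1e-15:
                    break
            step *= 0.5
        O = Z
        f = smooth(O) + lam * np.abs(O[off]).sum()
        if abs(f_old - f) < tol * max(1.0, abs(f)):
            break
        f_old = f
    return O


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
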