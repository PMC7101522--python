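"""Independent oracles used to cross-check the centrality implementation.

These deliberately take different routes than the package: distances come
from scipy's Floyd-Warshall, betweenness/stress from explicit enumeration
of every shortest path via networkx.  None of them share code with
ppiscreen.centrality.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import floyd_warshall

from ppiscreen.graph import Network


def to_nx(net: Network) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(net.sorted_nodes())
    g.add_edges_from(net.sorted_edges())
    return g


def fw_distances(net: Network) -> dict[str, dict[str, float]]:
    """All-pairs shortest paths via scipy Floyd-Warshall (inf = unreachable)."""
    nodes = net.sorted_nodes()
    idx = {n: i for i, n in enumerate(nodes)}
    amat = np.zeros((len(nodes), len(nodes)))
    for a, b in net.sorted_edges():
        amat[idx[a], idx[b]] = amat[idx[b], idx[a]] = 1
    dmat = floyd_warshall(amat, directed=False, unweighted=True)
    return {
        a: {b: dmat[idx[a], idx[b]] for b in nodes}
        for a in nodes
    }


def enumerate_bc_stress(net: Network) -> tuple[dict[str, float], dict[str, int]]:
    """Normalized betweenness and stress by exhaustive geodesic enumeration.

    For every unordered pair {s, t} all shortest paths are materialized;
    each path's interior nodes gain one geodesic (stress) and the pair's
    per-node path fractions accumulate into raw betweenness, normalized by
    2/((N-1)(N-2)) per connected component of size N.
    """
    g = to_nx(net)
    bc = {n: 0.0 for n in g}
    stress = {n: 0 for n in g}
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        nodes = sorted(comp)
        n = len(nodes)
        for i, s in enumerate(nodes):
            for t in nodes[i + 1 :]:
                paths = list(nx.all_shortest_paths(sub, s, t))
                for p in paths:
                    for v in p[1:-1]:
                        stress[v] += 1
                through = {}
                for p in paths:
                    for v in p[1:-1]:
                        through[v] = through.get(v, 0) + 1
                for v, c in through.items():
                    bc[v] += c / len(paths)
        if n > 2:
            norm = 2.0 / ((n - 1) * (n - 2))
            for v in nodes:
                bc[v] *= norm
    return bc, stress


def random_connected_net(n: int, p: float, seed: int) -> Network:
    """A connected G(n, p) network; disconnected draws are re-rolled
    deterministically (seed offset) until one is connected."""
    attempt = seed
    while True:
        g = nx.gnp_random_graph(n, p, seed=attempt)
        if n == 0 or nx.is_connected(g):
            break
        attempt += 100_003
    return Network(
        nodes=[f"N{i:02d}" for i in g.nodes],
        edges=[(f"N{a:02d}", f"N{b:02d}") for a, b in g.edges],
    )
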