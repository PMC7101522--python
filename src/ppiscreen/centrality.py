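"""Node centrality statistics for undirected, unweighted graphs.

Implements the NetworkAnalyzer-style per-node statistics used to rank genes
in a PPI main component:

degree
    Neighbor count.
avg_L
    Mean shortest-path length from the node to every other *reachable*
    node (its connected component); undefined for isolated nodes.
closeness (CC)
    ``1 / avg_L`` — how fast information spreads from the node.
betweenness (BC)
    Sum over unordered pairs ``{s, t}`` (both distinct from the node) of
    the fraction of s-t geodesics passing through the node, normalized by
    ``2 / ((N - 1)(N - 2))`` with ``N`` the component size, so BC lies in
    [0, 1].
stress
    Raw count of geodesics (shortest paths) passing through the node, over
    unordered source-target pairs; a pair with three shortest paths through
    the node contributes three.

All-pairs distances and geodesic counts come from one breadth-first search
per source; betweenness and stress are then assembled per node from the
distance and count matrices.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .graph import InputError, Network

__all__ = [
    "CentralityRecord",
    "CentralityTable",
    "all_pairs_distances",
    "closeness",
    "betweenness",
    "stress",
    "centrality_table",
    "closeness_from_avg_length",
    "round_for_report",
]

UNREACHABLE = float("inf")


def closeness_from_avg_length(avg_l: float) -> float:
    """Closeness centrality from an average shortest-path length: 1/avg_L."""
    if avg_l <= 0:
        raise InputError(f"average path length must be positive, got {avg_l}")
    return 1.0 / avg_l


def round_for_report(value: float, ndigits: int = 2) -> float:
    """Presentation rounding used by the report layer (metrics themselves
    are stored at full precision)."""
    return float(round(value, ndigits))


@dataclass(frozen=True)
class CentralityRecord:
    node: str
    degree: int
    stress: int
    avg_l: float | None
    betweenness: float
    closeness: float | None

    def as_row(self) -> list:
        return [
            self.node,
            self.degree,
            self.stress,
            self.avg_l,
            self.betweenness,
            self.closeness,
        ]


@dataclass
class CentralityTable:
    """One record per node, ordered by closeness descending, ties by symbol."""

    records: list[CentralityRecord]
    graph_name: str = ""

    HEADER = ("node", "degree", "stress", "avg_L", "betweenness", "closeness")

    def __post_init__(self) -> None:
        self.records = sorted(
            self.records,
            key=lambda r: (-(r.closeness if r.closeness is not None else -1.0), r.node),
        )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def record(self, node: str) -> CentralityRecord:
        for r in self.records:
            if r.node == node:
                return r
        raise KeyError(node)

    def values(self, metric: str) -> list[float]:
        if metric not in {"closeness", "degree", "stress", "betweenness"}:
            raise InputError(f"unknown metric {metric!r}")
        return [getattr(r, metric) for r in self.records]

    def sorted_by(self, metric: str, descending: bool = True) -> list[CentralityRecord]:
        sign = -1.0 if descending else 1.0
        return sorted(
            self.records, key=lambda r: (sign * getattr(r, metric), r.node)
        )

    def to_tsv(self) -> str:
        lines = ["\t".join(self.HEADER)]
        for r in self.records:
            avg_l = "NA" if r.avg_l is None else f"{round_for_report(r.avg_l):.2f}"
            cc = "NA" if r.closeness is None else f"{round_for_report(r.closeness):.2f}"
            lines.append(
                f"{r.node}\t{r.degree}\t{r.stress}\t{avg_l}\t"
                f"{round_for_report(r.betweenness):.2f}\t{cc}"
            )
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Shortest-path machinery
# ---------------------------------------------------------------------------


def _bfs(adj: dict[str, frozenset[str]], source: str) -> tuple[dict, dict]:
    """Single-source BFS returning distances and geodesic counts sigma."""
    dist = {source: 0}
    sigma = {source: 1}
    queue = deque([source])
    while queue:
        v = queue.popleft()
        for w in adj[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                sigma[w] = sigma[v]
                queue.append(w)
            elif dist[w] == dist[v] + 1:
                sigma[w] += sigma[v]
    return dist, sigma


def _matrices(net: Network, nodes: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Distance and geodesic-count matrices over ``nodes`` (BFS per source).

    D[i, j] = inf for unreachable pairs; S[i, j] = 0 there.
    """
    index = {n: i for i, n in enumerate(nodes)}
    adj = {n: net.neighbors(n) for n in nodes}
    n = len(nodes)
    dmat = np.full((n, n), UNREACHABLE)
    smat = np.zeros((n, n))
    for src in nodes:
        dist, sigma = _bfs(adj, src)
        i = index[src]
        for tgt, d in dist.items():
            dmat[i, index[tgt]] = d
            smat[i, index[tgt]] = sigma[tgt]
    return dmat, smat


def all_pairs_distances(net: Network) -> dict[str, dict[str, int]]:
    """All-pairs shortest-path lengths; unreachable pairs are omitted.

    Returned as ``{source: {target: distance}}`` with ``d(n, n) = 0``.
    """
    nodes = net.sorted_nodes()
    adj = {n: net.neighbors(n) for n in nodes}
    return {src: _bfs(adj, src)[0] for src in nodes}


def closeness(net: Network, node: str) -> tuple[float | None, float | None]:
    """(avg_L, closeness) of ``node``; (None, None) for an isolated node.

    avg_L averages over the node's connected component only, so it is
    always finite; closeness = 1/avg_L.
    """
    nodes = net.sorted_nodes()
    if node not in net:
        raise InputError(f"unknown node {node!r}")
    adj = {n: net.neighbors(n) for n in nodes}
    dist, _ = _bfs(adj, node)
    reach = [d for tgt, d in dist.items() if tgt != node]
    if not reach:
        return None, None
    avg_l = sum(reach) / len(reach)
    return avg_l, closeness_from_avg_length(avg_l)


def _through_counts(
    dmat: np.ndarray, smat: np.ndarray, v: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair geodesic counts through node v and total counts.

    Returns (sigma_through, sigma_total) as n x n matrices over ordered
    pairs (s, t); entries for pairs involving v or unreachable pairs are 0.
    """
    n = dmat.shape[0]
    dv = dmat[:, v]
    on_path = dv[:, None] + dv[None, :] == dmat  # d(s,v) + d(v,t) == d(s,t)
    through = np.where(on_path, smat[:, v][:, None] * smat[v, :][None, :], 0.0)
    mask = np.ones((n, n), dtype=bool)
    mask[v, :] = False
    mask[:, v] = False
    np.fill_diagonal(mask, False)
    mask &= np.isfinite(dmat)
    return np.where(mask, through, 0.0), np.where(mask, smat, 0.0)


def _betweenness_stress(
    net: Network, nodes: list[str]
) -> tuple[dict[str, float], dict[str, int]]:
    """Normalized betweenness and raw stress for every node of one component."""
    dmat, smat = _matrices(net, nodes)
    n = len(nodes)
    bc: dict[str, float] = {}
    st: dict[str, int] = {}
    for v, name in enumerate(nodes):
        through, total = _through_counts(dmat, smat, v)
        # unordered pairs: every pair appears at (s, t) and (t, s)
        stress_v = through.sum() / 2.0
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(total > 0, through / np.where(total > 0, total, 1.0), 0.0)
        raw_bc = frac.sum() / 2.0
        if n > 2:
            bc[name] = raw_bc * 2.0 / ((n - 1) * (n - 2))
        else:
            bc[name] = 0.0
        st[name] = int(round(stress_v))
    return bc, st


def betweenness(net: Network, node: str) -> float:
    """Normalized betweenness of ``node`` within its connected component."""
    if node not in net:
        raise InputError(f"unknown node {node!r}")
    comp = next(c for c in net.components() if node in c)
    nodes = sorted(comp)
    bc, _ = _betweenness_stress(net, nodes)
    return bc[node]


def stress(net: Network, node: str) -> int:
    """Stress (geodesic count through ``node``) within its component."""
    if node not in net:
        raise InputError(f"unknown node {node!r}")
    comp = next(c for c in net.components() if node in c)
    nodes = sorted(comp)
    _, st = _betweenness_stress(net, nodes)
    return st[node]


def centrality_table(net: Network) -> CentralityTable:
    """All four statistics for every node of a *connected* network.

    Callers analyzing a full interactome should decompose first and pass
    the main component.
    """
    if net.n_nodes == 0:
        raise InputError("empty network")
    if not net.is_connected():
        raise InputError(
            "network is disconnected; decompose() it and analyze one "
            "component at a time"
        )
    nodes = net.sorted_nodes()
    dmat, _ = _matrices(net, nodes)
    bc, st = _betweenness_stress(net, nodes)
    records = []
    for i, name in enumerate(nodes):
        others = np.delete(dmat[i], i)
        if others.size and np.isfinite(others).all():
            avg_l = float(others.mean())
            cc = closeness_from_avg_length(avg_l)
        else:
            avg_l, cc = None, None
        records.append(
            CentralityRecord(
                node=name,
                degree=net.degree(name),
                stress=st[name],
                avg_l=avg_l,
                betweenness=bc[name],
                closeness=cc,
            )
        )
    return CentralityTable(records=records, graph_name=net.name)
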