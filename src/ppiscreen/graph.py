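"""Graph data model, component census, and interchange-format I/O.

The pipeline operates on undirected, unweighted simple graphs over gene
symbols.  STRING confidence scores are consumed once, as an edge filter at
load time, and then discarded: every downstream statistic is unweighted.

Supported interchange formats:

``string_tsv``
    STRING-style tab-separated export with a header line naming at least
    ``node1``, ``node2`` and (optionally) ``combined_score``.  Scores on the
    0-999 integer scale are rescaled to [0, 1] by division by 1000.
``tsv2col``
    Plain two-column tab/whitespace-separated edge list.
``sif``
    Cytoscape simple-interaction format (``A interacts B [C ...]``).
``graphml``
    GraphML, delegated to :mod:`networkx`.

Degree-0 nodes cannot be expressed as edge rows, so the text formats accept
a node-declaration mechanism: a line carrying a single symbol declares the
node without any edge.  ``write_network`` uses the same mechanism so that a
read/write round trip is the identity on (nodes, edges).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

logger = logging.getLogger(__name__)

READ_FORMATS = ("string_tsv", "tsv2col", "sif", "graphml")
WRITE_FORMATS = ("tsv2col", "sif", "graphml")

#: STRING's "medium confidence" threshold, the conventional default filter.
DEFAULT_MIN_SCORE = 0.4


class InputError(ValueError):
    """Raised for malformed or inconsistent user input."""


class ConfigurationError(ValueError):
    """Raised for invalid configuration values (unknown format tags etc.)."""


def _norm_symbol(raw: str) -> str:
    # Trim whitespace only; case is preserved and compared exactly, since
    # silent case-folding can merge distinct gene symbols.
    return raw.strip()


@dataclass(frozen=True)
class EdgeRecord:
    """One row of an edge-list file after normalization."""

    node_a: str
    node_b: str
    score: float | None = None

    def __post_init__(self) -> None:
        if self.node_a == self.node_b:
            raise InputError(f"self-loop edge record: {self.node_a!r}")
        if self.score is not None and not 0.0 <= self.score <= 1.0:
            raise InputError(f"confidence score {self.score} outside [0, 1]")


class Network:
    """An undirected simple graph over gene-symbol nodes.

    Invariants enforced on construction and mutation: no self-loops, edge
    set semantics ({a, b} == {b, a}), every edge endpoint is a declared
    node.  Isolated (degree-0) nodes are first-class.
    """

    def __init__(
        self,
        nodes: Iterable[str] = (),
        edges: Iterable[tuple[str, str]] = (),
        name: str = "",
    ) -> None:
        self._g = nx.Graph()
        self.name = name
        for n in nodes:
            self.add_node(n)
        for a, b in edges:
            self.add_edge(a, b)

    # -- construction -----------------------------------------------------

    def add_node(self, node: str) -> None:
        node = _norm_symbol(node)
        if not node:
            raise InputError("empty node symbol")
        self._g.add_node(node)

    def add_edge(self, a: str, b: str) -> None:
        a, b = _norm_symbol(a), _norm_symbol(b)
        if not a or not b:
            raise InputError("empty node symbol in edge")
        if a == b:
            raise InputError(f"self-loop on {a!r} not allowed")
        self._g.add_edge(a, b)

    @classmethod
    def from_networkx(cls, g: nx.Graph, name: str = "") -> "Network":
        net = cls(name=name)
        for n in g.nodes:
            net.add_node(str(n))
        for a, b in g.edges:
            if a != b:
                net.add_edge(str(a), str(b))
        return net

    def to_networkx(self) -> nx.Graph:
        return self._g.copy()

    # -- queries ----------------------------------------------------------

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self._g.nodes)

    @property
    def edges(self) -> frozenset[frozenset[str]]:
        return frozenset(frozenset(e) for e in self._g.edges)

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def degree(self, node: str) -> int:
        if node not in self._g:
            raise InputError(f"unknown node {node!r}")
        return self._g.degree[node]

    def neighbors(self, node: str) -> frozenset[str]:
        if node not in self._g:
            raise InputError(f"unknown node {node!r}")
        return frozenset(self._g.neighbors(node))

    def has_edge(self, a: str, b: str) -> bool:
        return self._g.has_edge(a, b)

    def sorted_nodes(self) -> list[str]:
        return sorted(self._g.nodes)

    def sorted_edges(self) -> list[tuple[str, str]]:
        """Edges as (min, max) symbol pairs in lexicographic order."""
        return sorted(tuple(sorted(e)) for e in self._g.edges)

    def components(self) -> list[frozenset[str]]:
        """Connected components, largest first; ties by smallest member."""
        comps = [frozenset(c) for c in nx.connected_components(self._g)]
        return sorted(comps, key=lambda c: (-len(c), min(c)))

    def is_connected(self) -> bool:
        return self.n_nodes > 0 and nx.is_connected(self._g)

    def __contains__(self, node: str) -> bool:
        return node in self._g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __repr__(self) -> str:
        label = f" {self.name!r}" if self.name else ""
        return f"<Network{label}: {self.n_nodes} nodes, {self.n_edges} edges>"


@dataclass
class ComponentCensus:
    """Partition of a network into isolated nodes, small components, and the
    main (largest) connected component."""

    isolated: frozenset[str]
    small_components: list[frozenset[str]]
    main_component: frozenset[str]
    other_components: list[frozenset[str]] = field(default_factory=list)

    @property
    def sizes(self) -> dict:
        return {
            "isolated": len(self.isolated),
            "small": sorted((len(c) for c in self.small_components), reverse=True),
            "main": len(self.main_component),
            "other": sorted((len(c) for c in self.other_components), reverse=True),
            "total": (
                len(self.isolated)
                + sum(len(c) for c in self.small_components)
                + len(self.main_component)
                + sum(len(c) for c in self.other_components)
            ),
        }


def decompose(net: Network, small_max: int = 3) -> ComponentCensus:
    """Classify connected components into isolated / small / main.

    ``small_components`` holds every component with 2 <= size <= small_max
    that is not the main component; anything larger that is not the main
    component lands in ``other_components``.  The main component is the
    largest; an exact size tie is broken toward the component whose
    lexicographically smallest member sorts first (logged as a warning).
    """
    if net.n_nodes == 0:
        raise InputError("cannot decompose an empty network")
    if small_max < 2:
        raise ConfigurationError(f"small_max must be >= 2, got {small_max}")
    comps = net.components()
    max_size = len(comps[0])
    if sum(1 for c in comps if len(c) == max_size) > 1:
        logger.warning(
            "component-size tie at %d nodes; picking the component whose "
            "smallest member sorts first",
            max_size,
        )
    main = comps[0]
    isolated: set[str] = set()
    small: list[frozenset[str]] = []
    other: list[frozenset[str]] = []
    for c in comps[1:]:
        if len(c) == 1:
            isolated.update(c)
        elif len(c) <= small_max:
            small.append(c)
        else:
            other.append(c)
    return ComponentCensus(
        isolated=frozenset(isolated),
        small_components=small,
        main_component=main,
        other_components=other,
    )


def induced_subgraph(net: Network, keep: Iterable[str]) -> Network:
    """Induced subgraph: node set ``keep``, all edges with both ends kept."""
    keep_set = {_norm_symbol(n) for n in keep}
    unknown = keep_set - net.nodes
    if unknown:
        raise InputError(f"unknown node(s) in keep set: {sorted(unknown)}")
    sub = Network(name=net.name)
    for n in sorted(keep_set):
        sub.add_node(n)
    for a, b in net.sorted_edges():
        if a in keep_set and b in keep_set:
            sub.add_edge(a, b)
    return sub


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _iter_lines(path: Path) -> Iterator[tuple[int, str]]:
    try:
        text = path.read_text()
    except OSError as exc:
        raise InputError(f"cannot read {path}: {exc}") from exc
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        yield lineno, stripped


def _parse_string_tsv(path: Path) -> tuple[list[EdgeRecord], set[str], int]:
    """STRING export: header names columns; scores may be 0-1 or 0-999."""
    records: list[tuple[int, str, str, float | None]] = []
    declared: set[str] = set()
    lines = list(_iter_lines(path))
    if not lines:
        return [], set(), 0
    col_a, col_b, col_score = 0, 1, None
    start = 0
    header = lines[0][1].lstrip("#").split("\t")
    header = [h.strip().lower() for h in header]
    if "node1" in header or "protein1" in header:
        for alias in ("node1", "protein1"):
            if alias in header:
                col_a = header.index(alias)
        for alias in ("node2", "protein2"):
            if alias in header:
                col_b = header.index(alias)
        for alias in ("combined_score", "score"):
            if alias in header:
                col_score = header.index(alias)
        start = 1
    max_score = 0.0
    for lineno, line in lines[start:]:
        fields = line.split("\t")
        if len(fields) == 1:
            fields = line.split()
        if len(fields) == 1:
            declared.add(_norm_symbol(fields[0]))
            continue
        if len(fields) <= max(col_a, col_b):
            raise InputError(f"{path}:{lineno}: edge row with < 2 usable fields")
        score: float | None = None
        if col_score is not None and len(fields) > col_score:
            try:
                score = float(fields[col_score])
            except ValueError as exc:
                raise InputError(
                    f"{path}:{lineno}: bad score {fields[col_score]!r}"
                ) from exc
            max_score = max(max_score, score)
        records.append((lineno, fields[col_a], fields[col_b], score))
    # STRING publishes combined scores on either a 0-1 or a 0-999 scale.
    rescale = max_score > 1.0
    out: list[EdgeRecord] = []
    dropped_loops = 0
    for lineno, a, b, score in records:
        if score is not None and rescale:
            score = score / 1000.0
        a, b = _norm_symbol(a), _norm_symbol(b)
        if a == b:
            dropped_loops += 1
            declared.add(a)  # the gene itself is still part of the universe
            continue
        out.append(EdgeRecord(a, b, score))
    return out, declared, dropped_loops


def _parse_tsv2col(path: Path) -> tuple[list[EdgeRecord], set[str], int]:
    out: list[EdgeRecord] = []
    declared: set[str] = set()
    dropped_loops = 0
    for lineno, line in _iter_lines(path):
        fields = line.split("\t")
        if len(fields) == 1:
            fields = line.split()
        if len(fields) == 1:
            declared.add(_norm_symbol(fields[0]))
            continue
        a, b = _norm_symbol(fields[0]), _norm_symbol(fields[1])
        if not a or not b:
            raise InputError(f"{path}:{lineno}: edge row with < 2 fields")
        if a == b:
            dropped_loops += 1
            declared.add(a)
            continue
        out.append(EdgeRecord(a, b))
    return out, declared, dropped_loops


def _parse_sif(path: Path) -> tuple[list[EdgeRecord], set[str], int]:
    """SIF rows: ``source relation target [target ...]`` or a lone node."""
    out: list[EdgeRecord] = []
    declared: set[str] = set()
    dropped_loops = 0
    for lineno, line in _iter_lines(path):
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) == 1:
            declared.add(_norm_symbol(fields[0]))
            continue
        if len(fields) == 2:
            raise InputError(
                f"{path}:{lineno}: SIF row needs source, relation and >= 1 target"
            )
        src = _norm_symbol(fields[0])
        for tgt in fields[2:]:
            tgt = _norm_symbol(tgt)
            if src == tgt:
                dropped_loops += 1
                declared.add(src)
                continue
            out.append(EdgeRecord(src, tgt))
    return out, declared, dropped_loops


def read_edge_list(
    path: str | Path,
    format: str = "tsv2col",
    min_score: float = DEFAULT_MIN_SCORE,
    name: str | None = None,
) -> Network:
    """Load a network from an edge-list file.

    Self-loops are dropped, reciprocal/duplicate rows collapse to one edge,
    and (for score-bearing formats) edges with confidence below ``min_score``
    are removed.  A parse summary is logged at INFO level.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    if format not in READ_FORMATS:
        raise ConfigurationError(
            f"unknown format {format!r}; expected one of {READ_FORMATS}"
        )
    if format == "graphml":
        try:
            g = nx.read_graphml(path)
        except Exception as exc:  # malformed XML etc.
            raise InputError(f"cannot parse GraphML {path}: {exc}") from exc
        return Network.from_networkx(g, name=name or path.stem)

    parser = {
        "string_tsv": _parse_string_tsv,
        "tsv2col": _parse_tsv2col,
        "sif": _parse_sif,
    }[format]
    records, declared, dropped_loops = parser(path)

    net = Network(name=name or path.stem)
    dropped_score = 0
    for rec in records:
        if rec.score is not None and rec.score < min_score:
            # the edge goes, but its endpoints stay in the gene universe
            dropped_score += 1
            net.add_node(rec.node_a)
            net.add_node(rec.node_b)
            continue
        net.add_edge(rec.node_a, rec.node_b)
    for node in declared:
        if node:
            net.add_node(node)
    logger.info(
        "read %s [%s]: %d nodes, %d edges kept; %d self-loop rows dropped, "
        "%d edges below min_score=%.2f dropped",
        path,
        format,
        net.n_nodes,
        net.n_edges,
        dropped_loops,
        dropped_score,
        min_score,
    )
    return net


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_network(net: Network, path: str | Path, format: str = "tsv2col") -> None:
    """Write ``net`` so that reading it back reproduces (nodes, edges).

    Isolated nodes are emitted as single-symbol lines (tsv2col, sif) or
    natively (graphml).  Output ordering is deterministic.
    """
    path = Path(path)
    if format not in WRITE_FORMATS:
        raise ConfigurationError(
            f"unknown format {format!r}; expected one of {WRITE_FORMATS}"
        )
    touched = {n for e in net.sorted_edges() for n in e}
    isolated = sorted(net.nodes - touched)
    try:
        if format == "tsv2col":
            lines = [f"{a}\t{b}" for a, b in net.sorted_edges()]
            lines += isolated
            path.write_text("\n".join(lines) + ("\n" if lines else ""))
        elif format == "sif":
            lines = [f"{a}\tinteracts\t{b}" for a, b in net.sorted_edges()]
            lines += isolated
            path.write_text("\n".join(lines) + ("\n" if lines else ""))
        else:  # graphml
            g = nx.Graph(name=net.name)
            g.add_nodes_from(net.sorted_nodes())
            g.add_edges_from(net.sorted_edges())
            nx.write_graphml(g, path)
    except OSError as exc:
        raise InputError(f"cannot write {path}: {exc}") from exc
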