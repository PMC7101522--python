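"""The sub-network cascade around a hub set.

Given the main component of an interactome and its selected hubs, this
module builds, in order:

1. the hubs-only sub-network (do the hubs interact among themselves?),
2. the neighborhood sub-network — hubs plus all of their direct neighbors,
3. the minimal hub core — the smallest hub subset whose neighborhood
   sub-network stays connected while still containing every hub
   (the "integrity" criterion), found by exhaustive subset enumeration,
4. the residual sub-network — main-component nodes outside the full
   neighborhood sub-network, with its own degree-based hub screen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

from .centrality import CentralityRecord, CentralityTable
from .graph import InputError, Network, induced_subgraph
from .hubs import HubSelection, select_hubs

logger = logging.getLogger(__name__)

#: Exhaustive core search enumerates 2^h subsets; refuse above this size
#: unless the caller raises the bound explicitly.
MAX_HUBS_EXHAUSTIVE = 20


@dataclass
class NeighborhoodSubnet:
    """Induced sub-network on a seed set plus its direct neighbors."""

    seeds: frozenset[str]
    nodes: frozenset[str]
    subgraph: Network

    @property
    def n_neighbors(self) -> int:
        return len(self.nodes - self.seeds)


@dataclass
class CoreSearchResult:
    """Minimal hub subset maintaining sub-network integrity."""

    core: list[str]
    excluded_hubs: list[str]
    subnet: NeighborhoodSubnet
    integrity_ok: bool
    coverage: float


@dataclass
class ResidualSubnet:
    """Main-component nodes outside the full-hub neighborhood sub-network."""

    nodes: frozenset[str]
    subgraph: Network
    hubs: HubSelection | None


def hub_subnet(main: Network, hubs: Iterable[str]) -> Network:
    """Induced sub-network on exactly the hub set."""
    hub_set = set(hubs)
    sub = induced_subgraph(main, hub_set)
    if len(hub_set) > 1 and sub.n_edges == 0:
        logger.warning("hub set of %d nodes has no mutual interactions", len(hub_set))
    return sub


def neighborhood_subnet(main: Network, seeds: Iterable[str]) -> NeighborhoodSubnet:
    """Seeds plus the union of their direct neighbors, induced in ``main``."""
    seed_set = frozenset(seeds)
    if not seed_set:
        raise InputError("empty seed set")
    unknown = seed_set - main.nodes
    if unknown:
        raise InputError(f"unknown seed node(s): {sorted(unknown)}")
    nodes = set(seed_set)
    for s in seed_set:
        nodes |= main.neighbors(s)
    return NeighborhoodSubnet(
        seeds=seed_set,
        nodes=frozenset(nodes),
        subgraph=induced_subgraph(main, nodes),
    )


def _integrity(main: Network, subset: frozenset[str], all_hubs: frozenset[str]):
    """Check the integrity criterion for a hub subset.

    (i) the induced sub-network on subset + neighbors is connected, and
    (ii) every hub — including those left out of the subset — is a member.
    Returns the NeighborhoodSubnet when both hold, else None.
    """
    sub = neighborhood_subnet(main, subset)
    if not all_hubs <= sub.nodes:
        return None
    if not sub.subgraph.is_connected():
        return None
    return sub


def minimal_core_search(
    main: Network,
    hubs: Sequence[str],
    max_hubs: int = MAX_HUBS_EXHAUSTIVE,
) -> CoreSearchResult:
    """Smallest hub subset whose neighborhood sub-network keeps integrity.

    Subsets are enumerated in order of increasing size; among passing
    subsets of the minimal size the winner maximizes coverage (fraction of
    the full-hub sub-network's nodes retained), with remaining ties broken
    toward the lexicographically smallest sorted symbol tuple.  If no
    subset passes — the full-hub neighborhood sub-network itself is
    disconnected — the full hub set is returned with ``integrity_ok``
    False.
    """
    hub_list = sorted(set(hubs))
    if not hub_list:
        raise InputError("empty hub list")
    unknown = set(hub_list) - main.nodes
    if unknown:
        raise InputError(f"unknown hub node(s): {sorted(unknown)}")
    if len(hub_list) > max_hubs:
        raise InputError(
            f"{len(hub_list)} hubs exceed the exhaustive-search bound "
            f"({max_hubs}); pass max_hubs explicitly to raise it"
        )
    all_hubs = frozenset(hub_list)
    full = neighborhood_subnet(main, all_hubs)
    full_size = len(full.nodes)

    for size in range(1, len(hub_list) + 1):
        best = None  # (coverage, sorted-symbols, subnet)
        for combo in combinations(hub_list, size):
            sub = _integrity(main, frozenset(combo), all_hubs)
            if sub is None:
                continue
            coverage = len(sub.nodes) / full_size
            key = (-coverage, tuple(combo))
            if best is None or key < best[0]:
                best = (key, combo, sub, coverage)
        if best is not None:
            _, combo, sub, coverage = best
            core = list(combo)
            return CoreSearchResult(
                core=core,
                excluded_hubs=[h for h in hub_list if h not in combo],
                subnet=sub,
                integrity_ok=True,
                coverage=coverage,
            )
    logger.warning(
        "no hub subset satisfies the integrity criterion (full-hub "
        "sub-network disconnected); returning the full hub set"
    )
    return CoreSearchResult(
        core=hub_list,
        excluded_hubs=[],
        subnet=full,
        integrity_ok=False,
        coverage=1.0,
    )


def residual_analysis(
    main: Network,
    full_subnet: NeighborhoodSubnet,
    k: float = 2.0,
    sd_mode: str = "sample",
) -> ResidualSubnet:
    """Sub-network of main-component nodes left out of ``full_subnet``,
    with its own degree-based mean + k*SD hub screen.

    The residual sub-network may be disconnected; degrees are taken within
    it.  An empty residual yields an empty result with a warning.
    """
    if not full_subnet.nodes <= main.nodes:
        raise InputError("full_subnet was not derived from this network")
    residual_nodes = main.nodes - full_subnet.nodes
    sub = induced_subgraph(main, residual_nodes)
    if not residual_nodes:
        logger.warning("residual sub-network is empty; nothing to screen")
        return ResidualSubnet(nodes=frozenset(), subgraph=sub, hubs=None)
    hubs = None
    if len(residual_nodes) >= 2:
        # degree screen over the residual graph; components analyzed jointly
        records = [
            CentralityRecord(
                node=n,
                degree=sub.degree(n),
                stress=0,
                avg_l=None,
                betweenness=0.0,
                closeness=None,
            )
            for n in sub.sorted_nodes()
        ]
        table = CentralityTable(records=records, graph_name="residual")
        hubs = select_hubs(table, metric="degree", k=k, sd_mode=sd_mode)
    return ResidualSubnet(nodes=frozenset(residual_nodes), subgraph=sub, hubs=hubs)
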