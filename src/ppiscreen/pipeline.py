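"""End-to-end screen: load -> decompose -> centrality -> hub selection ->
neighborhood sub-network -> minimal core search -> residual analysis.

``run_screen`` executes every stage on the main component and returns a
:class:`ScreenReport`; with an output directory it also writes the report
JSON, the centrality and hub TSV tables, and the three sub-networks.  All
orderings are fixed, so re-running on identical input is byte-identical.

``validate_report`` re-checks the report's internal arithmetic — component
census totals, seed/neighbor accounting, sub-network vs residual
conservation, core-membership splits, and gene membership in the input
universe — and returns the list of violated rules (empty when valid).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from . import __version__
from .centrality import CentralityTable, centrality_table
from .graph import (
    ConfigurationError,
    InputError,
    Network,
    decompose,
    induced_subgraph,
    read_edge_list,
    write_network,
)
from .hubs import select_hubs, selection_to_tsv
from .subnets import (
    hub_subnet,
    minimal_core_search,
    neighborhood_subnet,
    residual_analysis,
)

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict[str, Any] = {
    "min_score": 0.4,
    "small_max": 3,
    "hub": {"metric": "closeness", "k": 2.0, "sd_mode": "sample"},
    "residual": {"metric": "degree", "k": 2.0},
    "core": {"max_hubs": 20},
}


def resolve_config(overrides: dict | None = None) -> dict:
    """Deep-merge user overrides onto the defaults; reject unknown keys."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, value in (overrides or {}).items():
        if key not in cfg:
            raise ConfigurationError(f"unknown config key {key!r}")
        if isinstance(cfg[key], dict):
            if not isinstance(value, dict):
                raise ConfigurationError(f"config key {key!r} expects a mapping")
            for sub, sval in value.items():
                if sub not in cfg[key]:
                    raise ConfigurationError(f"unknown config key {key}.{sub}")
                cfg[key][sub] = sval
        else:
            cfg[key] = value
    return cfg


@dataclass
class ScreenReport:
    """Machine-readable record of one full screen."""

    data: dict[str, Any] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.data, indent=2, sort_keys=True) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "ScreenReport":
        try:
            data = json.loads(text)
        except json.JSONDecodeError as exc:
            raise InputError(f"malformed report JSON: {exc}") from exc
        if not isinstance(data, dict):
            raise InputError("report JSON must be an object")
        return cls(data=data)


def _network_hash(net: Network) -> str:
    h = hashlib.sha256()
    for n in net.sorted_nodes():
        h.update(n.encode())
        h.update(b"\n")
    for a, b in net.sorted_edges():
        h.update(f"{a}\t{b}\n".encode())
    return h.hexdigest()


def run_screen(
    net: Network,
    config: dict | None = None,
    outdir: str | Path | None = None,
    provenance: dict | None = None,
) -> ScreenReport:
    """Run every stage of the screen on ``net``; optionally write outputs.

    An empty hub selection short-circuits the sub-network stages: the
    report then carries explicit ``"not run"`` markers instead of results.
    """
    cfg = resolve_config(config)
    report: dict[str, Any] = {
        "tool": {"name": "ppiscreen", "version": __version__},
        "config": cfg,
        "provenance": dict(provenance or {}),
        "network": {
            "name": net.name,
            "n_nodes": net.n_nodes,
            "n_edges": net.n_edges,
            "nodes": net.sorted_nodes(),
            "sha256": _network_hash(net),
        },
    }

    logger.info("stage: decompose (%d nodes, %d edges)", net.n_nodes, net.n_edges)
    census = decompose(net, small_max=cfg["small_max"])
    report["census"] = census.sizes
    main = induced_subgraph(net, census.main_component)
    main.name = f"{net.name}:main" if net.name else "main"

    logger.info("stage: centrality (main component, %d nodes)", main.n_nodes)
    table = centrality_table(main)

    logger.info("stage: hub selection (%s, k=%s)", cfg["hub"]["metric"], cfg["hub"]["k"])
    sel = select_hubs(
        table,
        metric=cfg["hub"]["metric"],
        k=cfg["hub"]["k"],
        sd_mode=cfg["hub"]["sd_mode"],
    )
    report["hub_selection"] = {
        "metric": sel.metric,
        "k": sel.k,
        "mean": sel.mean,
        "sd": sel.sd,
        "cutoff": sel.cutoff,
        "hubs": sel.hubs,
        "n_candidates": sel.n_candidates,
    }

    subnet_hub = subnet_full = core_res = residual = None
    if sel.is_empty:
        logger.warning("empty hub selection; sub-network stages skipped")
        report["subnet"] = "not run (empty hub selection)"
        report["core"] = "not run (empty hub selection)"
        report["residual"] = "not run (empty hub selection)"
    else:
        logger.info("stage: sub-networks (%d hubs)", len(sel.hubs))
        subnet_hub = hub_subnet(main, sel.hubs)
        subnet_full = neighborhood_subnet(main, sel.hubs)
        report["subnet"] = {
            "n_seeds": len(subnet_full.seeds),
            "n_neighbors": subnet_full.n_neighbors,
            "n_nodes": len(subnet_full.nodes),
            "hub_subnet_edges": subnet_hub.n_edges,
        }

        logger.info("stage: minimal core search")
        core_res = minimal_core_search(main, sel.hubs, max_hubs=cfg["core"]["max_hubs"])
        core_set = set(core_res.core)
        excluded_present = [
            h for h in core_res.excluded_hubs if h in core_res.subnet.nodes
        ]
        n_nodes = len(core_res.subnet.nodes)
        n_excl = len(excluded_present)
        report["core"] = {
            "core": core_res.core,
            "excluded_hubs": core_res.excluded_hubs,
            "integrity_ok": core_res.integrity_ok,
            "coverage": core_res.coverage,
            "n_core": len(core_res.core),
            "n_nodes": n_nodes,
            "n_excluded_present": n_excl,
            "n_plain_neighbors": n_nodes - len(core_set) - n_excl,
            "n_non_seed": n_nodes - len(core_set),
        }

        logger.info("stage: residual analysis")
        residual = residual_analysis(
            main, subnet_full, k=cfg["residual"]["k"], sd_mode=cfg["hub"]["sd_mode"]
        )
        report["residual"] = {
            "n_nodes": len(residual.nodes),
            "n_edges": residual.subgraph.n_edges,
            "hubs": residual.hubs.hubs if residual.hubs else [],
            "cutoff": residual.hubs.cutoff if residual.hubs else None,
            "metric": cfg["residual"]["metric"],
        }

    out = ScreenReport(data=report)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(out.to_json())
        (outdir / "centrality.tsv").write_text(table.to_tsv())
        (outdir / "hubs.tsv").write_text(selection_to_tsv(sel))
        if subnet_hub is not None:
            for label, sub in (
                ("subnet_hubs", subnet_hub),
                ("subnet_core", core_res.subnet.subgraph),
                ("residual", residual.subgraph),
            ):
                write_network(sub, outdir / f"{label}.tsv", "tsv2col")
                write_network(sub, outdir / f"{label}.graphml", "graphml")
    return out


def run_screen_file(
    path: str | Path,
    format: str = "tsv2col",
    config: dict | None = None,
    outdir: str | Path | None = None,
) -> ScreenReport:
    """Load an edge-list file and run the full screen on it."""
    cfg = resolve_config(config)
    net = read_edge_list(path, format=format, min_score=cfg["min_score"])
    prov = {"input": str(path), "format": format}
    return run_screen(net, config=config, outdir=outdir, provenance=prov)


# ---------------------------------------------------------------------------
# Report validation
# ---------------------------------------------------------------------------


def _get(data: dict, *keys):
    cur: Any = data
    for k in keys:
        if not isinstance(cur, dict) or k not in cur:
            return None
        cur = cur[k]
    return cur


def validate_report(report: ScreenReport | dict) -> list[str]:
    """Check a report's internal consistency; return violated rule names.

    Rules (each checked only when the report carries the fields involved,
    so partial, count-only reports are validatable):

    - ``census_total``: isolated + sum(small) + main + sum(other) = total.
    - ``subnet_accounting``: seeds + neighbors = sub-network size.
    - ``node_conservation``: sub-network size + residual size = main size.
    - ``core_members``: core + excluded-present + plain neighbors = core
      sub-network size.
    - ``core_non_seed``: excluded-present + plain neighbors = non-seed
      member count.
    - ``gene_membership``: every gene named anywhere in the report occurs
      in the input node universe (needs ``network.nodes``).
    """
    data = report.data if isinstance(report, ScreenReport) else report
    if not isinstance(data, dict):
        raise InputError("report must be a mapping")
    violations: list[str] = []

    census = _get(data, "census")
    if isinstance(census, dict) and census.get("total") is not None:
        total = (
            census.get("isolated", 0)
            + sum(census.get("small", []))
            + census.get("main", 0)
            + sum(census.get("other", []))
        )
        if total != census["total"]:
            violations.append("census_total")

    sub = _get(data, "subnet")
    if isinstance(sub, dict) and {"n_seeds", "n_neighbors", "n_nodes"} <= sub.keys():
        if sub["n_seeds"] + sub["n_neighbors"] != sub["n_nodes"]:
            violations.append("subnet_accounting")

    res = _get(data, "residual")
    if (
        isinstance(sub, dict)
        and isinstance(res, dict)
        and isinstance(census, dict)
        and sub.get("n_nodes") is not None
        and res.get("n_nodes") is not None
        and census.get("main") is not None
    ):
        if sub["n_nodes"] + res["n_nodes"] != census["main"]:
            violations.append("node_conservation")

    core = _get(data, "core")
    if isinstance(core, dict):
        if {"n_core", "n_excluded_present", "n_plain_neighbors", "n_nodes"} <= core.keys():
            if (
                core["n_core"] + core["n_excluded_present"] + core["n_plain_neighbors"]
                != core["n_nodes"]
            ):
                violations.append("core_members")
        if {"n_excluded_present", "n_plain_neighbors", "n_non_seed"} <= core.keys():
            if (
                core["n_excluded_present"] + core["n_plain_neighbors"]
                != core["n_non_seed"]
            ):
                violations.append("core_non_seed")

    universe = _get(data, "network", "nodes")
    if isinstance(universe, list):
        known = set(universe)
        named: set[str] = set()
        named.update(_get(data, "hub_selection", "hubs") or [])
        if isinstance(core, dict):
            named.update(core.get("core", []))
            named.update(core.get("excluded_hubs", []))
        if isinstance(res, dict):
            named.update(res.get("hubs", []))
        if named - known:
            violations.append("gene_membership")

    return violations
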