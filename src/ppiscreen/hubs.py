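"""Statistical hub selection: mean + k*SD cutoff over a centrality column.

A node is a hub when its metric value lies strictly above
``mean + k * SD`` of the metric over the candidate population.  The default
multiplier k = 2 is the conventional "top nodes" cutoff for closeness in
PPI screening; the SD uses the sample (n-1) denominator by default, with a
population-SD switch for tools that normalize by n.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .centrality import CentralityTable
from .graph import ConfigurationError, InputError

logger = logging.getLogger(__name__)

HUB_METRICS = ("closeness", "degree")


@dataclass
class HubSelection:
    """Outcome of a mean + k*SD screen over one centrality column."""

    metric: str
    k: float
    mean: float
    sd: float
    cutoff: float
    hubs: list[str]
    n_candidates: int
    values: dict[str, float] = field(default_factory=dict, repr=False)

    @property
    def is_empty(self) -> bool:
        return not self.hubs


def compute_cutoff(
    values: list[float], k: float = 2.0, sd_mode: str = "sample"
) -> tuple[float, float, float]:
    """(mean, sd, cutoff) with cutoff = mean + k * sd.

    ``sd_mode`` selects the sample (n-1 denominator, default) or population
    (n denominator) standard deviation.
    """
    if len(values) < 2:
        raise InputError(f"need >= 2 values to compute a cutoff, got {len(values)}")
    if sd_mode not in ("sample", "population"):
        raise ConfigurationError(f"sd_mode must be sample|population, got {sd_mode!r}")
    n = len(values)
    mean = sum(values) / n
    ss = sum((v - mean) ** 2 for v in values)
    denom = n - 1 if sd_mode == "sample" else n
    sd = math.sqrt(ss / denom)
    return mean, sd, mean + k * sd


def select_hubs(
    table: CentralityTable,
    metric: str = "closeness",
    k: float = 2.0,
    sd_mode: str = "sample",
) -> HubSelection:
    """Select every node whose ``metric`` is strictly above mean + k*SD.

    Hubs are ordered metric-descending, ties broken by symbol.  An empty
    selection (e.g. a perfectly homogeneous component) is legal and logged
    as a warning, not an error.
    """
    if metric not in HUB_METRICS:
        raise ConfigurationError(
            f"unknown hub metric {metric!r}; expected one of {HUB_METRICS}"
        )
    if len(table) == 0:
        raise InputError("empty centrality table")
    values = {}
    for rec in table:
        v = getattr(rec, metric)
        if v is None:
            raise InputError(f"metric {metric!r} undefined for node {rec.node!r}")
        values[rec.node] = float(v)
    mean, sd, cutoff = compute_cutoff(list(values.values()), k=k, sd_mode=sd_mode)
    hubs = sorted(
        (n for n, v in values.items() if v > cutoff),
        key=lambda n: (-values[n], n),
    )
    if not hubs:
        logger.warning(
            "hub selection empty: no %s value above cutoff %.4f "
            "(mean %.4f, sd %.4f, k %.2f)",
            metric,
            cutoff,
            mean,
            sd,
            k,
        )
    return HubSelection(
        metric=metric,
        k=k,
        mean=mean,
        sd=sd,
        cutoff=cutoff,
        hubs=hubs,
        n_candidates=len(values),
        values=values,
    )


def selection_to_tsv(sel: HubSelection) -> str:
    """Hub table as TSV: node, metric value, cutoff, mean, sd."""
    lines = [f"node\t{sel.metric}\tcutoff\tmean\tsd"]
    for n in sel.hubs:
        lines.append(
            f"{n}\t{sel.values[n]:.6g}\t{sel.cutoff:.6g}\t{sel.mean:.6g}\t{sel.sd:.6g}"
        )
    return "\n".join(lines) + "\n"
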