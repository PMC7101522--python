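"""The sub-network cascade: neighborhood subnet, minimal core, residual.

Starting from selected hubs, builds the hubs+neighbors sub-network, finds
the smallest hub combination that keeps that sub-network's integrity
(connected, all hubs retained), and screens the left-over residual
sub-network for degree hubs.
"""

from ppiscreen import (
    GeneratorConfig,
    centrality_table,
    decompose,
    generate,
    induced_subgraph,
    minimal_core_search,
    neighborhood_subnet,
    residual_analysis,
    select_hubs,
)

net, _ = generate(GeneratorConfig(seed=1))
main = induced_subgraph(net, decompose(net).main_component)
hubs = select_hubs(centrality_table(main), k=2.0).hubs
print(f"hubs: {hubs}")

subnet = neighborhood_subnet(main, hubs)
print(f"hubs+neighbors sub-network: {len(subnet.nodes)} nodes "
      f"({len(subnet.seeds)} seeds + {subnet.n_neighbors} neighbors)")

core = minimal_core_search(main, hubs)
print(f"minimal core: {core.core} (excluded: {core.excluded_hubs}, "
      f"coverage {core.coverage:.2f}, integrity_ok={core.integrity_ok})")

residual = residual_analysis(main, subnet, k=2.0)
print(f"residual sub-network: {len(residual.nodes)} nodes; "
      f"degree hubs: {residual.hubs.hubs if residual.hubs else []}")
# Node conservation holds by construction: neighborhood + residual nodes
# partition the main component.  The excluded hubs survive inside the
# core's sub-network as neighbors of the core genes.
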