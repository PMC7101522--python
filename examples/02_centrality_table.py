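"""Compute the per-gene centrality table of a small connected network.

The table carries the screening statistics for each node: degree, stress
(geodesics through the node), average shortest-path length avg_L,
normalized betweenness, and closeness = 1/avg_L.
"""

from ppiscreen import Network, centrality_table

# a hub (FOS) over four partners, one of which extends into a chain
net = Network(edges=[
    ("FOS", "IL6"), ("FOS", "TNF"), ("FOS", "TAC1"), ("FOS", "KNG1"),
    ("IL6", "TNF"), ("KNG1", "BDKRB1"), ("BDKRB1", "BDKRB2"),
])

table = centrality_table(net)
print(table.to_tsv())
# Rows are sorted by closeness, descending: FOS reaches every other gene
# fastest (highest closeness, most geodesics through it), while the
# chain-end BDKRB2 is the most peripheral.  closeness * avg_L = 1 for
# every row, at full precision.
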