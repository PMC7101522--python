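"""Load a STRING-style edge export and take a component census.

Builds a tiny confidence-scored edge list in a temp directory, loads it
with the medium-confidence filter (0.4), and partitions the resulting
graph into isolated genes, small components, and the main component.
"""

import tempfile
from pathlib import Path

from ppiscreen import decompose, read_edge_list

rows = [
    ("FOS", "IL6", 0.92), ("IL6", "TNF", 0.88), ("FOS", "TNF", 0.81),
    ("FOS", "JUN", 0.95), ("TAC1", "KNG1", 0.74), ("TAC1", "FOS", 0.66),
    ("GCH1", "SPR", 0.90), ("SPR", "PTS", 0.85), ("GCH1", "PTS", 0.82),
    ("OPRM1", "PENK", 0.35),  # below the confidence cutoff: edge dropped
]
with tempfile.TemporaryDirectory() as d:
    path = Path(d) / "export.tsv"
    lines = ["node1\tnode2\tcombined_score"]
    lines += [f"{a}\t{b}\t{s}" for a, b, s in rows]
    lines += ["TRPV1"]  # declared node with no kept interaction
    path.write_text("\n".join(lines) + "\n")

    net = read_edge_list(path, format="string_tsv", min_score=0.4)
    census = decompose(net, small_max=3)

print(f"loaded: {net.n_nodes} genes, {net.n_edges} interactions")
print(f"census: {census.sizes}")
print(f"main component: {sorted(census.main_component)}")
# The low-confidence OPRM1-PENK edge is filtered, so those genes join
# TRPV1 as isolated nodes; the GCH1/SPR/PTS triangle is a "small"
# component; the FOS-centered cluster is the main component that the
# downstream screening stages would analyze.
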