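"""One-call pipeline: generate, screen, and validate the report.

Equivalent to the `ppiscreen screen` CLI; the report JSON carries every
stage's counts plus provenance, and validate_report re-checks its
internal arithmetic.
"""

import json

from ppiscreen import GeneratorConfig, generate, run_screen, validate_report

net, planted = generate(GeneratorConfig(seed=1))
report = run_screen(net)

data = report.data
print("census:", data["census"])
print("hubs:", data["hub_selection"]["hubs"])
print("subnet:", data["subnet"])
print("core:", data["core"]["core"], "excluded:", data["core"]["excluded_hubs"])
print("residual genes:", data["residual"]["n_nodes"],
      "residual hubs:", data["residual"]["hubs"])
print("violations:", validate_report(report))
# An empty violation list means the report's arithmetic is self-consistent
# (census totals, seed/neighbor accounting, subnet+residual = main, core
# membership splits, and gene membership in the input universe).
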