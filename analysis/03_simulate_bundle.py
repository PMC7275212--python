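#!/usr/bin/env python
"""Generate the default synthetic input bundle with planted ground truth.

Writes ingredient, compound-target, disease-target, PPI-edge and GMT
files plus the ground-truth JSON under results/synthetic/bundle.  The
bundle mirrors the target study scale: 3 herbs x 15 ingredients, half
passing the ADME screen, ~50 % herb/disease target overlap, an
Erdős–Rényi PPI over the overlap, and one planted enriched term
(20 hub-destined genes in a 40-gene term).
"""

import json
from pathlib import Path

from netpharm import SynthesisConfig, write_bundle

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic" / "bundle"

cfg = SynthesisConfig(seed=12345)
truth = write_bundle(cfg, OUT)

print(f"bundle written to {OUT}")
print(f"ADME pass counts : {json.dumps(truth['adme_pass_counts'], sort_keys=True)}")
print(f"herb target sets : {json.dumps(truth['herb_target_counts'], sort_keys=True)}")
print(f"planted key targets: {len(truth['planted_overlap'])}")
print(f"PPI: {truth['ppi_nodes']} nodes, {truth['ppi_edges']} scored edges")
print(f"planted terms    : {truth['planted_term_ids']}")
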