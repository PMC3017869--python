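"""Regions of difference and the translational-start gene-calling rule.

Runs of >= 3 consecutive absent probes form regions of difference;
shorter runs are tallied but never call genes. A gene is absent iff its
strand-aware start codon coordinate falls inside a region.
"""

import pandas as pd

from cghkit import regions
from cghkit.simulate import GeneAnnotation

# a hand-built track: one single, one double, and one 4-probe region
calls = [1, 0, 1, 1, 0, 0, 1, 0, 0, 0, 0, 1, 1]
starts = [1 + 30 * i for i in range(len(calls))]
track = pd.DataFrame({"probe_id": [f"P{i}" for i in range(len(calls))],
                      "start": starts, "end": [s + 59 for s in starts],
                      "call": calls})
runs = regions.find_runs(track)
print(f"singles={len(runs.singles)} doubles={len(runs.doubles)} "
      f"regions={len(runs.regions)}")
region = runs.regions[0]
print(f"region of difference: {region.start}-{region.end} "
      f"({region.probe_count} probes)")

genes = [
    GeneAnnotation("start_in_region", region.start + 10, region.end + 400, "+"),
    GeneAnnotation("body_in_region_only", region.start - 200, region.end + 50, "+"),
]
out = regions.call_genes(runs.regions, genes)
print(out[["gene_id", "translational_start", "call"]].to_string(index=False))
# Only the gene whose translational start lies inside the region is
# called absent; a gene merely overlapping the region stays present.
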