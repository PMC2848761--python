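"""Re-apply the screening rules to the published tables shipped with the package.

The embedded tables carry the printed means, ratios, p-values and count pairs
from the original NIL study, so the thresholds can be audited end to end
without any external data.
"""

import math

import numpy as np

from seedqtl import datasets
from seedqtl.htts import binomial_p
from seedqtl.region import Marker, demarcate_region

# region span from the border markers
(c1, p1), (c2, p2) = datasets.QTL_BORDER_MARKERS.values()
region = demarcate_region([
    Marker(name="left", chromosome=c1, position=p1,
           polymorphic=False, segregating=False),
    Marker(name="mid", chromosome=c1, position=(p1 + p2) // 2,
           polymorphic=True, segregating=True),
    Marker(name="right", chromosome=c2, position=p2,
           polymorphic=False, segregating=False),
])
print(f"QTL region: {region.chromosome}:{region.start}-{region.end} "
      f"= {region.span_bp / 1e6:.2f} Mbp")

# genotype-contrast screen
geno = datasets.genotype_contrast_table()
either_fold = np.maximum(geno["ratio"], 1.0 / geno["ratio"])
n_pass = int(((either_fold >= 1.5) & (geno["fdr"] <= 0.05)).sum())
print(f"genotype contrast: {n_pass}/{len(geno)} probesets pass 1.5-fold + FDR; "
      f"{int((either_fold >= 4.0).sum())} reach 4-fold")

# read-count screen on the printed count pairs
htts = datasets.htts_de_table()
n_sig = sum(
    binomial_p(min(r.count_a, r.count_b), max(r.count_a, r.count_b)) <= 0.001
    and (math.inf if min(r.count_a, r.count_b) == 0
         else max(r.count_a, r.count_b) / min(r.count_a, r.count_b)) >= 2.0
    for r in htts.itertuples()
)
print(f"read-count screen: {n_sig}/{len(htts)} comparisons significant, "
      f"{htts['gene'].nunique()} distinct genes")

# per-library totals of the most expressed region genes
expr = datasets.top_expressed_table()
libs = ["A1", "A2", "A3", "A4", "B1", "B2", "B3", "B4"]
assert (expr[libs].sum(axis=1) == expr["total"]).all()
print(f"top expressed gene: {expr['gene'].iloc[0]} "
      f"(total {int(expr['total'].iloc[0])} reads across 8 libraries)")
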