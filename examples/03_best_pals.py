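"""Stringency filtering and the Best-PAL selection.

Simulates a corpus, keeps only PALs whose primers are unique in the read
library (the most stringent product-of-counts criterion at cutoff 1), and
then applies the Best-PAL rules: motif length 4-6 and strictly more than
7 repeat units -- the loci most likely to amplify one locus and to be
polymorphic.
"""

from palfinder import ScanConfig, best_pals, filter_pals, run_pipeline
from palfinder.simdata import PlantingPlan, simulate_corpus

plan = PlantingPlan(n_fragments=600, ssr_density=0.5, seed=3)
pairs, _ = simulate_corpus(plan)
cfg = ScanConfig()
result = run_pipeline(pairs, cfg)

pals = result.pals
strict = filter_pals(pals, "product", 1)
chosen = best_pals(pals, cfg)
print(f"PALs: {len(pals)}")
print(f"both primers unique (product = 1): {len(strict)}")
print(f"Best PALs (4-6mer motif, >7 units, unique primers): {len(chosen)}")
for rec in chosen[:5]:
    print(f"  {rec.read_id}: {rec.motifs_str}")
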