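"""Scan a single-end read set for microsatellites and summarize the yield.

Builds a small synthetic 454-style corpus with repeats planted in 30% of
reads, scans it, and prints the corpus-level statistics: how many reads
carry an SSR, the locus density per megabase, and the motif-length
spectrum.  On real data the same numbers say whether a library is worth
deeper sequencing for marker development.
"""

from palfinder import Platform, ScanConfig, run_pipeline
from palfinder.simdata import PlantingPlan, simulate_corpus

plan = PlantingPlan(
    n_fragments=400, ssr_density=0.3, platform=Platform.SE_454,
    read_len=250, seed=1,
)
reads, truth = simulate_corpus(plan)
cfg = ScanConfig(platform=Platform.SE_454, design_primers=False)
result = run_pipeline(reads, cfg)

s = result.summary
print(f"reads scanned:        {s.n_reads}")
print(f"megabases:            {s.megabases:.3f}")
print(f"reads with >=1 SSR:   {s.reads_with_ssrs}  (planted: {len(truth)})")
print(f"total loci:           {s.total_loci}")
print(f"loci per Mbp:         {s.loci_per_mbp:.1f}")
print(f"motif-length spectrum: {dict(sorted(s.per_k.items()))}")
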