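# palfinder

Microsatellite discovery, flanking PCR-primer design, and empirical primer
copy-number annotation, directly from raw shotgun sequencing reads — no
assembly, no enrichment, no reference genome.

## The problem

Simple sequence repeats (SSRs, microsatellites) — tandem arrays of 2–6 bp
units such as (AC)₁₂ or (AATG)₈ — are the workhorse length-polymorphism
markers of population genetics, linkage mapping, and wildlife forensics.
Developing them from a non-model organism used to require enriched
libraries, cloning, and Sanger sequencing. A cheaper route is to shotgun
sequence a small fraction of the genome and mine the raw reads directly:
any read that contains a perfect repeat *and* enough clean flanking
sequence for a PCR primer pair is a **potentially amplifiable locus
(PAL)**. Because the read set is a random sample of the genome, it also
doubles as an empirical reference for asking whether a candidate primer is
locus-specific: a primer whose sequence recurs across the library likely
sits in repetitive DNA and will mis-amplify.

`palfinder` implements this "reads-to-markers" pipeline for single-end
(454-style) and paired-end (Illumina-style) libraries:

1. **Scan** — find every maximal perfect 2–6mer tandem array meeting the
   detection thresholds (≥ 12 bp of complete units for 2–4mers; ≥ 3 units
   for 5–6mers). Units related by cyclic rotation or reverse complement
   (TG ≡ CA; TGG ≡ GTG ≡ GGT) are grouped under one canonical motif, giving
   4 / 10 / 33 / 102 / 350 classes for k = 2…6. Reads with multiple arrays
   are classed *compound* (different motifs) or *broken* (same motif);
   paired-end fragments whose repeat runs through the unsequenced insert
   gap are flagged *spanning*.
2. **Design** — mask low-complexity flanks, then choose one primer pair per
   read (or pair) satisfying: GC > 30 %; Tm 58–65 °C with ≤ 2 °C pair
   difference; a 3′ GC clamp of 2 bases; no homopolymer > 4 bp; plus
   self-complementarity limits. Among conforming pairs, the pair that
   brackets the most repeat units wins, ties broken by a Tm/length penalty.
   Paired mates are joined into a pseudo-template padded with N to the
   assumed insert size (default 325 bp), so a pair may straddle both mates.
3. **Annotate** — count each primer's exact occurrences (both strands,
   overlaps included) across the whole read library, and each pair's
   co-occurrences in amplifiable orientation, yielding five statistics per
   PAL: `fwd_count`, `rev_count`, `min`, `product = fwd × rev`, and
   `pair_count`.
4. **Filter** — three nested stringency criteria (`product` ≤ c, `min` ≤ c,
   `pair` ≤ c; most → least stringent) and a "Best PALs" selection
   (4–6mer motif, > 7 repeat units, copy criterion at cutoff 1) reduce
   thousands of candidates to a high-confidence marker panel.

A synthetic-data module (`palfinder.simdata`) generates single- or
paired-end corpora with planted repeats, clean unique flanks, controlled
duplication (known copy numbers), and an exact truth table, so the whole
pipeline is testable without any downloads.

## Worked example

```python
from palfinder import ScanConfig, run_pipeline, stringency_classes
from palfinder.simdata import PlantingPlan, simulate_corpus

plan = PlantingPlan(n_fragments=400, ssr_density=0.3, seed=2)
pairs, truth = simulate_corpus(plan)      # paired-end, 325 bp inserts
result = run_pipeline(pairs, ScanConfig())
```

Running `examples/02_full_pipeline_paired_end.py` (the script version of
the above) prints:

```
read pairs: 402   SSR-bearing pairs: 133
PALs (primer pair found): 84
PAL rate: 0.632
stringency product : {'=1': 84, '=2': 0, '>2': 0}
stringency min     : {'=1': 84, '=2': 0, '>2': 0}
stringency pair    : {'=1': 84, '=2': 0, '>2': 0}

example PAL frag00010: AG(6) [perfect]
  fwd AGGGTTTGCTTGCGCCTTCG  Tm 60.36C  GC 60%
  rev AGTAATGCTCGCTCCTCCGCC  Tm 60.55C  GC 62%
  product ~266 bp, penalty 0.88
  copy counts fwd/rev/min/product/pair: 1/1/1/1/1
```

133 of 402 simulated read pairs carry a detectable repeat; for 84 of them
(63 %) a conforming primer pair exists, and — because the simulated flanks
are unique by construction — every primer occurs exactly once in the
library, the ideal "both primers unique" case a marker developer filters
for. The `AG(6)` row shows one locus: an (AG)₆ dinucleotide array with its
designed primers, their thermodynamics, the expected product size on the
325 bp insert, and the five copy statistics.

The same pipeline is available from the shell:

```bash
palfinder simulate --n 400 --density 0.3 --seed 2 --out-prefix sim
palfinder run --reads1 sim_1.fasta --reads2 sim_2.fasta \
              --platform illumina --out pal_table.tsv
palfinder filter --table pal_table.tsv --criterion product --cutoff 1 \
                 --best-pals --out best.tsv
```

The output is a tab-delimited table (one row per SSR-bearing read/pair)
with the motifs, class, primer sequences and thermodynamics, and the five
copy-number statistics; see `examples/` for more narrative walk-throughs
(scanning only, Best-PAL selection, gap-spanning repeats).

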