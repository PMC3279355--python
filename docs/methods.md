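# Methods

This note documents the models, conventions, and numerical choices behind
`palfinder`, and what the synthetic-data tests do and do not demonstrate.

## Repeat model and canonicalization

A microsatellite is modelled as a **maximal perfect tandem array** of a
primitive 2–6 bp unit: no mismatches or indels inside the array, and the
array cannot be extended by one more unit base on either side. Partial
trailing units are excluded, so a locus spans exactly `units × k` bases and
`units` is the integer count of complete copies; on paired-end data this is
a lower bound on the true allele length whenever the repeat continues past
the read or through the insert gap.

Two conventions make motif accounting deterministic:

* **Canonical motif** — the lexicographic minimum over the 2k strings
  {rotations of the unit} ∪ {rotations of its reverse complement}. This
  groups strand and phase variants (TG/CA; TGG/GTG/GGT) into one class and
  yields 4, 10, 33, 102, 350 classes for k = 2…6 (the last three verified
  in-tree by exhaustive orbit enumeration).
* **Primitive units only** — a unit that is itself a tandem repeat of a
  shorter unit (ACAC, AAA…) has no class of its own; (AT)₈ is reported once
  at k = 2, never as a 4mer, and homopolymers are never SSRs (the minimum
  unit length is 2). Without this rule the per-k class counts above would
  not add up.

The scanner finds, for each period k, maximal runs of the self-match
predicate `s[i] == s[i+k]` (N never matches anything, including N), which
yields each maximal periodic region exactly once, at its leftmost
complete-unit start. An independent per-position brute-force detector in
the test suite must agree exactly on 1,000 random 200-mers and a panel of
adversarial strings (homopolymers, phase-shifted runs, abutting arrays).

**Detection thresholds** (configurable): total array length ≥ 12 bp for
k = 2–4 (i.e. 6/4/3 units) and ≥ 3 units for k = 5–6. These are the
standard marker-development settings; at these thresholds random
GC-balanced sequence almost never produces a false array, which the
zero-density simulation test exercises.

**Multi-locus reads.** A read with ≥ 2 arrays of different canonical motifs
is *compound*; with the same motif, *broken* (the two runs are reported
separately, never merged across the interruption). In paired-end mode the
classification is per mate. A *spanning* pair has loci of the same
canonical motif ending within `spanning_end_tolerance` bases (default 0,
i.e. touching) of both mates' 3′ termini — both 3′ ends face the insert
interior, so the repeat most plausibly continues through the gap. The
tolerance default is strict because the fragment-interior criterion is
qualitative; it is a config knob, and the tolerance-sensitivity test shows
its effect.

## Primer design

Flanks are first masked for low complexity: every tandem run (unit 2–6 bp)
meeting the detection thresholds, every homopolymer ≥ 5 bp, every N, the
target arrays themselves, and optionally user-supplied motifs. The 5 bp
homopolymer cutoff is the masking analogue of the "no poly-N > 4 inside a
primer" rule. Masking restricts primer placement only; products may cross
masked bases.

Candidate primers are every unmasked 18–27 nt window (optimum 20), in both
orientations, that passes all of:

1. GC content strictly > 30 %;
2. Tm ∈ [58, 65] °C (pairs additionally ≤ 2 °C apart);
3. last two 3′ bases ∈ {G, C};
4. no homopolymer > 4 nt;
5. self-complementarity (aligned-base counting against the primer's own
   reverse): any-alignment matches ≤ 8, 3′-anchored contiguous matches ≤ 3.

Tm is nearest-neighbor thermodynamics with the SantaLucia unified doublet
parameters, 50 mM monovalent cation, 50 nM annealing oligo, and the
SantaLucia entropy salt correction (computed via Biopython's
`MeltingTemp.Tm_NN`; a hand-computed oracle from the published table pins
the values in the tests to ± 0.5 °C).

Among valid pairs whose product lies in `product_size_range` (default
100–450 bp) and brackets at least one target array without overlapping it,
selection is lexicographic: **(1) maximum total repeat units bracketed —
the biologically operative criterion, since more visible units means a more
informative marker — (2) minimum penalty, (3) leftmost forward primer, (4)
leftmost reverse end** (the last two only to make ties deterministic). The
penalty is `|Tm−60.5|` per primer (weight 1.0) + `|len−20|` per primer
(weight 0.5) + pair Tm difference (weight 1.0); any monotone score over the
same criteria would do, so the exact weights are a documented contract
rather than a tuned quantity, and lower is defined as better.

**Paired-end pseudo-template.** mate1 + N·gap + revcomp(mate2), with
`gap = max(0, assumed_insert_size − len1 − len2)` (default insert 325 bp;
114 bp reads give a 97 bp gap). Primers can never contain N, hence never
overlap the gap; a pair with one primer per mate is flagged
`spans_insert_gap`, and its product estimate inherits the insert-size
assumption built into the template coordinates.

## Copy-number statistics

The read library itself approximates genomic copy number. Per primer:
exact, case-insensitive, ungapped substring occurrences of the primer and
its reverse complement over every read, overlaps included (a palindromic
primer is counted once per site). Exactness — no mismatch tolerance — keeps
the statistic reproducible and library-indexable; it is a counting
statistic, not an alignment. Per pair: the number of library units (read
pair, or single read) containing both primers in amplifiable orientation —
within one read, the forward primer with the reverse primer's reverse
complement starting at or downstream of it (or the strand-mirrored
arrangement); across mates, the forward primer in one mate and the reverse
primer in the other, each as stored. The within-one-read clause is a
deliberate superset of the across-mate count: a single read showing both
convergent primer sites is equally strong evidence of proximity.

Since every primer occurs at its own source locus, `pair ≤ min ≤ product`
pointwise, so at cutoff 1 the three stringency filters nest
(product ⊆ min ⊆ pair); the annotation warns if a library is passed that
does not contain the source reads (counts of 0 violate the model).

Counting is implemented as substring scans over one concatenated,
separator-joined text; tests require exact agreement with naive per-read,
per-offset oracles on ~10,000-read corpora.

## Best PALs

Motif length within [4, 6] (longer units are easier to score on a gel or
capillary), strictly more than 7 complete units (units ≥ 8; longer arrays
are more mutable, hence more polymorphic), and the configured copy
criterion (default `product`) equal to 1. For compound reads the judged
locus is the bracketed array with the most units (falling back to all the
read's arrays when no primer pair exists); the choice of the largest array
is this package's documented convention for multi-array reads.

## Synthetic corpora

The generator emulates the library geometry used for Illumina-based marker
discovery: 325 bp fragments, 114 bp mates (configurable), i.i.d. background
with configurable GC. Planting defaults: density 0.1 (the order of the
SSR-read fraction seen in squamate shotgun data; bird genomes run several
fold lower), per-k motif-length frequencies shaped like an observed shotgun
spectrum with 4mers dominant (0.217 / 0.158 / 0.411 / 0.085 / 0.131 for
k = 2…6), unit counts uniform between the detection threshold and 15, and
40 bp clean flanks.

Two guarantees make the truth table exact rather than probabilistic:
background segments are rejection-sampled until they contain no qualifying
array and no 5+ bp homopolymer, with run-boundary bases forced to break the
planted periodicity; and each assembled SSR-bearing read is re-screened so
its scan yields exactly the planted locus. The screening reuses the
package's scanner as a rejection predicate, but truth rows are written from
the planting parameters, never from a scan. Everything is driven by one
`random.Random(seed)`, so corpora are byte-reproducible.

What passing on these corpora does **not** show: robustness to sequencing
error (no error model), to quality artefacts (qualities are ignored by
design), or to realistic repeat landscapes — real flanks are often
repetitive, which lowers PAL rates and inflates copy counts in ways unique
random flanks cannot exhibit. The pipeline's *contracts* (detection,
constraint satisfaction, exact counting, nesting, determinism) are what the
tests establish.

## Problem sizes and numerics

The shipped test and acceptance workloads use corpora of 400–10,500 reads
and 500-locus planted sets — large enough to exercise every code path and
the counting statistics at full stringency while keeping the whole suite
in the low minutes on one core. All coordinates are 0-based half-open
internally; user-facing tables are 1-based inclusive where coordinates are
emitted. Floats in the output table are fixed to 2 decimals, which is what
makes end-to-end byte-level determinism a testable property. Degenerate
inputs: empty read files and mate-count mismatches are fatal; reads shorter
than any threshold simply yield no loci; an SSR with no flank (array at
base 0) yields a record with `primer_found = 0`, not an error.
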