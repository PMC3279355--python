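"""Flank masking and PCR primer-pair selection for SSR-bearing templates.

A locus is only useful as a length-polymorphism marker if primers can be
placed in its non-repetitive flanks, so the flanks are first masked for low
complexity (tandem runs that themselves meet the SSR thresholds, plus
homopolymers of 5 bp or more) and candidate primers are then enumerated on
the unmasked sequence under four hard criteria:

1. GC content strictly greater than 30%;
2. melting temperature 58-65 degrees C, with at most 2 degrees C difference
   between the two primers of a pair;
3. the last two 3' bases G or C (GC clamp);
4. no homopolymer longer than 4 bases within the primer.

plus self/pair complementarity limits and a length range of 18-27 nt
(optimum 20).  Among conforming pairs whose product lies in the configured
size range and brackets at least one target repeat, the pair bracketing the
most repeat units wins; ties go to the lowest penalty, then the leftmost
forward primer.  Melting temperatures come from nearest-neighbor
thermodynamics (SantaLucia unified parameters, 50 mM monovalent salt,
50 nM annealing oligo).

Paired-end mates are joined into a pseudo-template -- mate1, an N-gap
padding to the assumed insert size, then the reverse complement of mate2 --
so a pair may place one primer on each mate; primers never overlap the gap.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import TYPE_CHECKING, NamedTuple, Sequence

from Bio.SeqUtils import MeltingTemp as _mt

from .ssr_scan import SSRLocus, _scan_string, revcomp

if TYPE_CHECKING:  # pragma: no cover
    from .io_config import ReadPair, ScanConfig

HOMOPOLYMER_MASK_MIN = 5  # bp; low-complexity masking threshold for 1mers


@dataclass
class PrimerPair:
    """A forward/reverse primer pair on one template.

    ``rev_seq`` is given 5'->3' as synthesized, i.e. the reverse complement
    of the template plus-strand segment it binds ([rev_start, rev_end)).
    ``penalty`` is lower-is-better: |Tm - 60.5| per primer (weight 1.0),
    |length - 20| per primer (weight 0.5), and the pair Tm difference
    (weight 1.0).
    """

    fwd_seq: str
    rev_seq: str
    fwd_start: int
    fwd_end: int
    rev_start: int
    rev_end: int
    fwd_tm: float
    rev_tm: float
    fwd_gc: float
    rev_gc: float
    product_size_est: int
    penalty: float
    spans_insert_gap: bool = False
    bracketed_units: int = 0


class PairMap(NamedTuple):
    """Geometry of a paired-end pseudo-template."""

    len1: int
    gap: int
    len2: int


def build_pair_template(pair: "ReadPair", cfg: "ScanConfig") -> tuple[str, PairMap]:
    """Join mates into a pseudo-template padded to the assumed insert size.

    Template = mate1 + N*gap + revcomp(mate2), gap = max(0, insert - len1 -
    len2).  Primers may not overlap the N gap (N is never allowed in a
    primer); a pair with one primer on each mate spans the gap and its
    product size implicitly assumes the configured insert size.
    """
    from .io_config import Platform

    if cfg.platform is not Platform.PE_ILLUMINA:
        raise ValueError("pair templates require paired-end (Illumina) mode")
    l1, l2 = len(pair.mate1.bases), len(pair.mate2.bases)
    gap = max(0, cfg.assumed_insert_size - l1 - l2)
    template = pair.mate1.bases + "N" * gap + revcomp(pair.mate2.bases)
    return template, PairMap(l1, gap, l2)


def map_mate2_locus(locus: SSRLocus, pm: PairMap) -> tuple[int, int]:
    """Map a mate2 as-stored locus span onto pseudo-template coordinates."""
    offset = pm.len1 + pm.gap
    return offset + (pm.len2 - locus.end), offset + (pm.len2 - locus.start)


def mask_flanks(
    template: str,
    target_spans: Sequence[tuple[int, int]],
    cfg: "ScanConfig",
    extra_motifs: Sequence[str] = (),
) -> bytearray:
    """Mark template bases unavailable for primer placement.

    Masked: the target SSR span(s) themselves; every maximal tandem run
    (unit 2-6 bp) meeting the detection thresholds; homopolymers of
    `HOMOPOLYMER_MASK_MIN` bp or more; N bases; and, optionally, every
    occurrence of user-supplied simple-repeat motifs.  Products may still
    cross masked bases -- only primer placement is restricted.

    Returns a bytearray of 0/1 flags (1 = masked), same length as template.
    """
    n = len(template)
    mask = bytearray(n)
    for s, e in target_spans:
        for i in range(max(s, 0), min(e, n)):
            mask[i] = 1
    for s, e, _units, _unit in _scan_string(template, cfg):
        for i in range(s, e):
            mask[i] = 1
    i = 0
    while i < n:
        j = i
        while j < n and template[j] == template[i]:
            j += 1
        if template[i] == "N" or j - i >= HOMOPOLYMER_MASK_MIN:
            for p in range(i, j):
                mask[p] = 1
        i = j
    for motif in extra_motifs:
        motif = motif.strip().upper()
        if not motif:
            continue
        start = template.find(motif)
        while start != -1:
            for p in range(start, start + len(motif)):
                mask[p] = 1
            start = template.find(motif, start + 1)
    return mask


@lru_cache(maxsize=200_000)
def melting_temp(primer: str) -> float:
    """Nearest-neighbor melting temperature of a primer, in degrees C.

    SantaLucia unified NN parameters with 50 mM monovalent cation and 50 nM
    annealing oligo (the conventional primer-design conditions), SantaLucia
    entropy salt correction.  Deterministic for a given sequence.
    """
    if any(b not in "ACGT" for b in primer):
        raise ValueError(f"primer contains non-ACGT base: {primer!r}")
    return _mt.Tm_NN(
        primer, nn_table=_mt.DNA_NN3, Na=50, K=0, Tris=0, Mg=0, dNTPs=0,
        dnac1=50, dnac2=0, saltcorr=5,
    )


def gc_percent(seq: str) -> float:
    return 100.0 * sum(1 for b in seq if b in "GC") / len(seq)


def _max_homopolymer(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        if run > best:
            best = run
    return best


_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


def _self_any(seq: str) -> int:
    """Max complementary aligned bases between the primer and itself.

    Aligned-base counting: the primer is slid along its own reverse, and at
    each offset the number of Watson-Crick complementary aligned positions
    is counted; the maximum over offsets is returned.
    """
    n = len(seq)
    rev = seq[::-1]
    best = 0
    for shift in range(-(n - 1), n):
        count = 0
        for i in range(n):
            j = i + shift
            if 0 <= j < n and (seq[i], rev[j]) in _PAIRS:
                count += 1
        if count > best:
            best = count
    return best


def _self_end(seq: str) -> int:
    """Max contiguous complementary run anchored at the primer's 3' end."""
    n = len(seq)
    rev = seq[::-1]
    best = 0
    for shift in range(-(n - 1), n):
        count = 0
        for i in range(n - 1, -1, -1):  # walk in from the 3' terminus
            j = i + shift
            if 0 <= j < n and (seq[i], rev[j]) in _PAIRS:
                count += 1
            else:
                break
        if count > best:
            best = count
    return best


def _primer_ok(seq: str, cfg: "ScanConfig") -> float | None:
    """Apply the per-primer constraints; return Tm if all pass, else None."""
    clamp = seq[-cfg.gc_clamp_len:]
    if any(b not in "GC" for b in clamp):
        return None
    if _max_homopolymer(seq) > cfg.max_polyN:
        return None
    if gc_percent(seq) <= cfg.gc_min_pct:
        return None
    tm = melting_temp(seq)
    if not (cfg.tm_min <= tm <= cfg.tm_max):
        return None
    if _self_any(seq) > cfg.self_any_max or _self_end(seq) > cfg.self_end_max:
        return None
    return tm


def _candidate_sites(template: str, mask: bytearray, cfg: "ScanConfig"):
    """Yield (start, end) spans of clean template eligible to host a primer."""
    n = len(template)
    # prefix sums of masked/non-ACGT flags for O(1) window checks
    bad = [0] * (n + 1)
    for i, b in enumerate(template):
        bad[i + 1] = bad[i] + (1 if (mask[i] or b not in "ACGT") else 0)
    for start in range(n - cfg.primer_len_min + 1):
        for length in range(cfg.primer_len_min, cfg.primer_len_max + 1):
            end = start + length
            if end > n:
                break
            if bad[end] - bad[start] == 0:
                yield start, end


def _enumerate_primers(template: str, mask: bytearray, cfg: "ScanConfig"):
    """All conforming forward and reverse primer placements on a template.

    Returns (fwd, rev) lists of (start, end, seq, tm) tuples; a reverse
    primer's sequence is the reverse complement of the template segment it
    binds (5'->3' as synthesized, 3' end at the segment's left edge).
    """
    fwd, rev = [], []
    for start, end in _candidate_sites(template, mask, cfg):
        segment = template[start:end]
        tm = _primer_ok(segment, cfg)
        if tm is not None:
            fwd.append((start, end, segment, tm))
        rseq = revcomp(segment)
        tm = _primer_ok(rseq, cfg)
        if tm is not None:
            rev.append((start, end, rseq, tm))
    return fwd, rev


def design_pal(
    template: str,
    targets: Sequence[SSRLocus | tuple[int, int, int]],
    cfg: "ScanConfig",
    mask: bytearray | None = None,
    pair_map: PairMap | None = None,
) -> PrimerPair | None:
    """Select the best conforming primer pair bracketing the target repeats.

    `targets` are the SSR loci on the template, as `SSRLocus` objects in
    template coordinates or raw (start, end, units) triples.  Candidates of
    length 18-27 nt are enumerated on the unmasked flanks; a valid pair must
    satisfy every per-primer constraint, differ by at most
    ``tm_pair_maxdiff`` degrees, yield a product within
    ``product_size_range``, and bracket (flank without overlapping) at least
    one target.  Selection: (1) maximum total repeat units bracketed,
    (2) minimum penalty, (3) smallest forward start, (4) smallest reverse
    end.  Returns None when no valid pair exists -- the read keeps its SSR
    but is not a PAL.
    """
    if not targets:
        raise ValueError("design_pal requires at least one target locus")
    spans = [
        (t.start, t.end, t.units) if isinstance(t, SSRLocus) else tuple(t)
        for t in targets
    ]
    if mask is None:
        mask = mask_flanks(template, [(s, e) for s, e, _ in spans], cfg)
    fwd_cands, rev_cands = _enumerate_primers(template, mask, cfg)
    if not fwd_cands or not rev_cands:
        return None
    first_target_start = max(s for s, _, _ in spans)
    last_target_end = min(e for _, e, _ in spans)
    # prune to primers that can bracket at least one target
    fwd_cands = [c for c in fwd_cands if c[1] <= first_target_start]
    rev_cands = [c for c in rev_cands if c[0] >= last_target_end]
    lo, hi = cfg.product_size_range
    w_tm, w_len, w_diff = 1.0, 0.5, 1.0
    opt = cfg.primer_len_opt
    best_key = None
    best: PrimerPair | None = None
    for fs, fe, fseq, ftm in fwd_cands:
        for rs, re_, rseq, rtm in rev_cands:
            if rs < fe:
                continue
            diff = abs(ftm - rtm)
            if diff > cfg.tm_pair_maxdiff:
                continue
            product = re_ - fs
            if not (lo <= product <= hi):
                continue
            units = sum(u for s, e, u in spans if fe <= s and e <= rs)
            if units == 0:
                continue
            penalty = (
                w_tm * (abs(ftm - 60.5) + abs(rtm - 60.5))
                + w_len * (abs(fe - fs - opt) + abs(re_ - rs - opt))
                + w_diff * diff
            )
            key = (-units, penalty, fs, re_)
            if best_key is None or key < best_key:
                best_key = key
                spans_gap = bool(
                    pair_map
                    and fe <= pair_map.len1
                    and rs >= pair_map.len1 + pair_map.gap
                )
                best = PrimerPair(
                    fwd_seq=fseq, rev_seq=rseq,
                    fwd_start=fs, fwd_end=fe, rev_start=rs, rev_end=re_,
                    fwd_tm=ftm, rev_tm=rtm,
                    fwd_gc=gc_percent(fseq), rev_gc=gc_percent(rseq),
                    product_size_est=product, penalty=penalty,
                    spans_insert_gap=spans_gap, bracketed_units=units,
                )
    return best
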