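"""Empirical primer copy-number statistics over the read library.

A primer pair only makes a usable marker if it amplifies a single locus.
With no assembled genome available, the raw read set itself serves as the
reference: each primer's occurrences (as an exact, ungapped, case-insensitive
substring, counting both the sequence and its reverse complement, overlaps
included) are counted across every read, and each pair's co-occurrences in
amplifiable orientation are counted per library unit (a read pair in
paired-end mode, a single read otherwise).  Five statistics result:

* ``fwd_count``, ``rev_count`` -- per-primer library occurrence counts;
* ``min_count`` = min(fwd, rev) -- at cutoff 1, at least one primer is
  unique to the locus;
* ``product_count`` = fwd x rev -- at cutoff 1, both primers are unique
  (the most stringent criterion);
* ``pair_count`` -- units where both primers co-occur in amplifiable
  orientation, a direct proxy for how often the pair would prime a product.

Matching is exact by design: the statistic is a reproducible count, not an
alignment score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence, Union

from .primer_design import PrimerPair
from .ssr_scan import SSRLocus, revcomp

if TYPE_CHECKING:  # pragma: no cover
    from .io_config import ReadPair, ReadRecord

LibraryUnit = Union["ReadRecord", "ReadPair"]


@dataclass
class PALRecord:
    """One SSR-bearing read (or pair) with its primers and copy statistics."""

    read_id: str
    loci: list[SSRLocus]
    klass: str
    primers: PrimerPair | None = None
    bracketed_loci: list[SSRLocus] = field(default_factory=list)
    fwd_count: int = 0
    rev_count: int = 0
    min_count: int = 0
    product_count: int = 0
    pair_count: int = 0

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def motifs_str(self) -> str:
        return ";".join(f"{l.motif.canonical}({l.units})" for l in self.loci)


def _unit_reads(unit: LibraryUnit) -> tuple[str, ...]:
    if hasattr(unit, "mate1"):
        return (unit.mate1.bases, unit.mate2.bases)
    return (unit.bases,)


def _count_overlapping(hay: str, needle: str) -> int:
    count = 0
    pos = hay.find(needle)
    while pos != -1:
        count += 1
        pos = hay.find(needle, pos + 1)
    return count


def count_primer(primer: str, library: Iterable[LibraryUnit]) -> int:
    """Occurrences of a primer across every read in the library.

    Counts the primer and its reverse complement as exact ungapped
    substrings, summed over all reads (both mates in paired-end mode);
    overlapping occurrences all count.  A palindromic primer equals its own
    reverse complement and is counted once per site.
    """
    if not primer:
        raise ValueError("empty primer")
    primer = primer.upper()
    rc = revcomp(primer)
    total = 0
    for unit in library:
        for bases in _unit_reads(unit):
            total += _count_overlapping(bases, primer)
            if rc != primer:
                total += _count_overlapping(bases, rc)
    return total


def _cooccur_in_read(bases: str, fwd: str, rev: str) -> bool:
    """Both primers in one read, convergently oriented (amplifiable).

    On the plus strand that is fwd ... revcomp(rev); the strand-mirrored
    arrangement is rev ... revcomp(fwd).
    """
    for left, right in ((fwd, revcomp(rev)), (rev, revcomp(fwd))):
        i = bases.find(left)
        if i == -1:
            continue
        if bases.rfind(right) >= i:
            return True
    return False


def count_pair_cooccurrence(
    pair: PrimerPair | tuple[str, str], library: Iterable[LibraryUnit]
) -> int:
    """Library units containing both primers in amplifiable orientation.

    A unit counts (at most once) when either (a) one of its reads contains
    the forward primer with the reverse complement of the reverse primer
    downstream (or the strand-mirrored arrangement), or (b) in paired-end
    mode, one mate contains the forward primer and the other mate contains
    the reverse primer, each as stored -- both reads then point into the
    fragment, the amplifiable configuration.
    """
    if isinstance(pair, PrimerPair):
        fwd, rev = pair.fwd_seq, pair.rev_seq
    else:
        fwd, rev = pair
    fwd, rev = fwd.upper(), rev.upper()
    count = 0
    for unit in library:
        reads = _unit_reads(unit)
        hit = any(_cooccur_in_read(bases, fwd, rev) for bases in reads)
        if not hit and len(reads) == 2:
            m1, m2 = reads
            hit = (fwd in m1 and rev in m2) or (fwd in m2 and rev in m1)
        if hit:
            count += 1
    return count


def annotate_pals(
    pals: Sequence[PALRecord], library: Sequence[LibraryUnit]
) -> Sequence[PALRecord]:
    """Fill the five copy-number statistics of every primer-bearing record.

    Deterministic; records without primers are left untouched.  Each primer
    occurs at least once (at its own source locus), so a zero count signals
    an inconsistent library and is surfaced as a warning.
    """
    # one concatenated text (reads separated by '\n') lets each primer be
    # counted with two substring scans instead of a per-read Python loop
    joined = "\n".join(b for unit in library for b in _unit_reads(unit))

    def _fast_count(primer: str) -> int:
        primer = primer.upper()
        rc = revcomp(primer)
        n = _count_overlapping(joined, primer)
        if rc != primer:
            n += _count_overlapping(joined, rc)
        return n

    for rec in pals:
        p = rec.primers
        if p is None:
            continue
        rec.fwd_count = _fast_count(p.fwd_seq)
        rec.rev_count = _fast_count(p.rev_seq)
        rec.min_count = min(rec.fwd_count, rec.rev_count)
        rec.product_count = rec.fwd_count * rec.rev_count
        rec.pair_count = count_pair_cooccurrence(p, library)
        if rec.min_count < 1 or rec.pair_count < 1:
            warnings.warn(
                f"{rec.read_id}: primer copy count below self-occurrence; "
                "the annotated library does not contain the source read"
            )
    return pals
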