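"""Detection and classification of perfect microsatellites (SSRs) in reads.

A simple sequence repeat is a maximal perfect tandem array of a 2-6 bp unit.
Units related by cyclic rotation or reverse complementation describe the same
locus read from a different phase or strand, so every locus is reported under
a single canonical motif: the lexicographically smallest string among the
rotations of the unit and of its reverse complement.  Under that grouping
there are 4 dinucleotide classes, 10 trinucleotide classes, 33 tetra-, 102
penta- and 350 hexanucleotide classes (primitive units only: a unit that is
itself a tandem repeat of a shorter unit, such as ACAC, belongs to the
shorter unit's class).

Detection thresholds follow the marker-development convention: an array of a
2-4 bp unit qualifies when it reaches 12 bp of complete units; 5-6 bp units
qualify at 3 complete units.  Both are configurable (`ScanConfig`).
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache
from typing import TYPE_CHECKING, Iterable, NamedTuple, Sequence

if TYPE_CHECKING:  # pragma: no cover
    from .io_config import ReadPair, ReadRecord, ScanConfig

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

KMIN = 2
KMAX = 6


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class Motif(NamedTuple):
    """Canonical representative of a repeat-unit equivalence class."""

    canonical: str

    @property
    def k(self) -> int:
        return len(self.canonical)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.canonical


@dataclass
class SSRLocus:
    """One maximal perfect tandem array on a read.

    Coordinates are 0-based half-open on the read as stored; ``end - start``
    equals ``units * motif.k`` (partial trailing units are excluded).
    """

    read_id: str
    mate_index: int | None
    motif: Motif
    start: int
    end: int
    units: int
    unit: str  # the unit as it occurs at `start` (a rotation/complement of motif)
    klass: str = "perfect"  # perfect | compound | broken
    spans_gap: bool = False

    @property
    def total_len(self) -> int:
        return self.end - self.start

    @property
    def k(self) -> int:
        return self.motif.k


def is_primitive(unit: str) -> bool:
    """True if `unit` is not itself a tandem repeat of a shorter unit."""
    k = len(unit)
    for d in range(1, k):
        if k % d == 0 and unit == unit[:d] * (k // d):
            return False
    return True


@lru_cache(maxsize=None)
def canonical_motif(unit: str) -> Motif:
    """Canonicalize a repeat unit over cyclic rotation and reverse complement.

    Returns the lexicographic minimum of the 2k strings {rotations of unit}
    union {rotations of revcomp(unit)}, e.g. TG and CA both canonicalize to
    AC; TGG, GTG and GGT all canonicalize to ACC.

    Raises ValueError for non-primitive units (they have no class of their
    own) and for units outside 2..6 bp or containing non-ACGT bases.
    """
    k = len(unit)
    if not (KMIN <= k <= KMAX):
        raise ValueError(f"unit length {k} outside {KMIN}..{KMAX}: {unit!r}")
    if any(b not in "ACGT" for b in unit):
        raise ValueError(f"unit contains non-ACGT base: {unit!r}")
    if not is_primitive(unit):
        raise ValueError(f"non-primitive unit has no motif class: {unit!r}")
    rc = revcomp(unit)
    candidates = itertools.chain(
        (unit[i:] + unit[:i] for i in range(k)),
        (rc[i:] + rc[:i] for i in range(k)),
    )
    return Motif(min(candidates))


@lru_cache(maxsize=None)
def enumerate_motif_classes(k: int) -> frozenset[Motif]:
    """All distinct canonical motifs of unit length ``k`` (2..6).

    Sizes: 4, 10, 33, 102, 350 for k = 2..6.
    """
    if not (KMIN <= k <= KMAX):
        raise ValueError(f"k must be in {KMIN}..{KMAX}, got {k}")
    out = set()
    for bases in itertools.product("ACGT", repeat=k):
        unit = "".join(bases)
        if is_primitive(unit):
            out.add(canonical_motif(unit))
    return frozenset(out)


def _scan_string(s: str, cfg: "ScanConfig") -> list[tuple[int, int, int, str]]:
    """Maximal perfect tandem runs in `s`: (start, end, units, unit) tuples.

    A run of period k is kept only if its unit is primitive, so arrays like
    (AT)x8 are reported once at k=2 and never as a 4mer, and homopolymers are
    never reported (an AA "unit" is not primitive).
    """
    n = len(s)
    runs: list[tuple[int, int, int, str]] = []
    for k in range(cfg.kmin, cfg.kmax + 1):
        min_units = cfg.min_units(k)
        j = 0
        limit = n - k
        while j < limit:
            if s[j] != s[j + k] or s[j] not in "ACGT":
                j += 1
                continue
            a = j
            while j < limit and s[j] == s[j + k] and s[j] in "ACGT":
                j += 1
            # match run over [a, j); periodic region is [a, j + k)
            units = (j - a + k) // k
            if units >= min_units:
                unit = s[a : a + k]
                if is_primitive(unit):
                    runs.append((a, a + units * k, units, unit))
    runs.sort(key=lambda r: (r[0], len(r[3])))
    return runs


def find_perfect_ssrs(read: "ReadRecord", cfg: "ScanConfig") -> list[SSRLocus]:
    """All maximal perfect 2-6mer tandem arrays on a read meeting thresholds.

    Runs are maximal (not extendable by a full unit on either side), partial
    trailing units are trimmed, and each array is reported once under its
    smallest primitive period.  Loci are sorted by start coordinate.
    """
    return [
        SSRLocus(
            read_id=read.read_id,
            mate_index=read.mate_index,
            motif=canonical_motif(unit),
            start=start,
            end=end,
            units=units,
            unit=unit,
        )
        for start, end, units, unit in _scan_string(read.bases, cfg)
    ]


def classify_read_ssrs(loci: Sequence[SSRLocus]) -> list[str]:
    """Assign perfect/compound/broken class to the loci of one read.

    A single locus is perfect.  Multiple loci with at least two distinct
    canonical motifs are all compound; multiple loci sharing one canonical
    motif are all broken.  Classes are written onto the loci and returned.
    """
    if not loci:
        return []
    if len(loci) == 1:
        loci[0].klass = "perfect"
    elif len({l.motif for l in loci}) > 1:
        for l in loci:
            l.klass = "compound"
    else:
        for l in loci:
            l.klass = "broken"
    return [l.klass for l in loci]


def detect_spanning(
    pair: "ReadPair",
    loci1: Sequence[SSRLocus],
    loci2: Sequence[SSRLocus],
    cfg: "ScanConfig",
) -> bool:
    """Flag a repeat that extends through the unsequenced insert gap.

    Both mates are stored as sequenced, so each mate's 3' end is the
    fragment-interior terminus.  The pair spans when a locus on mate 1 ends
    within `spanning_end_tolerance` bases of mate 1's 3' end, a locus on
    mate 2 does the same, and the two canonical motifs agree
    (canonicalization makes the comparison strand-safe).  Matching loci are
    marked `spans_gap` and still reported individually.
    """
    from .io_config import Platform

    if cfg.platform is not Platform.PE_ILLUMINA:
        raise ValueError("spanning detection requires paired-end (Illumina) mode")
    tol = cfg.spanning_end_tolerance
    tail1 = [l for l in loci1 if l.end >= len(pair.mate1.bases) - tol]
    tail2 = [l for l in loci2 if l.end >= len(pair.mate2.bases) - tol]
    shared = {l.motif for l in tail1} & {l.motif for l in tail2}
    if not shared:
        return False
    for l in itertools.chain(tail1, tail2):
        if l.motif in shared:
            l.spans_gap = True
    return True


@dataclass
class ScanSummary:
    """Corpus-level scan statistics (SSR-read counts, density, spectra)."""

    n_reads: int
    megabases: float
    reads_with_ssrs: int
    total_loci: int
    compound_loci: int
    loci_per_mbp: float
    per_k: Counter = field(default_factory=Counter)
    per_motif: Counter = field(default_factory=Counter)


def summarize_scan(
    loci: Iterable[SSRLocus], n_reads: int, megabases: float
) -> ScanSummary:
    """Aggregate scan results into the standard summary statistics.

    `loci_per_mbp` is total loci divided by megabases of sequence scanned;
    `per_k` and `per_motif` are the motif-length and canonical-motif spectra.
    """
    loci = list(loci)
    reads = {(l.read_id, l.mate_index) for l in loci}
    per_k = Counter(l.k for l in loci)
    per_motif = Counter(l.motif.canonical for l in loci)
    compound = sum(1 for l in loci if l.klass == "compound")
    return ScanSummary(
        n_reads=n_reads,
        megabases=megabases,
        reads_with_ssrs=len(reads),
        total_loci=len(loci),
        compound_loci=compound,
        loci_per_mbp=(len(loci) / megabases) if megabases > 0 else 0.0,
        per_k=per_k,
        per_motif=per_motif,
    )
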