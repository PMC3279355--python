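"""Shared fixtures and independent brute-force oracles.

The oracles re-derive expected results by a different route from the
implementation (per-position unit comparison instead of match-run scanning,
naive substring scans instead of the indexed counters) so that agreement is
meaningful.
"""

from __future__ import annotations

import random

import pytest

from palfinder import ReadPair, ReadRecord, ScanConfig
from palfinder.ssr_scan import is_primitive


@pytest.fixture
def cfg() -> ScanConfig:
    return ScanConfig()


@pytest.fixture
def se_cfg() -> ScanConfig:
    return ScanConfig(platform="454")


def brute_force_ssrs(s: str, cfg: ScanConfig) -> list[tuple[int, int, int, str]]:
    """Independent tandem-repeat detector: test every (start, k) candidate.

    For each position and period, counts complete unit copies by direct
    slice comparison, keeps leftmost starts of each periodic region only,
    and applies the primitivity and threshold rules.  Returns sorted
    (start, end, units, unit) tuples matching the scanner's contract.
    """
    n = len(s)
    out = []
    for k in range(cfg.kmin, cfg.kmax + 1):
        for i in range(n - 2 * k + 1):
            unit = s[i : i + k]
            if any(b not in "ACGT" for b in unit) or not is_primitive(unit):
                continue
            # leftmost within its periodic region: the base before must not
            # continue the periodicity
            if i > 0 and s[i - 1] in "ACGT" and s[i - 1] == s[i - 1 + k]:
                continue
            m = 1
            while s[i + m * k : i + (m + 1) * k] == unit:
                m += 1
            if m >= cfg.min_units(k):
                out.append((i, i + m * k, m, unit))
    out.sort(key=lambda r: (r[0], len(r[3])))
    return out


def naive_primer_count(primer: str, reads: list[str]) -> int:
    """Independent occurrence counter: per-read, per-offset comparison."""
    from palfinder import revcomp

    primer = primer.upper()
    patterns = {primer, revcomp(primer)}
    total = 0
    for bases in reads:
        for pat in patterns:
            for i in range(len(bases) - len(pat) + 1):
                if bases[i : i + len(pat)] == pat:
                    total += 1
    return total


def naive_pair_cooccurrence(fwd: str, rev: str, units) -> int:
    """Independent co-occurrence counter mirroring the orientation contract."""
    from palfinder import revcomp

    def occ_starts(hay, needle):
        return [
            i for i in range(len(hay) - len(needle) + 1)
            if hay[i : i + len(needle)] == needle
        ]

    def in_read(bases):
        for left, right in ((fwd, revcomp(rev)), (rev, revcomp(fwd))):
            li = occ_starts(bases, left)
            ri = occ_starts(bases, right)
            if li and ri and max(ri) >= min(li):
                return True
        return False

    count = 0
    for unit in units:
        if isinstance(unit, ReadPair):
            reads = (unit.mate1.bases, unit.mate2.bases)
        else:
            reads = (unit.bases,)
        hit = any(in_read(b) for b in reads)
        if not hit and len(reads) == 2:
            m1, m2 = reads
            hit = (fwd in m1 and rev in m2) or (fwd in m2 and rev in m1)
        if hit:
            count += 1
    return count


def random_dna(rng: random.Random, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(alphabet) for _ in range(length))


def make_read(bases: str, read_id: str = "r", mate: int | None = None) -> ReadRecord:
    return ReadRecord(read_id=read_id, bases=bases, mate_index=mate)
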