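"""Synthetic shotgun read corpora with planted SSRs and known truth.

Emulates the geometry of a paired-end shotgun library built for marker
discovery -- 325 bp fragments read 114 bp from each end -- or a single-end
454-style library, with tandem repeats planted at a configurable density
and a truth table recording exactly what was planted where.  Background
sequence is i.i.d. with configurable GC content, rejection-screened so that
it contains no array meeting the detection thresholds and no homopolymer of
5+ bp; planted run boundaries are forced non-extendable.  The assembled
SSR-bearing read is re-screened so that its scan yields exactly the planted
locus, which makes truth-table recovery exact rather than probabilistic.

Duplication factors replicate whole fragments (fresh read ids, identical
bases) to create known primer copy numbers for testing the annotation
statistics.  Everything is deterministic given the seed.

What this generator does NOT emulate: sequencing errors, quality scores,
coverage biases, or realistic repeat landscapes (flanks are unique by
construction, unlike real genomes where flanking repeats are the main cause
of primer-design failure).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .io_config import Platform, ReadPair, ReadRecord, ScanConfig
from .primer_design import HOMOPOLYMER_MASK_MIN
from .ssr_scan import canonical_motif, is_primitive, _scan_string, revcomp

# per-k planting frequencies shaped like an observed shotgun SSR spectrum,
# where tetranucleotides dominate
DEFAULT_K_DIST = {2: 0.217, 3: 0.158, 4: 0.411, 5: 0.085, 6: 0.131}

TRUTH_COLUMNS = [
    "fragment_id", "read_id", "mate_index", "motif", "unit", "units",
    "start", "end", "dup_factor", "spanning",
]


@dataclass
class PlantingPlan:
    """Parameters of a synthetic corpus.

    ``ssr_density`` is the fraction of fragments carrying one planted SSR
    (default 0.1, the order of the SSR-read fraction seen in snake shotgun
    reads).  ``units_max`` caps planted array length (uniform draw between
    the detection threshold and the cap, further capped so the array plus
    two flanks fits the read).  ``duplication`` is a global factor or a
    {fragment_index: factor} map.
    """

    n_fragments: int = 500
    fragment_len: int = 325
    read_len: int = 114
    platform: Platform = Platform.PE_ILLUMINA
    ssr_density: float = 0.1
    k_dist: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_K_DIST)
    )
    units_min: int | None = None  # None = detection threshold per k
    units_max: int = 15
    flank_len: int = 40
    gc: float = 0.5
    duplication: int | dict[int, int] = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ssr_density <= 1.0:
            raise ValueError("ssr_density must be in [0, 1]")
        if not 0.0 < self.gc < 1.0:
            raise ValueError("gc must be in (0, 1)")
        if isinstance(self.platform, str):
            self.platform = Platform(self.platform)
        total = sum(self.k_dist.values())
        if total <= 0:
            raise ValueError("k_dist must have positive mass")
        self.k_dist = {k: v / total for k, v in self.k_dist.items()}

    def dup_factor(self, index: int) -> int:
        if isinstance(self.duplication, dict):
            return self.duplication.get(index, 1)
        return self.duplication


def _draw_base(rng: random.Random, gc: float) -> str:
    if rng.random() < gc:
        return rng.choice("GC")
    return rng.choice("AT")


def _has_homopolymer(s: str, n: int) -> bool:
    run = 1
    for a, b in zip(s, s[1:]):
        run = run + 1 if a == b else 1
        if run >= n:
            return True
    return False


def _clean_background(rng: random.Random, length: int, gc: float,
                      cfg: ScanConfig) -> str:
    """Random sequence with no qualifying SSR and no 5+ bp homopolymer."""
    while True:
        s = "".join(_draw_base(rng, gc) for _ in range(length))
        if _has_homopolymer(s, HOMOPOLYMER_MASK_MIN):
            continue
        if _scan_string(s, cfg):
            continue
        return s


def _random_primitive_unit(rng: random.Random, k: int) -> str:
    while True:
        unit = "".join(rng.choice("ACGT") for _ in range(k))
        if is_primitive(unit):
            return unit


def _choose_k(rng: random.Random, plan: PlantingPlan) -> int:
    r = rng.random()
    acc = 0.0
    for k, p in sorted(plan.k_dist.items()):
        acc += p
        if r <= acc:
            return k
    return max(plan.k_dist)


@dataclass
class PlantedLocus:
    """Truth-table row for one planted SSR."""

    fragment_id: str
    read_id: str
    mate_index: int | None
    motif: str
    unit: str
    units: int
    start: int  # 0-based half-open, on the read as stored
    end: int
    dup_factor: int
    spanning: bool = False


def _plant_in_read(
    rng: random.Random, plan: PlantingPlan, cfg: ScanConfig, read_len: int
) -> tuple[str, str, int, int, int] | None:
    """Build one read carrying exactly one planted SSR.

    Returns (bases, unit, units, start, end) or None if no feasible k.
    The assembled read is re-screened: its scan must yield exactly the
    planted run, so truth recovery is exact by construction.
    """
    for _ in range(200):
        k = _choose_k(rng, plan)
        lo = plan.units_min or cfg.min_units(k)
        hi = min(plan.units_max, (read_len - 2 * plan.flank_len) // k)
        if hi < lo:
            continue
        units = rng.randint(lo, hi)
        unit = _random_primitive_unit(rng, k)
        run = unit * units
        start = plan.flank_len
        right_len = read_len - start - len(run)
        for _ in range(50):
            left = _clean_background(rng, start, plan.gc, cfg)
            right = _clean_background(rng, right_len, plan.gc, cfg)
            if left[-1] == unit[-1] or right[0] == unit[0]:
                continue  # boundary base would extend the planted run
            bases = left + run + right
            found = _scan_string(bases, cfg)
            if len(found) == 1 and found[0] == (
                start, start + len(run), units, unit
            ):
                return bases, unit, units, start, start + len(run)
    return None


def simulate_corpus(
    plan: PlantingPlan,
    cfg: ScanConfig | None = None,
    out_prefix: str | Path | None = None,
) -> tuple[list[ReadRecord] | list[ReadPair], list[PlantedLocus]]:
    """Generate a synthetic corpus plus its truth table.

    Paired-end mode yields `ReadPair`s (mate1 = fragment prefix, mate2 =
    reverse complement of the fragment suffix); single-end mode yields one
    `ReadRecord` per fragment, read_len bases long.  Planted SSRs sit wholly
    inside mate1 (or the single read) with `flank_len` clean flanks.
    Duplicated fragments emit extra reads with ``<id>.dupN`` identifiers and
    identical bases.  With ``out_prefix``, writes ``<prefix>_1.fasta`` (and
    ``_2.fasta`` in PE mode) plus ``<prefix>_truth.tsv``.
    """
    if cfg is None:
        cfg = ScanConfig(platform=plan.platform)
    rng = random.Random(plan.seed)
    pe = plan.platform is Platform.PE_ILLUMINA
    read_len = plan.read_len
    if pe and 2 * read_len > plan.fragment_len:
        raise ValueError("paired-end mode needs fragment_len >= 2*read_len")
    if plan.flank_len * 2 >= read_len:
        raise ValueError("flank_len too large: no room to plant an SSR")

    units_or_reads: list = []
    truth: list[PlantedLocus] = []
    for i in range(plan.n_fragments):
        frag_id = f"frag{i:05d}"
        dup = plan.dup_factor(i)
        planted = None
        if rng.random() < plan.ssr_density:
            planted = _plant_in_read(rng, plan, cfg, read_len)
        if planted is None:
            read1 = _clean_background(rng, read_len, plan.gc, cfg)
        else:
            read1 = planted[0]
        if pe:
            middle = _clean_background(
                rng, plan.fragment_len - 2 * read_len, plan.gc, cfg
            )
            tail = _clean_background(rng, read_len, plan.gc, cfg)
            fragment = read1 + middle + tail
            mate2_bases = revcomp(fragment[-read_len:])
        for d in range(dup):
            rid = frag_id if d == 0 else f"{frag_id}.dup{d}"
            if pe:
                unit = ReadPair(
                    ReadRecord(rid, read1, 1, plan.platform),
                    ReadRecord(rid, mate2_bases, 2, plan.platform),
                )
            else:
                unit = ReadRecord(rid, read1, None, plan.platform)
            units_or_reads.append(unit)
            if planted is not None:
                _, u, n_units, s, e = planted
                truth.append(PlantedLocus(
                    fragment_id=frag_id, read_id=rid,
                    mate_index=1 if pe else None,
                    motif=canonical_motif(u).canonical, unit=u,
                    units=n_units, start=s, end=e, dup_factor=dup,
                ))
    if out_prefix is not None:
        write_corpus(units_or_reads, truth, out_prefix)
    return units_or_reads, truth


def spanning_fixture(
    plan: PlantingPlan,
    cfg: ScanConfig | None = None,
    n_pairs: int = 10,
    end_offset: int = 0,
) -> tuple[list[ReadPair], list[PlantedLocus]]:
    """Read pairs whose planted repeat crosses the unsequenced insert gap.

    Both mates end (``end_offset`` bases before their stored 3' terminus)
    in the same repeat: mate1 carries the run 5' side, mate2 -- stored as
    the reverse complement of the fragment suffix -- carries its 3' side,
    so its stored bases end in the reverse-complement motif.  Truth rows
    (one per mate) are marked spanning.
    """
    if cfg is None:
        cfg = ScanConfig(platform=Platform.PE_ILLUMINA)
    rng = random.Random(plan.seed)
    read_len = plan.read_len
    pairs: list[ReadPair] = []
    truth: list[PlantedLocus] = []
    for i in range(n_pairs):
        frag_id = f"span{i:05d}"
        k = _choose_k(rng, plan)
        units = max(plan.units_min or cfg.min_units(k), cfg.min_units(k))
        unit = _random_primitive_unit(rng, k)
        def build(mate_unit: str) -> tuple[str, int, int]:
            mrun = mate_unit * units
            head_len = read_len - len(mrun) - end_offset
            for _ in range(100):
                head = _clean_background(rng, head_len, plan.gc, cfg)
                if head[-1] == mate_unit[-1]:
                    continue
                tail = (
                    _clean_background(rng, end_offset, plan.gc, cfg)
                    if end_offset else ""
                )
                if tail and tail[0] == mate_unit[0]:
                    continue
                bases = head + mrun + tail
                found = _scan_string(bases, cfg)
                want = (head_len, head_len + len(mrun), units, mate_unit)
                if len(found) == 1 and found[0] == want:
                    return bases, want[0], want[1]
            raise RuntimeError("could not assemble clean spanning mate")

        b1, s1, e1 = build(unit)
        b2, s2, e2 = build(revcomp(unit))
        pairs.append(ReadPair(
            ReadRecord(frag_id, b1, 1, Platform.PE_ILLUMINA),
            ReadRecord(frag_id, b2, 2, Platform.PE_ILLUMINA),
        ))
        canon = canonical_motif(unit).canonical
        truth.append(PlantedLocus(frag_id, frag_id, 1, canon, unit,
                                  units, s1, e1, 1, spanning=True))
        truth.append(PlantedLocus(frag_id, frag_id, 2, canon, revcomp(unit),
                                  units, s2, e2, 1, spanning=True))
    return pairs, truth


def write_corpus(
    units: Sequence[ReadRecord | ReadPair],
    truth: Sequence[PlantedLocus],
    out_prefix: str | Path,
) -> list[Path]:
    """Write FASTA mate file(s) and the truth TSV; returns the paths."""
    out_prefix = Path(out_prefix)
    paths = []
    pe = bool(units) and isinstance(units[0], ReadPair)
    if pe:
        p1 = out_prefix.parent / f"{out_prefix.name}_1.fasta"
        p2 = out_prefix.parent / f"{out_prefix.name}_2.fasta"
        with open(p1, "w") as f1, open(p2, "w") as f2:
            for u in units:
                f1.write(f">{u.mate1.read_id}\n{u.mate1.bases}\n")
                f2.write(f">{u.mate2.read_id}\n{u.mate2.bases}\n")
        paths += [p1, p2]
    else:
        p1 = out_prefix.parent / f"{out_prefix.name}_1.fasta"
        with open(p1, "w") as f1:
            for u in units:
                f1.write(f">{u.read_id}\n{u.bases}\n")
        paths.append(p1)
    pt = out_prefix.parent / f"{out_prefix.name}_truth.tsv"
    with open(pt, "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for t in truth:
            fh.write("\t".join(str(x) for x in (
                t.fragment_id, t.read_id,
                "" if t.mate_index is None else t.mate_index,
                t.motif, t.unit, t.units, t.start, t.end, t.dup_factor,
                int(t.spanning),
            )) + "\n")
    paths.append(pt)
    return paths
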