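"""Read ingest, control-file parsing, and the tab-delimited locus table.

Reads come in as FASTA or FASTQ (plain or gzipped), one file for single-end
454-style data or two order-matched mate files for paired-end Illumina-style
data.  Fixed-length multiplex identifiers (MIDs) at the read start can be
trimmed on ingest.  All pipeline tunables live in `ScanConfig`, loadable
from a plain-text ``key = value`` control file.

Design notes:

* Mates are paired by record order across the two files, never by read-name
  munging; a record-count mismatch is fatal.
* FASTQ quality strings are ignored: the method operates on bases only.
* Reads containing N are kept; N never matches a repeat unit and is never
  placed inside a primer.
* Output coordinates, where emitted, are 1-based inclusive; internal
  coordinates are 0-based half-open.
"""

from __future__ import annotations

import enum
import gzip
import math
import warnings
from dataclasses import dataclass, fields
from pathlib import Path
from typing import IO, Iterator, Sequence

from Bio import SeqIO

from .copy_annotation import PALRecord
from .primer_design import PrimerPair
from .ssr_scan import Motif, SSRLocus


class Platform(enum.Enum):
    SE_454 = "454"
    PE_ILLUMINA = "illumina"


@dataclass(frozen=True)
class ReadRecord:
    """A single sequenced read: identifier plus uppercased ACGTN bases."""

    read_id: str
    bases: str
    mate_index: int | None = None
    platform: Platform = Platform.SE_454

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class ReadPair:
    """An order-matched mate pair; both mates stored as sequenced."""

    mate1: ReadRecord
    mate2: ReadRecord


@dataclass
class ScanConfig:
    """Every tunable of the pipeline, with marker-development defaults.

    Detection: a 2-4mer array qualifies at ``min_total_len_2to4mer`` bases of
    complete units (12 bp, i.e. 6/4/3 units); 5- and 6mers at
    ``min_units_5mer``/``min_units_6mer`` complete units (3 each).

    Primer design: GC content strictly above ``gc_min_pct`` percent, melting
    temperature within [``tm_min``, ``tm_max``] degrees C with at most
    ``tm_pair_maxdiff`` between the two primers of a pair, a GC clamp on the
    last ``gc_clamp_len`` 3' bases, and no homopolymer longer than
    ``max_polyN`` inside a primer.

    Paired-end geometry: mates are placed on a pseudo-template padded to
    ``assumed_insert_size`` with N bases; ``spanning_end_tolerance`` is how
    far from a mate's 3' end a repeat may stop and still count as spanning.
    """

    platform: Platform = Platform.PE_ILLUMINA
    min_total_len_2to4mer: int = 12
    min_units_5mer: int = 3
    min_units_6mer: int = 3
    kmin: int = 2
    kmax: int = 6
    design_primers: bool = True
    # primer constraints
    gc_min_pct: float = 30.0
    tm_min: float = 58.0
    tm_max: float = 65.0
    tm_pair_maxdiff: float = 2.0
    gc_clamp_len: int = 2
    max_polyN: int = 4
    primer_len_min: int = 18
    primer_len_opt: int = 20
    primer_len_max: int = 27
    self_any_max: int = 8
    self_end_max: int = 3
    product_size_min: int = 100
    product_size_max: int = 450
    # paired-end geometry
    assumed_insert_size: int = 325
    spanning_end_tolerance: int = 0
    mid_trim_len: int = 0
    # Best-PAL selection
    best_pal_kmin: int = 4
    best_pal_kmax: int = 6
    best_pal_min_units_exclusive: int = 7
    best_pal_copy_criterion: str = "product"

    def __post_init__(self) -> None:
        if isinstance(self.platform, str):
            self.platform = Platform(self.platform)
        if not self.tm_min < self.tm_max:
            raise ValueError("tm_min must be < tm_max")
        if not self.kmin <= self.kmax:
            raise ValueError("kmin must be <= kmax")
        for name in (
            "min_total_len_2to4mer",
            "min_units_5mer",
            "min_units_6mer",
            "gc_clamp_len",
            "max_polyN",
            "primer_len_min",
            "primer_len_opt",
            "primer_len_max",
            "product_size_min",
            "product_size_max",
            "assumed_insert_size",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("mid_trim_len", "spanning_end_tolerance"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.best_pal_copy_criterion not in ("product", "min", "pair"):
            raise ValueError("best_pal_copy_criterion must be product|min|pair")

    def min_units(self, k: int) -> int:
        """Minimum complete units for a period-k array to qualify."""
        if k <= 4:
            return math.ceil(self.min_total_len_2to4mer / k)
        if k == 5:
            return self.min_units_5mer
        return self.min_units_6mer

    @property
    def product_size_range(self) -> tuple[int, int]:
        return (self.product_size_min, self.product_size_max)


_BOOL_STRINGS = {
    "1": True, "true": True, "yes": True, "on": True,
    "0": False, "false": False, "no": False, "off": False,
}


def _coerce(name: str, raw: str, kind: type):
    raw = raw.strip()
    if kind is bool:
        try:
            return _BOOL_STRINGS[raw.lower()]
        except KeyError:
            raise ValueError(raw)
    if kind is Platform:
        return Platform(raw.lower())
    return kind(raw)


def parse_control_file(path: str | Path) -> ScanConfig:
    """Parse a ``key = value`` control file into a `ScanConfig`.

    Blank lines and ``#`` comments are ignored; unknown keys produce a
    warning and are skipped; missing keys take their documented defaults.
    An unparseable value for a known key is fatal, naming the key and line.
    """
    kinds: dict[str, type] = {}
    for f in fields(ScanConfig):
        if f.name == "platform":
            kinds[f.name] = Platform
        else:
            kinds[f.name] = type(getattr(ScanConfig(), f.name))
    values = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(
                    f"{path}:{lineno}: expected 'key = value', got {line!r}"
                )
            key, _, raw = line.partition("=")
            key = key.strip()
            if key not in kinds:
                warnings.warn(f"{path}:{lineno}: unknown key {key!r} ignored")
                continue
            try:
                values[key] = _coerce(key, raw, kinds[key])
            except (ValueError, KeyError):
                raise ValueError(
                    f"{path}:{lineno}: cannot parse value {raw.strip()!r} "
                    f"for key {key!r}"
                ) from None
    return ScanConfig(**values)


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path)


def _sniff_format(path: str | Path) -> str:
    with _open_text(path) as fh:
        for line in fh:
            if line.strip():
                if line.startswith(">"):
                    return "fasta"
                if line.startswith("@"):
                    return "fastq"
                raise ValueError(f"{path}: not FASTA or FASTQ (first record "
                                 f"starts with {line[0]!r})")
    raise ValueError(f"{path}: empty input file")


_ALLOWED = set("ACGTN")


def _iter_reads(
    path: str | Path, mate_index: int | None, cfg: ScanConfig
) -> Iterator[ReadRecord]:
    fmt = _sniff_format(path)
    seen: set[str] = set()
    with _open_text(path) as fh:
        for idx, rec in enumerate(SeqIO.parse(fh, fmt)):
            bases = str(rec.seq).upper()
            if cfg.mid_trim_len:
                bases = bases[cfg.mid_trim_len:]
            extra = set(bases) - _ALLOWED
            if extra:
                raise ValueError(
                    f"{path}: record {idx} ({rec.id}): non-ACGTN base(s) "
                    f"{sorted(extra)}"
                )
            if rec.id in seen:
                raise ValueError(f"{path}: duplicate read id {rec.id!r}")
            seen.add(rec.id)
            yield ReadRecord(
                read_id=rec.id,
                bases=bases,
                mate_index=mate_index,
                platform=cfg.platform,
            )


def load_reads(
    path1: str | Path,
    path2: str | Path | None,
    cfg: ScanConfig,
) -> list[ReadRecord] | list[ReadPair]:
    """Load one read file (single-end) or two order-matched mate files.

    Format (FASTA vs FASTQ) is auto-detected from the first record; bases
    are uppercased; if ``cfg.mid_trim_len > 0`` the first that many bases of
    every read are removed before anything else.  In paired-end mode a
    record-count mismatch between the two files is fatal.
    """
    if path2 is None:
        reads = list(_iter_reads(path1, None, cfg))
        if not reads:
            raise ValueError(f"{path1}: no records")
        return reads
    it1 = _iter_reads(path1, 1, cfg)
    it2 = _iter_reads(path2, 2, cfg)
    pairs: list[ReadPair] = []
    sentinel = object()
    from itertools import zip_longest

    for m1, m2 in zip_longest(it1, it2, fillvalue=sentinel):
        if m1 is sentinel or m2 is sentinel:
            raise ValueError(
                f"mate files {path1} and {path2} have different record counts"
            )
        pairs.append(ReadPair(m1, m2))
    if not pairs:
        raise ValueError(f"{path1}, {path2}: no records")
    return pairs


PAL_TABLE_COLUMNS = [
    "readID", "motifs", "n_loci", "class", "primer_found",
    "fwd_seq", "rev_seq", "fwd_tm", "rev_tm", "fwd_gc_pct", "rev_gc_pct",
    "product_size_est", "pair_penalty",
    "fwd_count", "rev_count", "min_count", "product_count", "pair_count",
]


def _fmt2(x: float) -> str:
    return f"{x:.2f}"


def pal_table_row(rec: PALRecord) -> list[str]:
    p = rec.primers
    if p is None:
        primer_cols = [""] * 8
        count_cols = [""] * 5
    else:
        primer_cols = [
            p.fwd_seq, p.rev_seq, _fmt2(p.fwd_tm), _fmt2(p.rev_tm),
            _fmt2(p.fwd_gc), _fmt2(p.rev_gc), str(p.product_size_est),
            _fmt2(p.penalty),
        ]
        count_cols = [
            str(rec.fwd_count), str(rec.rev_count), str(rec.min_count),
            str(rec.product_count), str(rec.pair_count),
        ]
    return [
        rec.read_id, rec.motifs_str, str(rec.n_loci), rec.klass,
        "1" if p is not None else "0",
        *primer_cols, *count_cols,
    ]


def write_pal_table(records: Sequence[PALRecord], path: str | Path) -> None:
    """Write the tab-delimited locus table: header + one row per record.

    Floats are printed with 2 decimals; primer and count fields are empty
    strings when no primer pair was found (primer_found = 0).
    """
    with open(path, "w") as fh:
        fh.write("\t".join(PAL_TABLE_COLUMNS) + "\n")
        for rec in records:
            fh.write("\t".join(pal_table_row(rec)) + "\n")


def _parse_motifs(text: str) -> list[tuple[str, int]]:
    out = []
    for part in text.split(";"):
        part = part.strip()
        if not part:
            continue
        motif, _, rest = part.partition("(")
        out.append((motif, int(rest.rstrip(")"))))
    return out


def read_pal_table(path: str | Path) -> list[PALRecord]:
    """Re-parse a locus table written by `write_pal_table`.

    Reconstructs enough of each record (loci motifs/units, class, primer
    sequences and statistics, copy counts) for filtering; primer template
    coordinates are not stored in the table and come back as 0.
    """
    records: list[PALRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != PAL_TABLE_COLUMNS:
            raise ValueError(f"{path}: unexpected header {header!r}")
        for line in fh:
            row = dict(zip(PAL_TABLE_COLUMNS, line.rstrip("\n").split("\t")))
            loci = [
                SSRLocus(
                    read_id=row["readID"], mate_index=None,
                    motif=Motif(m), start=0, end=n * len(m),
                    units=n, unit=m, klass=row["class"],
                )
                for m, n in _parse_motifs(row["motifs"])
            ]
            primers = None
            if row["primer_found"] == "1":
                primers = PrimerPair(
                    fwd_seq=row["fwd_seq"], rev_seq=row["rev_seq"],
                    fwd_start=0, fwd_end=0, rev_start=0, rev_end=0,
                    fwd_tm=float(row["fwd_tm"]), rev_tm=float(row["rev_tm"]),
                    fwd_gc=float(row["fwd_gc_pct"]),
                    rev_gc=float(row["rev_gc_pct"]),
                    product_size_est=int(row["product_size_est"]),
                    penalty=float(row["pair_penalty"]),
                )
            rec = PALRecord(
                read_id=row["readID"], loci=loci, klass=row["class"],
                primers=primers,
            )
            if primers is not None:
                rec.fwd_count = int(row["fwd_count"])
                rec.rev_count = int(row["rev_count"])
                rec.min_count = int(row["min_count"])
                rec.product_count = int(row["product_count"])
                rec.pair_count = int(row["pair_count"])
            records.append(rec)
    return records
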