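"""End-to-end orchestration: scan reads, design primers, annotate, write.

The unit of work is a read (single-end) or an order-matched read pair.
Each unit with at least one detected SSR produces one output record; primer
design and copy-number annotation then run on those records when enabled.
The whole pipeline is deterministic for a fixed corpus and configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .copy_annotation import PALRecord, annotate_pals
from .io_config import Platform, ReadPair, ReadRecord, ScanConfig, write_pal_table
from .primer_design import build_pair_template, design_pal, map_mate2_locus, mask_flanks
from .ssr_scan import (
    SSRLocus,
    classify_read_ssrs,
    detect_spanning,
    find_perfect_ssrs,
    summarize_scan,
)


@dataclass
class PipelineResult:
    records: list[PALRecord]
    summary: "object"

    @property
    def pals(self) -> list[PALRecord]:
        """Records for which a conforming primer pair was found."""
        return [r for r in self.records if r.primers is not None]

    @property
    def pal_rate(self) -> float:
        """Discrete PALs over SSR-bearing units."""
        return len(self.pals) / len(self.records) if self.records else 0.0


def _unit_class(loci: Sequence[SSRLocus]) -> str:
    """One class label per output row; spanning outranks compound outranks
    broken outranks perfect when a pair's mates disagree."""
    for klass in ("compound", "broken"):
        if any(l.klass == klass for l in loci):
            if any(l.spans_gap for l in loci):
                return "spanning"
            return klass
    if any(l.spans_gap for l in loci):
        return "spanning"
    return "perfect"


def _process_se(read: ReadRecord, cfg: ScanConfig) -> PALRecord | None:
    loci = find_perfect_ssrs(read, cfg)
    if not loci:
        return None
    classify_read_ssrs(loci)
    rec = PALRecord(read_id=read.read_id, loci=loci, klass=_unit_class(loci))
    if cfg.design_primers:
        template = read.bases
        mask = mask_flanks(template, [(l.start, l.end) for l in loci], cfg)
        pair = design_pal(template, loci, cfg, mask=mask)
        if pair is not None:
            rec.primers = pair
            rec.bracketed_loci = [
                l for l in loci
                if pair.fwd_end <= l.start and l.end <= pair.rev_start
            ]
    return rec


def _process_pe(pair: ReadPair, cfg: ScanConfig) -> PALRecord | None:
    loci1 = find_perfect_ssrs(pair.mate1, cfg)
    loci2 = find_perfect_ssrs(pair.mate2, cfg)
    if not loci1 and not loci2:
        return None
    classify_read_ssrs(loci1)
    classify_read_ssrs(loci2)
    if loci1 and loci2:
        detect_spanning(pair, loci1, loci2, cfg)
    all_loci = loci1 + loci2
    rec = PALRecord(
        read_id=pair.mate1.read_id, loci=all_loci, klass=_unit_class(all_loci)
    )
    if cfg.design_primers:
        template, pm = build_pair_template(pair, cfg)
        targets = []
        for l in loci1:
            targets.append((l, (l.start, l.end, l.units)))
        for l in loci2:
            s, e = map_mate2_locus(l, pm)
            targets.append((l, (s, e, l.units)))
        spans = [t for _, t in targets]
        mask = mask_flanks(template, [(s, e) for s, e, _ in spans], cfg)
        best = design_pal(template, spans, cfg, mask=mask, pair_map=pm)
        if best is not None:
            rec.primers = best
            rec.bracketed_loci = [
                l for l, (s, e, _) in targets
                if best.fwd_end <= s and e <= best.rev_start
            ]
    return rec


def run_pipeline(
    units: Sequence[ReadRecord] | Sequence[ReadPair],
    cfg: ScanConfig,
    annotate: bool = True,
) -> PipelineResult:
    """Scan a corpus, design primers, and annotate copy numbers.

    `units` is a list of reads (single-end) or pairs (paired-end), e.g. from
    `io_config.load_reads` or `simdata.simulate_corpus`.  Copy-number
    annotation uses the same corpus as the counting library.
    """
    pe = cfg.platform is Platform.PE_ILLUMINA
    records: list[PALRecord] = []
    all_loci: list[SSRLocus] = []
    n_reads = 0
    n_bases = 0
    for unit in units:
        if pe:
            if not isinstance(unit, ReadPair):
                raise TypeError("paired-end mode expects ReadPair units")
            n_reads += 2
            n_bases += len(unit.mate1.bases) + len(unit.mate2.bases)
            rec = _process_pe(unit, cfg)
        else:
            if isinstance(unit, ReadPair):
                raise TypeError("single-end mode expects ReadRecord units")
            n_reads += 1
            n_bases += len(unit.bases)
            rec = _process_se(unit, cfg)
        if rec is not None:
            records.append(rec)
            all_loci.extend(rec.loci)
    if annotate and cfg.design_primers:
        annotate_pals(records, list(units))
    summary = summarize_scan(all_loci, n_reads, n_bases / 1e6)
    return PipelineResult(records=records, summary=summary)


def run_files(
    path1: str | Path,
    path2: str | Path | None,
    cfg: ScanConfig,
    out: str | Path | None = None,
) -> PipelineResult:
    """Load read file(s), run the pipeline, optionally write the PAL table."""
    from .io_config import load_reads

    units = load_reads(path1, path2, cfg)
    result = run_pipeline(units, cfg)
    if out is not None:
        write_pal_table(result.records, out)
    return result
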