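"""Stringency filtering of annotated PALs and the Best-PAL selection.

Three overlapping stringency criteria, ordered most to least stringent,
judge how repetitive a PAL's primers are in the read library:

* ``product`` -- forward count x reverse count; 1 means both primers were
  each seen exactly once in the entire read set;
* ``min``     -- min(forward, reverse); 1 means at least one primer is
  unique to the locus;
* ``pair``    -- co-occurrences of the pair in amplifiable orientation;
  least stringent because sequencing depth may simply be too low to catch
  repeated pairs.

Observation classes 1 / 2 / >2 summarize each criterion over a PAL set.
Because every primer occurs at least at its own source locus,
product <= 1 implies min <= 1 implies pair <= 1, so the filtered sets nest.

"Best PALs" are the ultra-high-quality subset: motif length 4-6 (easier to
score), strictly more than 7 observed repeat units (more likely
polymorphic), and a copy criterion at cutoff 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

from .copy_annotation import PALRecord

if TYPE_CHECKING:  # pragma: no cover
    from .io_config import ScanConfig

CRITERIA = ("product", "min", "pair")

_ATTR = {
    "product": "product_count",
    "min": "min_count",
    "pair": "pair_count",
}


def _statistic(rec: PALRecord, criterion: str) -> int:
    try:
        return getattr(rec, _ATTR[criterion])
    except KeyError:
        raise ValueError(
            f"unknown criterion {criterion!r}; expected one of {CRITERIA}"
        ) from None


@dataclass
class StringencyReport:
    """Counts and proportions of PALs in classes {=1, =2, >2} per criterion."""

    total: int
    counts: dict[str, dict[str, int]] = field(default_factory=dict)
    proportions: dict[str, dict[str, float]] = field(default_factory=dict)


def stringency_classes(pals: Sequence[PALRecord]) -> StringencyReport:
    """Classify each PAL under each stringency criterion into 1 / 2 / >2."""
    pals = [p for p in pals if p.primers is not None]
    counts: dict[str, dict[str, int]] = {}
    proportions: dict[str, dict[str, float]] = {}
    for criterion in CRITERIA:
        c = {"=1": 0, "=2": 0, ">2": 0}
        for rec in pals:
            v = _statistic(rec, criterion)
            c["=1" if v == 1 else "=2" if v == 2 else ">2"] += 1
        counts[criterion] = c
        n = len(pals)
        proportions[criterion] = {
            k: (v / n if n else 0.0) for k, v in c.items()
        }
    return StringencyReport(total=len(pals), counts=counts,
                            proportions=proportions)


def filter_pals(
    pals: Sequence[PALRecord], criterion: str, cutoff: int
) -> list[PALRecord]:
    """Keep PALs whose chosen copy statistic is at most `cutoff`.

    Monotone in the cutoff and order-stable.  Records without primers are
    never kept (they have no copy statistics).
    """
    if cutoff < 1:
        raise ValueError("cutoff must be >= 1")
    if criterion not in CRITERIA:
        raise ValueError(
            f"unknown criterion {criterion!r}; expected one of {CRITERIA}"
        )
    return [
        rec for rec in pals
        if rec.primers is not None and _statistic(rec, criterion) <= cutoff
    ]


def _best_target_locus(rec: PALRecord):
    """The locus a Best-PAL decision judges: the bracketed (or, failing
    that, any) locus with the most repeat units."""
    pool = rec.bracketed_loci or rec.loci
    return max(pool, key=lambda l: l.units)


def best_pals(pals: Sequence[PALRecord], cfg: "ScanConfig") -> list[PALRecord]:
    """Ultra-high-quality subset: long motifs, long arrays, unique primers.

    Keeps PALs whose judged locus has motif length within
    [best_pal_kmin, best_pal_kmax] (default 4-6) and strictly more than
    ``best_pal_min_units_exclusive`` units (default 7, i.e. >= 8), and whose
    configured copy criterion (default ``product``) is 1.
    """
    out = []
    for rec in pals:
        if rec.primers is None or not rec.loci:
            continue
        locus = _best_target_locus(rec)
        if not (cfg.best_pal_kmin <= locus.k <= cfg.best_pal_kmax):
            continue
        if locus.units <= cfg.best_pal_min_units_exclusive:
            continue
        if _statistic(rec, cfg.best_pal_copy_criterion) > 1:
            continue
        out.append(rec)
    return out
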