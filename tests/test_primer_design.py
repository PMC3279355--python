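"""Flank masking, melting temperature, and primer-pair selection."""

import math
import random

import pytest

from palfinder import (
    ReadPair,
    ReadRecord,
    ScanConfig,
    build_pair_template,
    design_pal,
    mask_flanks,
    melting_temp,
    revcomp,
)
from palfinder.primer_design import (
    PairMap,
    _enumerate_primers,
    _max_homopolymer,
    gc_percent,
    map_mate2_locus,
)
from palfinder.ssr_scan import Motif, SSRLocus

from conftest import random_dna

# SantaLucia unified nearest-neighbor parameters (dH kcal/mol, dS cal/mol/K)
# transcribed from the published table for the hand oracle below
_NN = {
    "AA": (-7.9, -22.2), "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "GT": (-8.4, -22.4), "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}
_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


def _oracle_tm(seq: str) -> float:
    """Independent NN Tm: published doublet table, terminal penalties,
    SantaLucia entropy salt correction at 50 mM Na+, 50 nM oligo."""
    dh = ds = 0.0
    for end in (seq[0], seq[-1]):
        if end in "AT":
            dh, ds = dh + 2.3, ds + 4.1
        else:
            dh, ds = dh + 0.1, ds - 2.8
    for i in range(len(seq) - 1):
        xy = seq[i : i + 2]
        if xy not in _NN:
            xy = _COMP[xy[1]] + _COMP[xy[0]]
        h, s = _NN[xy]
        dh, ds = dh + h, ds + s
    ds += 0.368 * (len(seq) - 1) * math.log(0.05)
    return 1000 * dh / (ds + 1.987 * math.log(50e-9)) - 273.15


class TestMeltingTemp:
    @pytest.mark.parametrize(
        "seq",
        [
            "ACGTGCATGCATTGCAGCTG",
            "GGCATCGTTAGCTAGCCGTAGG",
            "TTGACCGGTTAACCGGTTGACC",
            "CAGTCAGTCAGTCAGTCG",
        ],
    )
    def test_matches_hand_computed_nn_sum(self, seq):
        assert melting_temp(seq) == pytest.approx(_oracle_tm(seq), abs=0.5)

    def test_appending_g_raises_tm(self):
        rng = random.Random(3)
        for _ in range(30):
            primer = random_dna(rng, 20)
            assert melting_temp(primer + "G") > melting_temp(primer)

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            melting_temp("ACGTNACGTACGTACGTACG")


class TestMaskFlanks:
    def _mask(self, template, spans=(), **kw):
        return mask_flanks(template, spans, ScanConfig(platform="454"), **kw)

    def test_homopolymer_six_masked(self):
        rng = random.Random(4)
        t = "GTCAGTCGAT" + "A" * 6 + "CGATCGGATC"
        m = self._mask(t)
        assert all(m[10:16])
        assert not any(m[:10]) and not any(m[16:])

    def test_flanking_ssr_masked(self):
        t = "GTCAGTCGAT" + "AG" * 7 + "CGATCGGATC"
        m = self._mask(t)
        assert all(m[10:24])

    def test_random_flank_unmasked_target_masked(self):
        rng = random.Random(5)
        from palfinder.simdata import _clean_background

        cfg = ScanConfig(platform="454")
        t = _clean_background(rng, 50, 0.5, cfg)
        m = mask_flanks(t, [(20, 30)], cfg)
        assert all(m[20:30])
        assert not any(m[:20]) and not any(m[30:])

    def test_n_bases_masked(self):
        m = self._mask("ACGTNNNNACGT")
        assert bytes(m) == b"\x00\x00\x00\x00\x01\x01\x01\x01\x00\x00\x00\x00"

    def test_user_pattern_file_motifs_masked(self):
        t = "ACGTGGATCCACGT"
        m = self._mask(t, extra_motifs=["GGATCC"])
        assert all(m[4:10]) and not any(m[:4]) and not any(m[10:])


def _fixture_template(seed=2, unit="AATG", units=8, flank=60, gc=0.55):
    """Unique GC-balanced flanks around a planted array; frozen seed."""
    from palfinder.simdata import _clean_background

    cfg = ScanConfig(platform="454")
    rng = random.Random(seed)
    left = _clean_background(rng, flank, gc, cfg)
    right = _clean_background(rng, flank, gc, cfg)
    assert left[-1] != unit[-1] and right[0] != unit[0]
    template = left + unit * units + right
    target = (flank, flank + len(unit) * units, units)
    return template, target, cfg


class TestDesignPal:
    def test_pair_brackets_all_units(self):
        template, target, cfg = _fixture_template()
        pair = design_pal(template, [target], cfg)
        assert pair is not None
        assert pair.bracketed_units == 8
        # primers flank the repeat and bind the template where claimed
        assert template[pair.fwd_start : pair.fwd_end] == pair.fwd_seq
        assert revcomp(template[pair.rev_start : pair.rev_end]) == pair.rev_seq
        assert pair.fwd_end <= target[0] and pair.rev_start >= target[1]

    def test_every_constraint_holds_on_returned_pair(self):
        template, target, cfg = _fixture_template()
        pair = design_pal(template, [target], cfg)
        for seq, tm in ((pair.fwd_seq, pair.fwd_tm), (pair.rev_seq, pair.rev_tm)):
            assert gc_percent(seq) > cfg.gc_min_pct
            assert cfg.tm_min <= tm <= cfg.tm_max
            assert all(b in "GC" for b in seq[-cfg.gc_clamp_len:])
            assert _max_homopolymer(seq) <= cfg.max_polyN
            assert cfg.primer_len_min <= len(seq) <= cfg.primer_len_max
        assert abs(pair.fwd_tm - pair.rev_tm) <= cfg.tm_pair_maxdiff
        lo, hi = cfg.product_size_range
        assert lo <= pair.product_size_est <= hi

    def test_no_left_flank_returns_none(self):
        template, target, cfg = _fixture_template()
        t0 = template[target[0]:]  # repeat starts at base 0
        assert design_pal(t0, [(0, target[1] - target[0], 8)], cfg) is None

    def test_at_only_flanks_return_none(self):
        rng = random.Random(9)
        cfg = ScanConfig(platform="454")
        # AT alphabet cannot satisfy the GC clamp
        left = "ATTAATTATAATATTAATTATTAATATTATAATTATATTA"
        right = "TAATATTAATTATTAATATTATAATTATATTAATTATAAT"
        template = left + "AATG" * 8 + right
        assert design_pal(template, [(40, 72, 8)], cfg) is None

    def test_deterministic(self):
        template, target, cfg = _fixture_template()
        assert design_pal(template, [target], cfg) == design_pal(
            template, [target], cfg
        )

    def test_unit_maximization_beats_penalty(self):
        """Exhaustive-oracle check: no valid candidate pair brackets more
        repeat units than the returned pair, and among pairs with that
        many units none has a lower penalty."""
        template, target, cfg = _fixture_template(seed=3)
        mask = mask_flanks(template, [(target[0], target[1])], cfg)
        pair = design_pal(template, [target], cfg, mask=mask)
        fwd, rev = _enumerate_primers(template, mask, cfg)
        lo, hi = cfg.product_size_range
        best_units, best_pen = 0, None
        for fs, fe, fseq, ftm in fwd:
            for rs, re_, rseq, rtm in rev:
                if rs < fe or abs(ftm - rtm) > cfg.tm_pair_maxdiff:
                    continue
                if not (lo <= re_ - fs <= hi):
                    continue
                units = target[2] if (fe <= target[0] and target[1] <= rs) else 0
                if units == 0:
                    continue
                pen = (
                    abs(ftm - 60.5) + abs(rtm - 60.5)
                    + 0.5 * (abs(fe - fs - 20) + abs(re_ - rs - 20))
                    + abs(ftm - rtm)
                )
                if units > best_units or (
                    units == best_units
                    and (best_pen is None or pen < best_pen)
                ):
                    best_units, best_pen = units, pen
        assert pair.bracketed_units == best_units
        assert pair.penalty == pytest.approx(best_pen)

    def test_compound_pair_prefers_more_units(self):
        """With two arrays on one template, a pair bracketing both (12
        units) beats any pair bracketing only one, even at worse penalty."""
        from palfinder.simdata import _clean_background

        cfg = ScanConfig(platform="454")
        rng = random.Random(12)
        mid = None
        for _ in range(100):
            left = _clean_background(rng, 55, 0.55, cfg)
            mid_c = _clean_background(rng, 45, 0.55, cfg)
            right = _clean_background(rng, 55, 0.55, cfg)
            a = "AATG" * 8
            b = "ACCTG" * 4
            if left[-1] == "G" or mid_c[0] == "A" or mid_c[-1] == "G":
                continue
            if right[0] == "A":
                continue
            template = left + a + mid_c + b + right
            spans = [
                (55, 55 + 32, 8),
                (55 + 32 + 45, 55 + 32 + 45 + 20, 4),
            ]
            pair = design_pal(template, spans, cfg)
            if pair is not None:
                assert pair.bracketed_units in (8, 4, 12)
                if pair.bracketed_units == 12:
                    return
        pytest.skip("no template admitting a both-bracketing pair found")


class TestPairTemplate:
    def _pair(self, b1, b2):
        return ReadPair(
            ReadRecord("p", b1, 1, "illumina"), ReadRecord("p", b2, 2, "illumina")
        )

    def test_gap_padding_to_insert_size(self, cfg):
        rng = random.Random(13)
        pair = self._pair(random_dna(rng, 114), random_dna(rng, 114))
        template, pm = build_pair_template(pair, cfg)
        assert pm == PairMap(114, 97, 114)
        assert len(template) == 325
        assert template[114:211] == "N" * 97
        assert template[:114] == pair.mate1.bases
        assert template[211:] == revcomp(pair.mate2.bases)

    def test_long_mates_clamp_gap_to_zero(self):
        cfg = ScanConfig(assumed_insert_size=200)
        rng = random.Random(14)
        pair = self._pair(random_dna(rng, 114), random_dna(rng, 114))
        template, pm = build_pair_template(pair, cfg)
        assert pm.gap == 0
        assert len(template) == 228

    def test_se_mode_is_an_error(self, se_cfg):
        rng = random.Random(15)
        pair = self._pair(random_dna(rng, 50), random_dna(rng, 50))
        with pytest.raises(ValueError):
            build_pair_template(pair, se_cfg)

    def test_mate2_locus_maps_into_revcomp_segment(self, cfg):
        rng = random.Random(16)
        b2 = random_dna(rng, 50) + "AATG" * 8 + random_dna(rng, 32)
        pair = self._pair(random_dna(rng, 114), b2)
        template, pm = build_pair_template(pair, cfg)
        locus = SSRLocus("p", 2, Motif("AATG"), 50, 82, 8, "AATG")
        s, e = map_mate2_locus(locus, pm)
        assert template[s:e] == revcomp(b2[50:82])

    def test_primers_never_overlap_gap(self, cfg):
        """A template whose only clean flanks touch the N gap yields no
        primer landing inside the gap."""
        rng = random.Random(17)
        from palfinder.simdata import _clean_background

        b1 = _clean_background(rng, 82, 0.55, cfg) + "AATG" * 8
        b2 = _clean_background(rng, 114, 0.55, cfg)
        pair = self._pair(b1, b2)
        template, pm = build_pair_template(pair, cfg)
        spans = [(82, 114, 8)]
        result = design_pal(template, spans, cfg, pair_map=pm)
        if result is not None:
            assert "N" not in template[result.fwd_start : result.fwd_end]
            assert "N" not in template[result.rev_start : result.rev_end]
            assert result.spans_insert_gap
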