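import pytest

from refbias.assign import (
    AlleleCall,
    assign_read_context,
    assign_read_naive,
    tally_site,
    tally_sites,
)
from refbias.io import AlignedRead, PhasedVariant, ReadTruth
from refbias.variants import AssignmentConfig, HetSite, build_context, extend_effective, prepare_sites

from conftest import random_seq


def _prepared_site(ref_seq, pos, ref, alt, gt=(0, 1)):
    cfg = AssignmentConfig()
    s = HetSite(variant=PhasedVariant("c", pos, ref, alt, gt))
    build_context(s, ref_seq, [], cfg)
    extend_effective(s, ref_seq, cfg)
    return s


REF = random_seq(200, 20)
SNV_POS = 100
SNV_REF = REF[SNV_POS - 1]
SNV_ALT = "A" if SNV_REF != "A" else "C"


def _read(pos, seq, cigar=None, mapq=42, truth=None, rid="r"):
    cigar = cigar or [("M", len(seq))]
    return AlignedRead(rid, "c", pos, cigar, mapq, seq, truth)


def _ref_window(start, end):  # 1-based inclusive slice of REF
    return REF[start - 1 : end]


class TestNaive:
    def test_snv_ref_and_alt(self):
        site = _prepared_site(REF, SNV_POS, SNV_REF, SNV_ALT)
        ref_read = _read(81, _ref_window(81, 120))
        assert assign_read_naive(site, ref_read) is AlleleCall.REF
        alt_seq = _ref_window(81, 120)
        alt_seq = alt_seq[:19] + SNV_ALT + alt_seq[20:]
        assert assign_read_naive(site, _read(81, alt_seq)) is AlleleCall.ALT

    def test_shifted_gap_is_other(self):
        """A deletion whose gap the aligner placed one repeat unit away from
        the VCF position extracts a partial allele -> OTHER."""
        left = random_seq(60, 21)
        right = random_seq(60, 22)
        ref = left + "G" + "ATTC" * 3 + "T" + right
        site = _prepared_site(ref, 61, "G" + "ATTC" * 2, "G")
        # ALT read: sequence lacks two units; gap placed one unit right of VCF spot
        seq = left[-30:] + "G" + "ATTC" + "T" + right[:30]
        read = _read(31, seq, [("M", 35), ("D", 8), ("M", 31)])
        assert assign_read_naive(site, read) is AlleleCall.OTHER

    def test_never_both(self):
        site = _prepared_site(REF, SNV_POS, SNV_REF, SNV_ALT)
        for start in range(70, 100):
            call = assign_read_naive(site, _read(start, _ref_window(start, start + 39)))
            assert call in (AlleleCall.REF, AlleleCall.OTHER)


class TestContextAware:
    def test_full_alt_context_match(self):
        site = _prepared_site(REF, SNV_POS, SNV_REF, SNV_ALT)
        seq = _ref_window(81, 120)
        seq = seq[:19] + SNV_ALT + seq[20:]
        assert assign_read_context(site, _read(81, seq)) is AlleleCall.ALT

    def test_suffix_only_match_is_ref(self):
        """Read truncated mid-flank, matching a suffix of ref_context only."""
        site = _prepared_site(REF, SNV_POS, SNV_REF, SNV_ALT)
        # read starts 2 bases left of the SNV: left flank truncated
        read = _read(SNV_POS - 2, _ref_window(SNV_POS - 2, SNV_POS + 37))
        assert assign_read_context(site, read) is AlleleCall.REF

    def test_repeat_not_spanned_is_both(self):
        left = random_seq(60, 23)
        right = random_seq(60, 24)
        ref = left + "G" + "ATTC" * 7 + "T" + right
        site = _prepared_site(ref, 61, "GATTC", "G")
        # REF-haplotype read ending inside the tract: cannot span the
        # effective variant
        read = _read(41, ref[40:80])
        assert assign_read_context(site, read) is AlleleCall.BOTH

    def test_two_flank_errors_are_other(self):
        site = _prepared_site(REF, SNV_POS, SNV_REF, SNV_ALT)
        seq = list(_ref_window(81, 120))
        for off in (17, 21):  # both flanks corrupted, site mid-read
            seq[off] = "A" if seq[off] != "A" else "G"
        assert assign_read_context(site, _read(81, "".join(seq))) is AlleleCall.OTHER

    def test_unanchored_insertion_right_anchor(self):
        """Read whose inserted prefix is unanchored on the left still matches
        the ALT context through its right-anchored portion."""
        ins = "TTAGTTCGAA"
        pos = 100
        site = _prepared_site(REF, pos, REF[pos - 1], REF[pos - 1] + ins)
        # read begins mid-insertion: soft-clipped inserted bases + reference
        seq = ins[4:] + _ref_window(pos + 1, pos + 40)
        read = _read(pos + 1, seq, [("S", 6), ("M", 40)])
        # matching is purely sequence-based; the suffix of alt_context
        # (insertion tail + right flank) appears at the read start
        assert assign_read_context(site, read) is AlleleCall.ALT

    def test_symmetry_swapping_alleles(self):
        """Swapping REF and ALT (and the phase) swaps the calls exactly."""
        site = _prepared_site(REF, SNV_POS, SNV_REF, SNV_ALT, gt=(0, 1))
        swapped = _prepared_site(REF_SWAPPED, SNV_POS, SNV_ALT, SNV_REF, gt=(1, 0))
        reads = []
        for start in range(70, 100, 3):
            seq = _ref_window(start, start + 39)
            reads.append(_read(start, seq))
            alt_seq = seq[: SNV_POS - start] + SNV_ALT + seq[SNV_POS - start + 1 :]
            reads.append(_read(start, alt_seq))
        flip = {AlleleCall.REF: AlleleCall.ALT, AlleleCall.ALT: AlleleCall.REF}
        for r in reads:
            a = assign_read_context(site, r)
            b = assign_read_context(swapped, r)
            assert b == flip.get(a, a)


# reference in which the SNV ALT allele is the reference base
REF_SWAPPED = REF[: SNV_POS - 1] + SNV_ALT + REF[SNV_POS:]


class TestGapShiftRobustness:
    def test_context_unchanged_naive_degraded(self, gap_shift_run, tandem_repeat_fixture):
        """Re-placed gaps flip naive REF/ALT calls to OTHER but leave
        context-aware calls equal to truth (exact recovery)."""
        _, variant = tandem_repeat_fixture
        run = gap_shift_run
        site = next(s for s in run.sites if not s.disregarded)
        n_other_naive = 0
        for r in run.aligned:
            if not r.overlaps(site.eff_start, site.eff_end):
                continue
            if assign_read_naive(site, r) is AlleleCall.OTHER:
                n_other_naive += 1
            call = assign_read_context(site, r)
            if call in (AlleleCall.REF, AlleleCall.ALT):
                want = AlleleCall.REF if r.truth.hap_index - 1 == variant.ref_hap() else AlleleCall.ALT
                assert call is want
            else:
                assert call is AlleleCall.BOTH  # never OTHER on error-free reads
        assert n_other_naive >= 1


class TestTally:
    def test_counts(self):
        site = _prepared_site(REF, SNV_POS, SNV_REF, SNV_ALT)
        reads = []
        for i in range(6):  # REF reads
            reads.append(_read(81, _ref_window(81, 120), rid=f"ref{i}"))
        for i in range(4):  # ALT reads
            seq = _ref_window(81, 120)
            reads.append(_read(81, seq[:19] + SNV_ALT + seq[20:], rid=f"alt{i}"))
        bad = list(_ref_window(81, 120))
        bad[19] = "N"
        reads.append(_read(81, "".join(bad).replace("N", "G" if SNV_REF != "G" else "T"), rid="oth"))
        ev = tally_site(site, reads)
        assert (ev.n_ref, ev.n_alt) == (6, 4)
        assert ev.n_other + ev.n_both == 1
        assert ev.mean_mapq == 42.0

    def test_zero_reads(self):
        site = _prepared_site(REF, SNV_POS, SNV_REF, SNV_ALT)
        ev = tally_site(site, [])
        assert ev.n_overlapping == 0 and ev.mean_mapq == 0.0

    def test_mismapped_counted_from_truth(self):
        site = _prepared_site(REF, SNV_POS, SNV_REF, SNV_ALT)
        reads = [
            _read(81, _ref_window(81, 120), truth=ReadTruth(1, "decoy", 1, 40), rid=f"f{i}", mapq=0)
            for i in range(6)
        ]
        ev = tally_site(site, reads)
        assert ev.n_mismapped == 6
        assert ev.mean_mapq == 0.0

    def test_cohort_match_tallies_all_members(self):
        """A read matching the combined cohort string is tallied for every
        member site, per the cohort-first rule."""
        ref = random_seq(300, 25)
        p1, p2 = 150, 160
        v1 = PhasedVariant("c", p1, ref[p1 - 1], "A" if ref[p1 - 1] != "A" else "C", (0, 1))
        v2 = PhasedVariant("c", p2, ref[p2 - 1], "A" if ref[p2 - 1] != "A" else "C", (0, 1))
        sites, cohorts = prepare_sites([v1, v2], ref)
        assert len(cohorts) == 1 and len(cohorts[0].members) == 2
        # hap2 (ALT-carrying for both) read across the cohort
        alt_seq = list(ref[p1 - 21 : p2 + 20])
        alt_seq[20] = v1.alt_allele
        alt_seq[p2 - p1 + 20] = v2.alt_allele
        read = _read(p1 - 20, "".join(alt_seq), rid="c1")
        evidence = tally_sites(sites, cohorts, [read])
        assert evidence[p1].n_alt == 1
        assert evidence[p2].n_alt == 1
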