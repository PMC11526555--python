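"""Read QC, anchored extraction, tallying and genotype calling."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apestr.allele_caller import (
    AlleleTally,
    CallStatus,
    ExtractStatus,
    GenotypeCall,
    amplification_matrix,
    assign_read,
    call_genotype,
    call_sample,
    extract_repeat_region,
    read_qc,
    tally_alleles,
)

def q(n, quality=30):
    return chr(quality + 33) * n


class TestReadQC:
    def test_short_read_dropped(self):
        assert read_qc([("r1", "A" * 49, q(49))], min_len=50) == []

    def test_good_read_unchanged(self):
        out = read_qc([("r1", "A" * 100, q(100))], min_len=50)
        assert out == [("r1", "A" * 100, q(100))]

    def test_low_quality_tail_trimmed(self):
        # Q30 until base 60, Q2 afterwards. Window means (width 4, Q>=20):
        # the first failing window starts at 58 ((30+30+2+2)/4 = 16 < 20),
        # so the read is cut to 58 bases.
        seq = "A" * 100
        qual = q(60) + chr(2 + 33) * 40
        out = read_qc([("r1", seq, qual)], min_len=50, qual_window=4, qual_mean=20)
        assert len(out) == 1 and len(out[0][1]) == 58

    def test_trimmed_below_min_len_dropped(self):
        qual = q(40) + chr(2 + 33) * 60
        assert read_qc([("r1", "A" * 100, qual)], min_len=50) == []

    def test_adapter_prefix_stripped(self):
        out = read_qc([("r1", "ACGT" + "T" * 60, q(64))], min_len=50, adapter="ACGT")
        assert out[0][1] == "T" * 60

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="r1"):
            read_qc([("r1", "ACGT", q(3))])


class TestExtraction:
    def test_clean_read(self, toy_locus):
        read = toy_locus.anchor5 + "AATG" * 7 + toy_locus.flank3
        status, region = extract_repeat_region(read, toy_locus)
        assert status is ExtractStatus.OK and region == "AATG" * 7

    def test_truncated_read_missing_flank(self, toy_locus):
        read = toy_locus.anchor5 + "AATG" * 7
        status, _ = extract_repeat_region(read, toy_locus)
        assert status is ExtractStatus.NO_FLANK

    def test_anchor_with_one_mismatch(self, toy_locus):
        anchor = "A" + toy_locus.anchor5[1:]  # mutate first anchor base
        read = anchor + "AATG" * 7 + toy_locus.flank3
        status, region = extract_repeat_region(read, toy_locus, max_mismatch=1)
        assert status is ExtractStatus.OK and region == "AATG" * 7
        status, _ = extract_repeat_region(read, toy_locus, max_mismatch=0)
        assert status is ExtractStatus.NO_ANCHOR

    def test_duplicate_anchor_is_ambiguous(self, toy_locus):
        read = toy_locus.anchor5 + toy_locus.anchor5 + "AATG" * 7 + toy_locus.flank3
        status, _ = extract_repeat_region(read, toy_locus)
        assert status is ExtractStatus.AMBIGUOUS

    def test_region_outside_expected_range(self, toy_locus):
        read = toy_locus.anchor5 + "AATG" * 30 + toy_locus.flank3
        status, _ = extract_repeat_region(read, toy_locus)
        assert status is ExtractStatus.OUT_OF_RANGE

    def test_assign_read_picks_right_locus(self, toy_locus, compound_locus):
        read = compound_locus.anchor5 + "GGAA" * 5 + compound_locus.flank3
        outcome, name, region = assign_read(read, [toy_locus, compound_locus])
        assert outcome == "ok" and name == "TOY2" and region == "GGAA" * 5

    def test_assign_read_unassigned(self, toy_locus, compound_locus):
        outcome, _, _ = assign_read("ACGT" * 25, [toy_locus, compound_locus])
        assert outcome == "unassigned"


class TestTally:
    def test_identical_reads_one_entry(self, toy_locus):
        reads = [toy_locus.anchor5 + "AATG" * 7 + toy_locus.flank3] * 100
        tally = tally_alleles(reads, toy_locus)
        assert tally.counts == {"AATG" * 7: 100}
        assert tally.total + tally.n_unassigned + tally.n_ambiguous == 100

    def test_stutter_folding(self, toy_locus):
        full = toy_locus.anchor5 + "AATG" * 7 + toy_locus.flank3
        minus1 = toy_locus.anchor5 + "AATG" * 6 + toy_locus.flank3
        reads = [full] * 100 + [minus1] * 8
        tally = tally_alleles(reads, toy_locus, stutter_fold=True, stutter_ratio=0.15)
        assert tally.counts == {"AATG" * 7: 108}
        assert tally.stutter_merged == {"AATG" * 6: "AATG" * 7}

    def test_true_het_not_folded(self, toy_locus):
        full = toy_locus.anchor5 + "AATG" * 7 + toy_locus.flank3
        minus1 = toy_locus.anchor5 + "AATG" * 6 + toy_locus.flank3
        reads = [full] * 100 + [minus1] * 60
        tally = tally_alleles(reads, toy_locus, stutter_fold=True, stutter_ratio=0.15)
        assert tally.counts == {"AATG" * 7: 100, "AATG" * 6: 60}


class TestCallGenotype:
    def test_low_depth(self):
        assert call_genotype({"A": 15}, ref_het_depth=50)[2] is CallStatus.LOW_DEPTH

    def test_failed(self):
        assert call_genotype({}, ref_het_depth=50)[2] is CallStatus.FAILED

    def test_balanced_het(self):
        alleles, depths, status = call_genotype({"A": 100, "B": 95}, ref_het_depth=100)
        assert status is CallStatus.GENOTYPED_HET and set(alleles) == {"A", "B"}

    def test_homozygote_by_depth(self):
        alleles, depths, status = call_genotype({"A": 210}, ref_het_depth=100, tau=1.5)
        assert status is CallStatus.GENOTYPED_HOM and alleles == ["A"]

    def test_het_with_null_by_depth(self):
        _, _, status = call_genotype({"A": 95}, ref_het_depth=100, tau=1.5)
        assert status is CallStatus.HET_WITH_NULL

    @settings(derandomize=True, max_examples=100)
    @given(d1=st.integers(150, 400), extra=st.integers(0, 200))
    def test_homozygote_monotone_in_depth(self, d1, extra):
        """Raising a homozygote's depth can never flip it to het-with-null."""
        s1 = call_genotype({"A": d1}, ref_het_depth=100)[2]
        s2 = call_genotype({"A": d1 + extra}, ref_het_depth=100)[2]
        if s1 is CallStatus.GENOTYPED_HOM:
            assert s2 is CallStatus.GENOTYPED_HOM

    def test_ref_required_for_single_allele(self):
        with pytest.raises(ValueError):
            call_genotype({"A": 100})


class TestCallSample:
    def test_sample_reference_from_own_hets(self, toy_locus, compound_locus):
        tallies = {
            # unambiguous het at TOY2 fixes ref_het_depth at 50
            "TOY2": AlleleTally(counts={"GGAA" * 5: 50, "GGAA" * 6: 50}),
            # single allele at depth 60 < 1.5 * 50 -> het with null
            "TOY1": AlleleTally(counts={"AATG" * 7: 60}),
        }
        loci = {"TOY1": toy_locus, "TOY2": compound_locus}
        calls = {c.locus: c for c in call_sample(tallies, loci, "s1")}
        assert calls["TOY2"].status is CallStatus.GENOTYPED_HET
        assert calls["TOY1"].status is CallStatus.HET_WITH_NULL
        # and with depth >= 75 it becomes a homozygote
        tallies["TOY1"] = AlleleTally(counts={"AATG" * 7: 80})
        calls = {c.locus: c for c in call_sample(tallies, loci, "s1")}
        assert calls["TOY1"].status is CallStatus.GENOTYPED_HOM
        assert calls["TOY1"].alleles[0].ce_label == "7"


def _call(sample, locus, status):
    return GenotypeCall(sample, locus, (), (), status)


class TestAmplificationMatrix:
    def test_all_genotyped_is_core(self):
        calls = [
            _call(s, l, CallStatus.GENOTYPED_HET)
            for s in ("a1", "a2", "b1", "b2")
            for l in ("L1", "L2", "L3")
        ]
        groups = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        summary = amplification_matrix(calls, groups)
        assert summary.n_core == 3
        assert set(summary.locus_groups.values()) == {"core"}

    def test_whole_group_failure_is_restricted(self):
        calls = [_call(s, "L1", CallStatus.GENOTYPED_HOM) for s in ("a1", "a2")]
        calls += [_call(s, "L1", CallStatus.FAILED) for s in ("b1", "b2")]
        groups = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        summary = amplification_matrix(calls, groups)
        assert summary.locus_groups["L1"] == "failed_or_restricted"

    def test_individual_dropout_is_partial(self):
        calls = [_call(s, "L1", CallStatus.GENOTYPED_HOM) for s in ("a1", "a2", "b1")]
        calls += [_call("b2", "L1", CallStatus.LOW_DEPTH)]
        groups = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        assert amplification_matrix(calls, groups).locus_groups["L1"] == "partial"

    def test_unknown_sample_rejected(self):
        with pytest.raises(ValueError, match="x1"):
            amplification_matrix([_call("x1", "L1", CallStatus.FAILED)], {})
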