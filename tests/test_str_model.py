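"""Repeat-array decomposition, classification and naming."""

import json

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apestr.str_model import (
    AlleleStructure,
    Motif,
    RepeatBlock,
    StructuralClass,
    ce_designation,
    ce_label_from_length,
    classify_structure,
    decompose_repeat_region,
    format_bracketed,
    is_repeat_derived,
    parse_bracketed,
    structure_from_extracted,
    structure_from_region,
    structure_to_record,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


class TestDecompose:
    def test_single_perfect_run(self):
        blocks, irq = decompose_repeat_region("AATGAATGAATG", ["AATG"], 2)
        assert [(b.motif.sequence, b.count, b.start) for b in blocks] == [("AATG", 3, 0)]
        assert irq == []

    def test_compound_two_motifs(self):
        blocks, irq = decompose_repeat_region("GGAAGGAAGGAAGGCAGGCA", ["GGAA", "GGCA"], 2)
        assert [(b.motif.sequence, b.count) for b in blocks] == [("GGAA", 3), ("GGCA", 2)]
        assert irq == []

    def test_partial_copy_interruption_is_derived(self):
        blocks, irq = decompose_repeat_region("AGATAGATAGATGATAGATAGAT", ["AGAT"], 2)
        assert [(b.count, b.start) for b in blocks] == [(3, 0), (2, 15)]
        assert [(x.sequence, x.start, x.derived) for x in irq] == [("GAT", 12, True)]

    def test_single_copy_below_min_run_is_interstitial(self):
        blocks, irq = decompose_repeat_region("AATGCCCCC", ["AATG"], 2)
        assert blocks == []
        assert len(irq) == 1 and irq[0].sequence == "AATGCCCCC"

    def test_rejects_non_dna_with_position(self):
        with pytest.raises(ValueError, match="position 4"):
            decompose_repeat_region("AATGNATG", ["AATG"], 2)

    def test_rejects_empty_motif_set(self):
        with pytest.raises(ValueError):
            decompose_repeat_region("AATG", [], 2)

    @settings(derandomize=True, max_examples=300)
    @given(region=dna)
    def test_reconstruction_invariant(self, region):
        """Blocks plus interruptions always concatenate back to the region."""
        blocks, irq = decompose_repeat_region(region, ["AGAT", "AG", "GATA"], 2)
        parts = sorted(
            [(b.start, b.sequence) for b in blocks] + [(x.start, x.sequence) for x in irq]
        )
        assert "".join(s for _, s in parts) == region


class TestDerived:
    @pytest.mark.parametrize(
        "seq,motifs,expect",
        [
            ("GACA", ["GATA"], True),  # Hamming 1
            ("AATA", ["GATA"], True),
            ("GAT", ["GATA"], True),  # one-base-short partial copy
            ("GAT", ["AGAT"], True),  # partial copy in shifted phase
            ("CCTTC", ["GATA"], False),  # unrelated insertion
            ("GG", ["GATA"], False),
        ],
    )
    def test_examples(self, seq, motifs, expect):
        assert is_repeat_derived(seq, motifs) is expect


class TestClassify:
    def _mk(self, text, motifs):
        return parse_bracketed(text, motifs).structural_class

    def test_methods_taxonomy(self):
        """The six named architectures plus unclassified."""
        assert self._mk("[GATA]5", ["GATA"]) == StructuralClass.PERFECT
        assert self._mk("[GATA]4 CCTTC [GATA]3", ["GATA"]) == StructuralClass.INTERRUPTED
        assert self._mk("[GATA]4 GACA [GATA]3", ["GATA"]) == StructuralClass.IMPERFECT
        assert self._mk("[GATA]4 GAT [GATA]3", ["GATA"]) == StructuralClass.IMPERFECT
        assert self._mk("[GATA]4 [GACA]3", ["GATA", "GACA"]) == StructuralClass.COMPOUND
        assert (
            self._mk("[GATA]4 CCTTC [GACA]3", ["GATA", "GACA"])
            == StructuralClass.COMPOUND_INTERRUPTED
        )
        assert (
            self._mk("[GATA]4 AATA [GACA]3", ["GATA", "GACA"])
            == StructuralClass.IMPERFECT_COMPOUND
        )

    def test_mixed_length_motifs_unclassified(self):
        assert self._mk("[AGAT]2 [AG]9", ["AGAT", "AG"]) == StructuralClass.UNCLASSIFIED

    def test_no_blocks_unclassified(self):
        assert classify_structure([], []) == StructuralClass.UNCLASSIFIED

    @settings(derandomize=True, max_examples=200)
    @given(region=dna, order=st.permutations(["GATA", "GACA", "GAAA"]))
    def test_class_invariant_to_motif_order(self, region, order):
        base = structure_from_region(region, ["GATA", "GACA", "GAAA"]).structural_class
        assert structure_from_region(region, list(order)).structural_class == base


class TestCeDesignation:
    @pytest.mark.parametrize("nbases,motif_len,label", [(28, 4, "7"), (39, 4, "9.3"), (10, 5, "2")])
    def test_labels(self, nbases, motif_len, label):
        assert ce_label_from_length(nbases, motif_len) == label

    def test_same_length_isoalleles_share_ce_label(self):
        a = structure_from_region("AATG" * 7, ["AATG"])
        b = structure_from_region("AATG" * 3 + "ACTG" + "AATG" * 3, ["AATG"])
        da, db = ce_designation(a, "AATG"), ce_designation(b, "AATG")
        assert da.ce_label == db.ce_label == "7"
        assert da.array_seq != db.array_seq

    @settings(derandomize=True, max_examples=100)
    @given(count=st.integers(3, 12), pos=st.integers(0, 30))
    def test_ce_invariant_to_internal_substitution(self, count, pos):
        region = "AGAT" * count
        pos = pos % len(region)
        swapped = {"A": "C", "C": "A", "G": "T", "T": "G"}[region[pos]]
        mutated = region[:pos] + swapped + region[pos + 1 :]
        a = structure_from_region(region, ["AGAT"])
        b = structure_from_region(mutated, ["AGAT"])
        assert ce_designation(a, "AGAT").ce_label == ce_designation(b, "AGAT").ce_label


class TestBracketed:
    def test_format_single_block(self):
        s = structure_from_region("AATG" * 3, ["AATG"])
        assert format_bracketed(s) == "[AATG]3"

    def test_parse_compact(self):
        s = parse_bracketed("[GGAA]3[GGCA]2", ["GGAA", "GGCA"])
        assert s.region == "GGAAGGAAGGAAGGCAGGCA"

    def test_parse_with_interruption(self):
        s = parse_bracketed("[AGAT]3 GAT [AGAT]2", ["AGAT"])
        assert len(s.region) == 23
        assert s.interruptions[0].start == 12

    def test_malformed_rejected_with_offset(self):
        with pytest.raises(ValueError, match="offset 7"):
            parse_bracketed("[AGAT]3[XGAT]2", ["AGAT"])

    def test_roundtrip(self):
        text = "[GATA]4 AATA [GACA]3"
        s = parse_bracketed(text, ["GATA", "GACA"])
        assert format_bracketed(s) == text
        assert parse_bracketed(format_bracketed(s), ["GATA", "GACA"]).region == s.region


class TestExtractedStructure:
    def test_margins_become_flanks(self):
        extracted = "CCGTAC" + "AATG" * 7 + "TTGACG"
        s = structure_from_extracted(extracted, ["AATG"])
        assert s.flank5 == "CCGTAC" and s.flank3 == "TTGACG"
        assert s.region == "AATG" * 7
        assert s.full_sequence == extracted
        assert s.structural_class == StructuralClass.PERFECT

    def test_no_blocks_keeps_whole_string(self):
        s = structure_from_extracted("CCGTACGTT", ["AATG"])
        assert s.region == "CCGTACGTT" and s.blocks == ()


def test_json_record():
    s = structure_from_region("AATG" * 7, ["AATG"])
    rec = structure_to_record(s, "AATG")
    assert json.loads(json.dumps(rec)) == rec
    assert rec["class"] == "perfect" and rec["ce_label"] == "7"


def test_reconstruction_enforced():
    with pytest.raises(ValueError, match="reconstruct"):
        AlleleStructure(
            region="AATGAATG",
            blocks=(RepeatBlock(Motif("AATG"), 1, 0),),
            interruptions=(),
        )
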