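import pytest
from hypothesis import given, strategies as st

from varsieve.consequence import (
    CODON_TABLE,
    CdsVariant,
    DELETION,
    DELINS,
    DUPLICATION,
    INSERTION,
    SUBSTITUTION,
    apply_variants,
    build_cds,
    diff_proteins,
    parse_hgvs_c,
    predict_effect,
    translate,
)
from varsieve.errors import DataError, ReferenceMismatchError, UnsupportedNotationError


class TestParseHgvsC:
    @pytest.mark.parametrize(
        "notation, expected",
        [
            ("c.1183_1184delGC", (DELETION, 1183, 1184, "GC", "")),
            ("c.1183_1184 delGC", (DELETION, 1183, 1184, "GC", "")),
            ("c.1187_1188dupTT", (DUPLICATION, 1187, 1188, "TT", "TT")),
            ("c.76A>T", (SUBSTITUTION, 76, 76, "A", "T")),
            ("c.5del", (DELETION, 5, 5, "", "")),
            ("c.5delA", (DELETION, 5, 5, "A", "")),
            ("c.8dup", (DUPLICATION, 8, 8, "", "")),
            ("c.4_5insAGG", (INSERTION, 4, 5, "", "AGG")),
            ("c.10_12delinsAA", (DELINS, 10, 12, "", "AA")),
            ("c.10_12delTTTinsAA", (DELINS, 10, 12, "TTT", "AA")),
        ],
    )
    def test_grammar(self, notation, expected):
        v = parse_hgvs_c(notation)
        assert (v.kind, v.start, v.end, v.stated_ref, v.inserted) == expected

    def test_inverted_range_is_error(self):
        with pytest.raises(DataError, match="inverted"):
            parse_hgvs_c("c.10_9delAA")

    @pytest.mark.parametrize("notation", ["c.88+2A>G", "c.-14G>C", "c.*46T>A", "c.[76A>C]"])
    def test_unsupported_grammar(self, notation):
        with pytest.raises(UnsupportedNotationError):
            parse_hgvs_c(notation)

    def test_nonadjacent_insertion_rejected(self):
        with pytest.raises(UnsupportedNotationError, match="flanking"):
            parse_hgvs_c("c.4_7insA")

    def test_stated_length_mismatch(self):
        with pytest.raises(DataError, match="length"):
            parse_hgvs_c("c.4_5delAAA")

    def test_garbage(self):
        with pytest.raises(UnsupportedNotationError):
            parse_hgvs_c("p.A395C")


class TestApplyVariants:
    def test_joint_del_and_dup(self):
        """GC deletion at 1183-1184 plus TT duplication at 1187-1188 turns
        codons GCT GTT into TGT TTT with no net length change."""
        cds = build_cds(396, {395: "GCT", 396: "GTT"})
        assert cds[1182:1188] == "GCTGTT"
        mutated = apply_variants(
            cds, [parse_hgvs_c("c.1183_1184delGC"), parse_hgvs_c("c.1187_1188dupTT")]
        )
        assert mutated[1182:1188] == "TGTTTT"
        assert len(mutated) == len(cds)
        assert mutated[:1182] == cds[:1182]

    def test_empty_variant_list_identity(self):
        cds = build_cds(10)
        assert apply_variants(cds, []) == cds

    def test_del_then_equal_insertion_restores_length(self):
        cds = "ATGAAACCC"
        out = apply_variants(
            cds,
            [CdsVariant(DELETION, 4, 5, "AA"), CdsVariant(INSERTION, 6, 7, inserted="TT")],
        )
        assert len(out) == len(cds)
        assert out == "ATGATTCCC"

    def test_substitution(self):
        assert apply_variants("ATGAAA", [parse_hgvs_c("c.4A>G")]) == "ATGGAA"

    def test_duplication_copies_span(self):
        assert apply_variants("ATGACT", [parse_hgvs_c("c.4_5dupAC")]) == "ATGACACT"

    def test_insertion_between_flanks(self):
        assert apply_variants("ATGACT", [parse_hgvs_c("c.3_4insGGG")]) == "ATGGGGACT"

    def test_reference_mismatch_names_position(self):
        with pytest.raises(ReferenceMismatchError) as err:
            apply_variants("ATGAAA", [parse_hgvs_c("c.4_5delCC")])
        assert err.value.position == 4
        assert err.value.expected == "CC" and err.value.found == "AA"

    def test_no_ref_check_escape_hatch(self):
        out = apply_variants("ATGAAA", [parse_hgvs_c("c.4_5delCC")], check_ref=False)
        assert out == "ATGA"

    def test_overlapping_variants_rejected(self):
        with pytest.raises(DataError, match="overlap"):
            apply_variants(
                "ATGAAACCC",
                [CdsVariant(DELETION, 4, 6), CdsVariant(SUBSTITUTION, 5, 5, "A", "G")],
                check_ref=False,
            )

    def test_beyond_cds_rejected(self):
        with pytest.raises(DataError, match="beyond"):
            apply_variants("ATGAAA", [CdsVariant(DELETION, 7, 8)])

    @given(st.data())
    def test_joint_equals_sequential_right_to_left(self, data):
        """Joint application is the same as applying variants one at a time
        from the rightmost position leftwards."""
        n_codons = data.draw(st.integers(min_value=6, max_value=20))
        cds = build_cds(n_codons, filler="ACC")
        n_var = data.draw(st.integers(min_value=1, max_value=3))
        starts = data.draw(
            st.lists(
                st.integers(min_value=2, max_value=len(cds) - 4),
                min_size=n_var, max_size=n_var, unique=True,
            )
        )
        starts.sort()
        variants = []
        prev_end = 0
        for s in starts:
            if s <= prev_end:
                continue
            kind = data.draw(st.sampled_from([SUBSTITUTION, DELETION, DUPLICATION, INSERTION]))
            if kind == SUBSTITUTION:
                ref = cds[s - 1]
                alt = data.draw(st.sampled_from([b for b in "ACGT" if b != ref]))
                v = CdsVariant(SUBSTITUTION, s, s, ref, alt)
            elif kind == DELETION:
                e = min(s + data.draw(st.integers(0, 2)), len(cds))
                v = CdsVariant(DELETION, s, e, cds[s - 1 : e])
            elif kind == DUPLICATION:
                e = min(s + data.draw(st.integers(0, 2)), len(cds))
                v = CdsVariant(DUPLICATION, s, e, cds[s - 1 : e], cds[s - 1 : e])
            else:
                ins = data.draw(st.text(alphabet="ACGT", min_size=1, max_size=4))
                v = CdsVariant(INSERTION, s, s + 1, inserted=ins)
            variants.append(v)
            prev_end = v.end
        joint = apply_variants(cds, variants)
        sequential = cds
        for v in sorted(variants, key=lambda v: v.start, reverse=True):
            sequential = apply_variants(sequential, [v], check_ref=False)
        assert joint == sequential
        # net length bookkeeping
        assert len(joint) - len(cds) == sum(v.net_length_change for v in variants)


class TestTranslate:
    def test_all_64_codons_match_reference_table(self):
        """Translation agrees with an independently maintained standard
        genetic code (NCBI table 1 via biopython) on every codon."""
        from Bio.Seq import Seq

        for b1 in "ACGT":
            for b2 in "ACGT":
                for b3 in "ACGT":
                    codon = b1 + b2 + b3
                    expected = str(Seq(codon).translate())
                    ours = CODON_TABLE[codon]
                    assert ours == expected
                    assert translate("ATG" + codon + "GGG") == (
                        "M" if expected == "*" else "M" + expected + "G"
                    )

    @pytest.mark.parametrize(
        "cds, protein",
        [("GCTGTT", "AV"), ("TGTTTT", "CF"), ("ATGTAA", "M"), ("ATGGCACGA", "MAR")],
    )
    def test_examples(self, cds, protein):
        assert translate(cds) == protein

    def test_trailing_partial_codon_ignored(self, caplog):
        assert translate("ATGGCAC") == "MA"
        assert any("partial codon" in r.message for r in caplog.records)

    def test_non_acgt_is_error(self):
        with pytest.raises(DataError, match="non-ACGT"):
            translate("ATGNNN")

    def test_too_short(self):
        with pytest.raises(DataError, match="too short"):
            translate("AT")


class TestDiffProteins:
    def test_two_consecutive_substitutions(self):
        wt = "M" + "K" * 393 + "AV" + "K" * 4
        mut = "M" + "K" * 393 + "CF" + "K" * 4
        d = diff_proteins(wt, mut, cds_length_change=0)
        assert d.substitutions == ((395, "A", "C"), (396, "V", "F"))
        assert d.frameshift_at is None and d.length_change == 0

    def test_identical(self):
        d = diff_proteins("MKT", "MKT")
        assert d.substitutions == () and d.frameshift_at is None

    def test_single_substitution(self):
        assert diff_proteins("MKT", "MRT").substitutions == ((2, "K", "R"),)

    def test_frameshift_flag_from_length_change(self):
        d = diff_proteins("MKTAAA", "MKRGGG", cds_length_change=-1)
        assert d.frameshift_at == 3

    def test_stop_gained_detection(self):
        d = diff_proteins("MKTAAA", "MKT", cds_length_change=0)
        assert d.stop_gained_at == 4


class TestPredictEffect:
    def test_worked_example(self):
        """The confirmed deletion+duplication pair produces exactly the two
        reported residue changes, Ala395Cys and Val396Phe, frame preserved."""
        cds = build_cds(396, {395: "GCT", 396: "GTT"})
        diff = predict_effect(
            cds, [parse_hgvs_c("c.1183_1184delGC"), parse_hgvs_c("c.1187_1188dupTT")]
        )
        assert diff.substitutions == ((395, "A", "C"), (396, "V", "F"))
        assert diff.frameshift_at is None
        assert diff.length_change == 0
        assert diff.summary == "p.A395C; p.V396F"
        # residue indices are the codons containing CDS positions 1183 and 1186
        assert (1183 + 2) // 3 == 395 and (1186 + 2) // 3 == 396

    @pytest.mark.parametrize(
        "notation, net, frame_preserved",
        [
            ("c.4_5delAA", -2, False),
            ("c.4_6delAAA", -3, True),
            ("c.4_5insTTT", 3, True),
            ("c.5dupA", 1, False),
            ("c.5A>G", 0, True),
        ],
    )
    def test_single_variant_length_and_frame(self, notation, net, frame_preserved):
        cds = build_cds(8)  # ATG AAA AAA ...
        v = parse_hgvs_c(notation)
        mutated = apply_variants(cds, [v])
        assert len(mutated) - len(cds) == v.net_length_change == net
        diff = predict_effect(cds, [v])
        assert (diff.frameshift_at is None) == frame_preserved


def test_build_cds_validation():
    with pytest.raises(DataError, match="stop"):
        build_cds(5, {3: "TAA"})
    with pytest.raises(DataError, match="codon"):
        build_cds(5, {2: "AXT"})
    cds = build_cds(4, {4: "TAA"})  # terminal stop is allowed
    assert translate(cds) == "MKK"
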