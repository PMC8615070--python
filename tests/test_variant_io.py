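import logging

import pytest
from hypothesis import given, strategies as st

from varsieve.errors import DataError
from varsieve.variant_io import (
    AnnotationDialect,
    CohortDesign,
    UNANNOTATED,
    VariantKey,
    normalize_key,
    read_design,
    read_sample,
    read_variant_table,
    variant_class,
    write_variant_table,
)

from conftest import make_variant


class TestNormalizeKey:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            (("1", 100, "CAG", "CTG"), ("1", 101, "A", "T")),
            (("1", 100, "A", "G"), ("1", 100, "A", "G")),
            (("1", 100, "ATT", "AT"), ("1", 100, "AT", "A")),  # suffix then anchored
            (("1", 100, "TAAA", "TA"), ("1", 100, "TAA", "T")),
            (("2", 50, "GC", "GA"), ("2", 51, "C", "A")),
        ],
    )
    def test_examples(self, raw, expected):
        assert normalize_key(VariantKey(*raw)) == VariantKey(*expected)

    def test_identical_alleles_rejected(self):
        with pytest.raises(DataError):
            VariantKey("1", 100, "A", "A")

    allele = st.text(alphabet="ACGT", min_size=1, max_size=5)

    @given(allele, allele, st.integers(min_value=1, max_value=1000))
    def test_idempotent_and_allele_preserving(self, ref, alt, pos):
        """Normalization is idempotent and the raw and normalized keys encode
        the same substitution when applied to a reference context."""
        if ref == alt:
            return
        key = VariantKey("1", pos, ref, alt)
        norm = normalize_key(key)
        assert normalize_key(norm) == norm
        # embed the raw ref at pos in a synthetic context and apply both ways
        context = "T" * (pos - 1) + ref + "GGGG"
        raw_applied = context[: pos - 1] + alt + context[pos - 1 + len(ref):]
        assert context[norm.pos - 1 : norm.pos - 1 + len(norm.ref)] == norm.ref
        norm_applied = (
            context[: norm.pos - 1] + norm.alt + context[norm.pos - 1 + len(norm.ref):]
        )
        assert raw_applied == norm_applied

    def test_prefix_trimming_keeps_anchor(self):
        n = normalize_key(VariantKey("1", 10, "CA", "C"))
        assert (n.pos, n.ref, n.alt) == (10, "CA", "C")


@pytest.mark.parametrize(
    "ref, alt, expected",
    [("A", "G", "SNV"), ("A", "AT", "insertion"), ("ATG", "A", "deletion"), ("AT", "GC", "indel")],
)
def test_variant_class(ref, alt, expected):
    assert variant_class(VariantKey("1", 5, ref, alt)) == expected


VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=chr2,length=100000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
"""

VCF_BODY = """chr2\t100\t.\tA\tG\t.\t.\t.\tGT\t0/1
chr2\t200\t.\tC\tT\t.\t.\t.\tGT\t1/1
chr2\t300\t.\tG\tGA\t.\t.\t.\tGT\t0/1
chr2\t400\t.\tT\tA,TC\t.\t.\t.\tGT\t1/2
chr2\t500\t.\tCAG\tCTG\t.\t.\t.\tGT\t0/1
"""

ANNO = "\t".join(["chrom", "pos", "ref", "alt", "gene", "consequence",
                  "dbsnp_af", "esp_af", "predictions"]) + "\n" + "\n".join([
    "chr2\t100\tA\tG\tANKRD36\tmissense_variant\t0.0001\t\tD&B",
    "chr2\t200\tC\tT\tGENEB\tsynonymous_variant\t0.2\t0.1\t",
    "chr2\t300\tG\tGA\tGENEC\tframeshift_variant\t\t\tD",
    "chr2\t400\tT\tA\tGENED\tmissense_variant\t\t\tD&D",
    "chr2\t400\tT\tTC\tGENED\tframeshift_variant\t\t\tD",
    "chr2\t501\tA\tT\tGENEE\tmissense_variant\t0.001\t\t",
]) + "\n"


@pytest.fixture
def sample_files(tmp_path):
    vcf = tmp_path / "S1.vcf"
    vcf.write_text(VCF_HEADER + VCF_BODY)
    anno = tmp_path / "S1.tsv"
    anno.write_text(ANNO)
    return vcf, anno


class TestReadSample:
    def test_field_mapping(self, sample_files):
        variants = read_sample(*sample_files, "S1")
        first = [v for v in variants if v.key.pos == 100][0]
        assert first.gene == "ANKRD36"
        assert first.consequences == frozenset({"missense_variant"})
        assert first.pop_freqs == {"dbSNP": 0.0001}
        assert first.predictions == ("D", "B")
        assert first.zygosity == "heterozygous"

    def test_no_silent_drops_and_multiallelic_split(self, sample_files):
        variants = read_sample(*sample_files, "S1")
        # 5 records, one with two alts -> 6 alleles
        assert len(variants) == 6
        assert sum(1 for v in variants if v.key.pos == 400) == 2

    def test_normalized_join(self, sample_files):
        # VCF CAG>CTG at 500 joins the annotation row written as 501 A>T
        v = [x for x in read_sample(*sample_files, "S1") if x.key.pos == 501][0]
        assert (v.key.ref, v.key.alt, v.gene) == ("A", "T", "GENEE")

    def test_homozygous_genotype(self, sample_files):
        v = [x for x in read_sample(*sample_files, "S1") if x.key.pos == 200][0]
        assert v.zygosity == "homozygous"

    def test_unannotated_flagged_with_warning(self, tmp_path, caplog):
        vcf = tmp_path / "S1.vcf"
        vcf.write_text(VCF_HEADER + VCF_BODY + "chr2\t600\t.\tA\tC\t.\t.\t.\tGT\t0/1\n")
        anno = tmp_path / "S1.tsv"
        anno.write_text(ANNO)
        with caplog.at_level(logging.WARNING):
            variants = read_sample(vcf, anno, "S1")
        assert len(variants) == 7
        flagged = [v for v in variants if UNANNOTATED in v.consequences]
        assert len(flagged) == 1 and flagged[0].key.pos == 600
        assert any("no annotation" in r.message for r in caplog.records)

    def test_orphan_annotation_logged_and_skipped(self, tmp_path, caplog):
        vcf = tmp_path / "S1.vcf"
        vcf.write_text(VCF_HEADER + VCF_BODY)
        anno = tmp_path / "S1.tsv"
        anno.write_text(ANNO + "chr2\t900\tA\tG\tGENEX\tmissense_variant\t\t\t\n")
        with caplog.at_level(logging.WARNING):
            variants = read_sample(vcf, anno, "S1")
        assert len(variants) == 6
        assert any("match no VCF record" in r.message for r in caplog.records)

    def test_empty_vcf(self, tmp_path):
        vcf = tmp_path / "S1.vcf"
        vcf.write_text(VCF_HEADER)
        anno = tmp_path / "S1.tsv"
        anno.write_text(ANNO)
        assert read_sample(vcf, anno, "S1") == []

    def test_missing_file_fatal(self, tmp_path):
        anno = tmp_path / "S1.tsv"
        anno.write_text(ANNO)
        with pytest.raises(DataError, match="not found"):
            read_sample(tmp_path / "nope.vcf", anno, "S1")

    @pytest.mark.parametrize("bad", ["1.5", "abc", "-0.1"])
    def test_malformed_frequency_fatal_with_row(self, tmp_path, sample_files, bad):
        vcf, _ = sample_files
        anno = tmp_path / "bad.tsv"
        lines = ANNO.splitlines()
        lines[1] = lines[1].replace("0.0001", bad)
        anno.write_text("\n".join(lines) + "\n")
        with pytest.raises(DataError, match="row 2"):
            read_sample(vcf, anno, "S1")

    def test_chr_prefix_harmonization(self, tmp_path):
        vcf = tmp_path / "S1.vcf"
        vcf.write_text(VCF_HEADER + "chr2\t100\t.\tA\tG\t.\t.\t.\tGT\t0/1\n")
        anno = tmp_path / "S1.tsv"
        anno.write_text(ANNO.replace("chr2", "2"))
        verbatim = read_sample(vcf, anno, "S1")
        assert UNANNOTATED in verbatim[0].consequences  # names differ verbatim
        harmonized = read_sample(vcf, anno, "S1", harmonize_chr=True)
        assert harmonized[0].gene == "ANKRD36"


def test_variant_table_round_trip(tmp_path, toy_sample):
    path = tmp_path / "variants.tsv"
    write_variant_table(toy_sample, path)
    back = read_variant_table(path)
    assert back == toy_sample


class TestCohortDesign:
    def test_roles(self):
        d = CohortDesign({"a": "AP", "b": "BC", "c": "CP", "h": "HEALTHY"})
        assert set(d.cases) == {"a", "b"}
        assert set(d.controls) == {"c", "h"}

    def test_unknown_group(self):
        with pytest.raises(DataError, match="unknown group"):
            CohortDesign({"a": "XX"})

    def test_read_design(self, tmp_path):
        p = tmp_path / "design.tsv"
        p.write_text("sample_id\tgroup\nS1\tAP\nS2\tcp\n")
        d = read_design(p)
        assert d.assignments == {"S1": "AP", "S2": "CP"}

    def test_duplicate_samples_rejected(self, tmp_path):
        p = tmp_path / "design.tsv"
        p.write_text("sample_id\tgroup\nS1\tAP\nS1\tCP\n")
        with pytest.raises(DataError, match="duplicate"):
            read_design(p)

    def test_requires_cases_and_controls(self):
        with pytest.raises(DataError, match="control"):
            CohortDesign({"a": "AP"}).require_cases_and_controls()
        with pytest.raises(DataError, match="case"):
            CohortDesign({"c": "CP"}).require_cases_and_controls()


def test_dialect_column_remapping(tmp_path):
    vcf = tmp_path / "S1.vcf"
    vcf.write_text(VCF_HEADER + "chr2\t100\t.\tA\tG\t.\t.\t.\tGT\t0/1\n")
    anno = tmp_path / "S1.tsv"
    anno.write_text(
        "Chr\tPosition\tRef\tAlt\tSymbol\tEffect\tAF\tSIFT\n"
        "chr2\t100\tA\tG\tANKRD36\tmissense_variant\t0.001\tD\n"
    )
    dialect = AnnotationDialect(
        chrom="Chr", pos="Position", ref="Ref", alt="Alt", gene="Symbol",
        consequence="Effect", predictions="SIFT", freq_columns={"dbSNP": "AF"},
    )
    v = read_sample(vcf, anno, "S1", dialect)[0]
    assert v.gene == "ANKRD36" and v.pop_freqs == {"dbSNP": 0.001}
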