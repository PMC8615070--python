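import pytest
from hypothesis import settings

from varsieve.variant_io import AnnotatedVariant, VariantKey, HETEROZYGOUS

settings.register_profile("ci", derandomize=True, max_examples=200)
settings.load_profile("ci")


def make_variant(
    pos,
    sample_id="S1",
    chrom="1",
    ref="A",
    alt="G",
    zygosity=HETEROZYGOUS,
    gene="GENE1",
    consequences=("missense_variant",),
    pop_freqs=None,
    predictions=(),
):
    return AnnotatedVariant(
        sample_id=sample_id,
        key=VariantKey(chrom, pos, ref, alt),
        zygosity=zygosity,
        gene=gene,
        consequences=frozenset(consequences),
        pop_freqs=pop_freqs or {},
        predictions=tuple(predictions),
    )


@pytest.fixture
def toy_sample():
    """20 hand-built variants from one sample: 8 fall at the consequence
    stage, 4 at the frequency stage, 3 at the consensus stage, 5 survive."""
    v = make_variant
    dropped_consequence = [
        v(100, consequences=("synonymous_variant",)),
        v(110, consequences=("synonymous_variant",), pop_freqs={"dbSNP": 0.0001}),
        v(120, consequences=("synonymous_variant",), predictions=("D", "D")),
        v(130, consequences=("synonymous_variant",)),
        v(140, consequences=("intron_variant",)),
        v(150, consequences=("intron_variant",), gene="GENE2"),
        v(160, consequences=("intergenic_variant",), gene=""),
        v(170, consequences=("3_prime_UTR_variant",)),
    ]
    dropped_frequency = [
        v(200, pop_freqs={"dbSNP": 0.2, "ESP": 0.15}),
        v(210, pop_freqs={"dbSNP": 0.01}),
        v(220, pop_freqs={"ESP": 0.0051}, predictions=("D", "D", "D")),
        v(230, consequences=("stop_gained",), pop_freqs={"dbSNP": 0.3}),
    ]
    dropped_consensus = [
        v(300, predictions=("B", "B", "B")),
        v(310, predictions=("T", "T", "T", "U"), pop_freqs={"dbSNP": 0.001}),
        v(320, predictions=("B", "B", "B", "B", "D")),  # 4/5 = 80% benign
    ]
    survivors = [
        v(400, predictions=("D", "D")),
        v(410, consequences=("stop_gained",), pop_freqs={"dbSNP": 0.001}, predictions=("D", "U")),
        v(420, consequences=("frameshift_variant",), ref="AT", alt="A"),
        v(430, consequences=("intron_variant", "splice_acceptor_variant"), predictions=("D",)),
        v(440, consequences=("inframe_deletion",), ref="AGCT", alt="A",
          pop_freqs={"dbSNP": 0.004}, predictions=("B", "D")),  # 1/2 benign < 70%
    ]
    return dropped_consequence + dropped_frequency + dropped_consensus + survivors


@pytest.fixture
def toy_survivor_positions():
    return {400, 410, 420, 430, 440}
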