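"""The rare-variant filter cascade.

Three ordered, pure per-variant predicates mirror the prioritization used
to nominate progression biomarkers from annotated exomes:

1. **consequence/impact** — drop synonymous, intronic and intergenic calls;
   keep variants with HIGH or MODERATE (protein-altering) impact and any
   splice-site variant;
2. **population frequency** — drop variants seen at > ``max_pop_freq``
   (default 0.005) in *any* population database; variants absent from all
   databases are kept (novel variants are the interesting ones);
3. **predictor consensus** — drop variants a ≥ 70% majority of predictors
   with a known verdict call benign (B) or tolerated (T).

Each stage records in/out counts in a :class:`FilterFunnel`, the audit
trail of the cascade.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

from .errors import ConfigError, DataError
from .variant_io import AnnotatedVariant, CONSEQUENCE_VOCAB

log = logging.getLogger(__name__)

RETAIN = "RETAIN"
EXCLUDE = "EXCLUDE"

#: Impact class per consequence term (VEP/SnpEff-style taxonomy).
IMPACT_BY_TERM = {
    "stop_gained": "HIGH",
    "stop_lost": "HIGH",
    "start_lost": "HIGH",
    "frameshift_variant": "HIGH",
    "splice_acceptor_variant": "HIGH",
    "splice_donor_variant": "HIGH",
    "missense_variant": "MODERATE",
    "inframe_insertion": "MODERATE",
    "inframe_deletion": "MODERATE",
    "protein_altering_variant": "MODERATE",
    "synonymous_variant": "LOW",
    "splice_region_variant": "LOW",
    "stop_retained_variant": "LOW",
    "intron_variant": "MODIFIER",
    "intergenic_variant": "MODIFIER",
    "5_prime_UTR_variant": "MODIFIER",
    "3_prime_UTR_variant": "MODIFIER",
    "upstream_gene_variant": "MODIFIER",
    "downstream_gene_variant": "MODIFIER",
    "unannotated": "MODIFIER",
}

SPLICE_TERMS = frozenset(
    {"splice_acceptor_variant", "splice_donor_variant", "splice_region_variant"}
)

STAGE_NAMES = ("consequence", "frequency", "consensus")


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the cascade.

    ``max_pop_freq`` — strict upper bound on population allele frequency
    (a variant at exactly the threshold is retained); ``consensus_threshold``
    — fraction of known predictor calls that must agree on B (or on T) for
    the variant to be eliminated, inclusive at the boundary.
    """

    max_pop_freq: float = 0.005
    consensus_threshold: Fraction = Fraction(70, 100)
    retained_impacts: frozenset = frozenset({"HIGH", "MODERATE"})
    excluded_consequences: frozenset = frozenset(
        {"synonymous_variant", "intron_variant", "intergenic_variant"}
    )
    strict_terms: bool = False  # unknown consequence term: error (True) or exclude+warn

    def __post_init__(self):
        if not (0.0 < self.max_pop_freq < 1.0):
            raise ConfigError(f"max_pop_freq must be in (0, 1), got {self.max_pop_freq}")
        t = Fraction(self.consensus_threshold).limit_denominator(10**6)
        if not (Fraction(1, 2) < t <= 1):
            raise ConfigError(
                f"consensus_threshold must be in (0.5, 1], got {self.consensus_threshold}"
            )
        object.__setattr__(self, "consensus_threshold", t)


def classify_consequence(
    consequences: Iterable[str],
    retained_impacts: frozenset = FilterParams.retained_impacts,
    strict: bool = False,
) -> str:
    """RETAIN iff any term has a retained impact class or is a splice term.

    A variant annotated with several terms is kept if *any one* of them
    qualifies (e.g. ``{intron_variant, splice_acceptor_variant}`` is
    retained: the splice annotation dominates).
    """
    decision = EXCLUDE
    for term in consequences:
        impact = IMPACT_BY_TERM.get(term)
        if impact is None:
            if strict:
                raise DataError(f"unknown consequence term {term!r}")
            log.warning("unknown consequence term %r treated as MODIFIER", term)
            continue
        if impact in retained_impacts or term in SPLICE_TERMS:
            decision = RETAIN
    return decision


def filter_population_frequency(v: AnnotatedVariant, params: FilterParams) -> str:
    """EXCLUDE iff the maximum frequency across available sources exceeds the cutoff.

    Absence from every database is a defined state and means RETAIN — such
    novel variants are precisely the prioritized ones.
    """
    if not v.pop_freqs:
        return RETAIN
    return EXCLUDE if max(v.pop_freqs.values()) > params.max_pop_freq else RETAIN


def consensus_prediction(
    predictions: Sequence[str],
    threshold: Fraction = FilterParams.consensus_threshold,
) -> str:
    """Aggregate predictor calls into B, T, or RETAIN.

    Frequencies are computed over *known* calls only (U drops out of both
    numerator and denominator) with exact rational arithmetic, so the
    boundary is exact: 7 B out of 10 known is a B consensus, 2 of 3 is not.
    B and T verdicts mean the variant is eliminated as likely neutral; an
    empty or all-unknown list retains the variant.
    """
    threshold = Fraction(threshold).limit_denominator(10**6)
    known = [p for p in predictions if p in ("B", "T", "D")]
    if not known:
        return RETAIN
    n = len(known)
    if Fraction(known.count("B"), n) >= threshold:
        return "B"
    if Fraction(known.count("T"), n) >= threshold:
        return "T"
    return RETAIN


@dataclass(frozen=True)
class FunnelStage:
    name: str
    variants_in: int
    variants_out: int

    def __post_init__(self):
        if self.variants_out > self.variants_in:
            raise DataError(
                f"funnel stage {self.name}: out ({self.variants_out}) > in ({self.variants_in})"
            )


@dataclass
class FilterFunnel:
    """Per-sample audit of the cascade: ordered (stage, in, out) counts."""

    sample_id: str
    stages: list = field(default_factory=list)

    def add(self, name: str, variants_in: int, variants_out: int) -> None:
        self.stages.append(FunnelStage(name, variants_in, variants_out))

    @property
    def n_input(self) -> int:
        return self.stages[0].variants_in if self.stages else 0

    @property
    def n_survivors(self) -> int:
        return self.stages[-1].variants_out if self.stages else 0

    def rows(self):
        for s in self.stages:
            yield {
                "sample_id": self.sample_id,
                "stage": s.name,
                "variants_in": s.variants_in,
                "variants_out": s.variants_out,
            }


def run_cascade(
    variants: Sequence[AnnotatedVariant],
    params: FilterParams | None = None,
) -> tuple[list, FilterFunnel]:
    """Apply the three filter stages in order to one sample's variants.

    Returns ``(survivors, funnel)``.  Survivors are a subsequence of the
    input (order preserved); each stage is a pure per-variant predicate, so
    the cascade is idempotent and every stage is monotone non-increasing.
    """
    params = params or FilterParams()
    sample_ids = {v.sample_id for v in variants}
    if len(sample_ids) > 1:
        raise DataError(f"run_cascade expects variants from one sample, got {sorted(sample_ids)}")
    funnel = FilterFunnel(sample_id=sample_ids.pop() if sample_ids else "")

    current = list(variants)
    n_in = len(current)
    current = [
        v
        for v in current
        if classify_consequence(v.consequences, params.retained_impacts, params.strict_terms)
        == RETAIN
    ]
    funnel.add("consequence", n_in, len(current))

    n_in = len(current)
    current = [v for v in current if filter_population_frequency(v, params) == RETAIN]
    funnel.add("frequency", n_in, len(current))

    n_in = len(current)
    current = [
        v
        for v in current
        if consensus_prediction(v.predictions, params.consensus_threshold) == RETAIN
    ]
    funnel.add("consensus", n_in, len(current))

    log.info(
        "cascade %s: %d -> %d survivors", funnel.sample_id, funnel.n_input, funnel.n_survivors
    )
    return current, funnel


def write_funnels(funnels: Iterable[FilterFunnel], path) -> None:
    import pandas as pd

    rows = [row for f in funnels for row in f.rows()]
    pd.DataFrame(
        rows, columns=["sample_id", "stage", "variants_in", "variants_out"]
    ).to_csv(path, sep="\t", index=False)
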