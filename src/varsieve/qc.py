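"""Per-sample variant QC statistics and cohort descriptive fractions.

Mirrors the usual exome QC table: variant-class counts (SNVs, indels,
synonymous, missense, stop gained/lost, frameshift, inframe indels),
heterozygous/homozygous ratio and transition/transversion (Ts/Tv) ratio.
Undefined ratios (zero denominator) are reported as ``None`` and written
as ``NA`` — distinguishable from a true zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Sequence

import pandas as pd

from .errors import DataError
from .variant_io import AnnotatedVariant, HETEROZYGOUS, HOMOZYGOUS, VariantKey

log = logging.getLogger(__name__)

TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})


@dataclass(frozen=True)
class VariantClassCounts:
    """One sample's variant-class tallies plus het/hom and Ts/Tv ratios."""

    n_snp: int = 0
    n_indel: int = 0
    n_synonymous: int = 0
    n_missense: int = 0
    n_stop_gained: int = 0
    n_stop_lost: int = 0
    n_frameshift: int = 0
    n_inframe_ins: int = 0
    n_inframe_del: int = 0
    het_hom_ratio: float | None = None
    ts_tv_ratio: float | None = None


_CONSEQUENCE_BUCKETS = {
    "synonymous_variant": "n_synonymous",
    "missense_variant": "n_missense",
    "stop_gained": "n_stop_gained",
    "stop_lost": "n_stop_lost",
    "frameshift_variant": "n_frameshift",
    "inframe_insertion": "n_inframe_ins",
    "inframe_deletion": "n_inframe_del",
}


def is_transition(ref: str, alt: str) -> bool:
    return (ref, alt) in TRANSITIONS


def ts_tv_ratio(snvs: Iterable[VariantKey | AnnotatedVariant]) -> float | None:
    """Transitions (A<->G, C<->T) over transversions; ``None`` when no transversions.

    Input must be SNVs (single-base ref and alt); anything else is an error.
    """
    n_ts = n_tv = 0
    for item in snvs:
        key = item.key if isinstance(item, AnnotatedVariant) else item
        if len(key.ref) != 1 or len(key.alt) != 1:
            raise DataError(f"ts_tv_ratio expects SNVs only, got {key}")
        if is_transition(key.ref, key.alt):
            n_ts += 1
        else:
            n_tv += 1
    if n_tv == 0:
        log.warning("Ts/Tv undefined: no transversions among %d SNVs", n_ts)
        return None
    return n_ts / n_tv


def het_hom_ratio(variants: Iterable[AnnotatedVariant]) -> float | None:
    """Heterozygous over homozygous count; ``None`` when there are no homozygotes."""
    n_het = n_hom = 0
    for v in variants:
        if v.zygosity == HETEROZYGOUS:
            n_het += 1
        elif v.zygosity == HOMOZYGOUS:
            n_hom += 1
    if n_hom == 0:
        log.warning("het/hom undefined: no homozygous variants")
        return None
    return n_het / n_hom


def class_counts(variants: Sequence[AnnotatedVariant]) -> VariantClassCounts:
    """Tally one sample's variants into the QC table categories.

    A variant increments ``n_snp`` or ``n_indel`` by its allele class, and
    one consequence bucket per matching term (a variant annotated both
    missense and splice-region counts once under missense).
    """
    counts = {f: 0 for f in _CONSEQUENCE_BUCKETS.values()}
    n_snp = n_indel = 0
    snv_keys = []
    for v in variants:
        if v.variant_class == "SNV":
            n_snp += 1
            snv_keys.append(v.key)
        else:
            n_indel += 1
        for term, bucket in _CONSEQUENCE_BUCKETS.items():
            if term in v.consequences:
                counts[bucket] += 1
    return VariantClassCounts(
        n_snp=n_snp,
        n_indel=n_indel,
        het_hom_ratio=het_hom_ratio(variants) if variants else None,
        ts_tv_ratio=ts_tv_ratio(snv_keys) if snv_keys else None,
        **counts,
    )


def cohort_fraction(numerator: int, denominator: int) -> float:
    """Percentage 100*n/d, half-up rounded to one decimal (report-table style)."""
    if denominator <= 0:
        raise DataError(f"cohort_fraction denominator must be positive, got {denominator}")
    pct = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


_QC_COLUMNS = [
    "sample_id", "n_snp", "n_synonymous", "n_missense", "n_stop_gained",
    "n_stop_lost", "n_indel", "n_frameshift", "n_inframe_ins",
    "n_inframe_del", "het_hom_ratio", "ts_tv_ratio",
]


def qc_table(stats_by_sample: dict) -> pd.DataFrame:
    """One row per sample, columns in the conventional QC-table order."""
    rows = []
    for sid, c in stats_by_sample.items():
        row = {"sample_id": sid}
        for col in _QC_COLUMNS[1:]:
            val = getattr(c, col)
            row[col] = "NA" if val is None else val
        rows.append(row)
    return pd.DataFrame(rows, columns=_QC_COLUMNS)


def write_qc_table(stats_by_sample: dict, path) -> None:
    qc_table(stats_by_sample).to_csv(path, sep="\t", index=False)
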