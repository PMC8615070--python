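"""Reading and normalising per-sample variant calls and their annotations.

VCF records (read with :mod:`pysam`) are joined to a tab-separated
annotation table on the *normalized* variant key, producing one
:class:`AnnotatedVariant` per (record, alt allele).  Multi-allelic records
are split before normalization, so every downstream decision (filtering,
exclusivity) is per allele.  The annotation dialect (column names, list
separators, frequency sources) is configurable through
:class:`AnnotationDialect` because annotation exports vary between tools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

from .errors import DataError

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

HETEROZYGOUS = "heterozygous"
HOMOZYGOUS = "homozygous"

#: Sentinel consequence for VCF records with no annotation row.
UNANNOTATED = "unannotated"

#: Controlled consequence vocabulary (Sequence Ontology style terms).
CONSEQUENCE_VOCAB = frozenset(
    {
        "synonymous_variant",
        "missense_variant",
        "stop_gained",
        "stop_lost",
        "start_lost",
        "frameshift_variant",
        "inframe_insertion",
        "inframe_deletion",
        "splice_acceptor_variant",
        "splice_donor_variant",
        "splice_region_variant",
        "intron_variant",
        "intergenic_variant",
        "5_prime_UTR_variant",
        "3_prime_UTR_variant",
        "upstream_gene_variant",
        "downstream_gene_variant",
        "stop_retained_variant",
        "protein_altering_variant",
        UNANNOTATED,
    }
)

PREDICTION_CALLS = ("B", "T", "D", "U")  # benign, tolerated, damaging, unknown

CASE_GROUPS = frozenset({"AP", "BC"})
CONTROL_GROUPS = frozenset({"CP", "HEALTHY"})
GROUPS = CASE_GROUPS | CONTROL_GROUPS


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of one alternate allele: chromosome, 1-based position, ref, alt."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self):
        if self.pos < 1:
            raise DataError(f"variant position must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or not set(allele) <= VALID_BASES:
                raise DataError(
                    f"{name} allele must be a non-empty ACGT string, got {allele!r}"
                )
        if self.ref == self.alt:
            raise DataError(
                f"ref and alt are identical ({self.ref!r} at {self.chrom}:{self.pos}): not a variant"
            )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


def normalize_key(key: VariantKey) -> VariantKey:
    """Trim shared allele context to a minimal representation.

    Common trailing bases are removed first, then common leading bases are
    removed while both alleles retain at least one base (the anchor base of
    indel notation survives).  The position advances by the number of
    leading bases trimmed.  Idempotent; raises :class:`DataError` if the
    alleles collapse to equality (the record was not a variant).
    """
    ref, alt, pos = key.ref, key.alt, key.pos
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if ref == alt:
        raise DataError(f"{key}: alleles identical after trimming; not a variant")
    if ref == key.ref and alt == key.alt:
        return key
    return VariantKey(key.chrom, pos, ref, alt)


def variant_class(key: VariantKey) -> str:
    """Classify an allele pair as SNV / insertion / deletion / indel."""
    if len(key.ref) == 1 and len(key.alt) == 1:
        return "SNV"
    if len(key.ref) < len(key.alt):
        return "insertion"
    if len(key.ref) > len(key.alt):
        return "deletion"
    return "indel"  # equal-length multi-base substitution


@dataclass(frozen=True)
class AnnotatedVariant:
    """One called variant in one sample, with its annotations."""

    sample_id: str
    key: VariantKey
    zygosity: str  # heterozygous | homozygous
    gene: str = ""  # may be empty for intergenic variants
    consequences: frozenset = frozenset({UNANNOTATED})
    pop_freqs: Mapping[str, float] = field(default_factory=dict)
    predictions: tuple = ()

    def __post_init__(self):
        if self.zygosity not in (HETEROZYGOUS, HOMOZYGOUS):
            raise DataError(f"invalid zygosity {self.zygosity!r}")
        if not self.consequences:
            raise DataError("consequences must be non-empty")
        for src, f in self.pop_freqs.items():
            if not (0.0 <= f <= 1.0):
                raise DataError(f"population frequency {src}={f} outside [0, 1]")
        for p in self.predictions:
            if p not in PREDICTION_CALLS:
                raise DataError(f"invalid predictor call {p!r}")

    def __hash__(self):  # pop_freqs is a dict; hash a frozen view of it
        return hash(
            (self.sample_id, self.key, self.zygosity, self.gene,
             self.consequences, tuple(sorted(self.pop_freqs.items())), self.predictions)
        )

    @property
    def variant_class(self) -> str:
        return variant_class(self.key)


@dataclass(frozen=True)
class CohortDesign:
    """Assignment of samples to phase groups (CP, AP, BC, HEALTHY).

    Advanced-phase samples (AP, BC) are the cases; chronic-phase and
    healthy samples are the controls.
    """

    assignments: Mapping[str, str]

    def __post_init__(self):
        for sid, grp in self.assignments.items():
            if grp not in GROUPS:
                raise DataError(f"sample {sid!r}: unknown group {grp!r} (expected one of {sorted(GROUPS)})")

    @property
    def samples(self) -> tuple:
        return tuple(self.assignments)

    @property
    def cases(self) -> tuple:
        return tuple(s for s, g in self.assignments.items() if g in CASE_GROUPS)

    @property
    def controls(self) -> tuple:
        return tuple(s for s, g in self.assignments.items() if g in CONTROL_GROUPS)

    def require_cases_and_controls(self):
        if not self.cases:
            raise DataError("exclusivity analysis requires at least one case sample (AP or BC)")
        if not self.controls:
            raise DataError("exclusivity analysis requires at least one control sample (CP or HEALTHY)")


def read_design(path) -> CohortDesign:
    """Read a two-column (sample_id, group) TSV design file."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"design file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "sample_id" not in cols or "group" not in cols:
        raise DataError(f"design file {path} must have 'sample_id' and 'group' columns")
    sids = df[cols["sample_id"]].tolist()
    if len(sids) != len(set(sids)):
        raise DataError(f"design file {path} has duplicate sample ids")
    return CohortDesign(dict(zip(sids, df[cols["group"]].str.upper())))


def write_design(design: CohortDesign, path) -> None:
    pd.DataFrame(
        {"sample_id": list(design.assignments), "group": list(design.assignments.values())}
    ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class AnnotationDialect:
    """Column-name mapping for the annotation TSV.

    Defaults match the tables written by this package's simulator; override
    the fields to ingest another annotation export.  ``freq_columns`` maps
    frequency *source names* (as they will appear in ``pop_freqs``) to
    column names; empty cells mean "absent from that database".
    """

    chrom: str = "chrom"
    pos: str = "pos"
    ref: str = "ref"
    alt: str = "alt"
    gene: str = "gene"
    consequence: str = "consequence"
    predictions: str = "predictions"
    freq_columns: Mapping[str, str] = field(
        default_factory=lambda: {"dbSNP": "dbsnp_af", "ESP": "esp_af"}
    )
    list_sep: str = "&"


DEFAULT_DIALECT = AnnotationDialect()


def _parse_freq(cell, source: str, row_num: int) -> float | None:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
        return None
    try:
        f = float(cell)
    except (TypeError, ValueError):
        raise DataError(f"annotation row {row_num}: non-numeric {source} frequency {cell!r}")
    if not (0.0 <= f <= 1.0):
        raise DataError(f"annotation row {row_num}: {source} frequency {f} outside [0, 1]")
    return f


def read_annotation_table(path, dialect: AnnotationDialect = DEFAULT_DIALECT) -> dict:
    """Read an annotation TSV into a map normalized VariantKey -> annotation fields.

    Returns ``{key: (gene, consequences, pop_freqs, predictions)}``.
    Malformed frequencies are fatal (with the offending row number);
    duplicate keys merge their consequence and prediction sets.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"annotation table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    needed = [dialect.chrom, dialect.pos, dialect.ref, dialect.alt,
              dialect.gene, dialect.consequence]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise DataError(f"annotation table {path} missing columns: {missing}")

    table: dict[VariantKey, tuple] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header line
        rowd = dict(zip(df.columns, row))
        try:
            key = normalize_key(
                VariantKey(
                    str(rowd[dialect.chrom]),
                    int(rowd[dialect.pos]),
                    rowd[dialect.ref].upper(),
                    rowd[dialect.alt].upper(),
                )
            )
        except (ValueError, DataError) as exc:
            raise DataError(f"annotation row {i}: bad variant key ({exc})")
        cons = frozenset(
            t for t in rowd[dialect.consequence].split(dialect.list_sep) if t
        ) or frozenset({UNANNOTATED})
        freqs = {}
        for source, col in dialect.freq_columns.items():
            if col in df.columns:
                f = _parse_freq(rowd.get(col), source, i)
                if f is not None:
                    freqs[source] = f
        preds = ()
        if dialect.predictions in df.columns and rowd[dialect.predictions]:
            preds = tuple(rowd[dialect.predictions].split(dialect.list_sep))
        if key in table:
            g0, c0, f0, p0 = table[key]
            table[key] = (g0 or rowd[dialect.gene], c0 | cons, {**f0, **freqs}, p0 + preds)
        else:
            table[key] = (rowd[dialect.gene], cons, freqs, preds)
    return table


def _zygosity_from_gt(gt, alt_index: int) -> str:
    """Zygosity of one alt allele from a genotype tuple (alt_index is 1-based)."""
    if gt is None or all(a is None for a in gt):
        return HETEROZYGOUS  # missing genotype; caller logs a warning
    called = [a for a in gt if a is not None]
    if called and all(a == alt_index for a in called) and len(called) > 1:
        return HOMOZYGOUS
    return HETEROZYGOUS


def read_sample(
    vcf_path,
    annotation_path,
    sample_id: str,
    dialect: AnnotationDialect = DEFAULT_DIALECT,
    harmonize_chr: bool = False,
) -> list:
    """Read one sample's VCF and annotation table into AnnotatedVariants.

    Every VCF alt allele yields exactly one AnnotatedVariant (no silent
    drops): alleles with no annotation row are emitted with
    ``consequences == {unannotated}`` and a logged warning.  Annotation rows
    matching no VCF record are logged and skipped.  When ``harmonize_chr``
    is set, a leading ``chr`` prefix is stripped from chromosome names on
    both sides before joining; otherwise names are compared verbatim.
    """
    vcf_path = Path(vcf_path)
    if not vcf_path.exists():
        raise DataError(f"VCF not found: {vcf_path}")
    annotation = read_annotation_table(annotation_path, dialect)

    def canon(chrom: str) -> str:
        return chrom[3:] if harmonize_chr and chrom.lower().startswith("chr") else chrom

    if harmonize_chr:
        annotation = {replace(k, chrom=canon(k.chrom)): v for k, v in annotation.items()}

    variants: list[AnnotatedVariant] = []
    seen_keys: set[VariantKey] = set()
    n_unannotated = 0
    with pysam.VariantFile(str(vcf_path)) as vf:
        vcf_samples = list(vf.header.samples)
        if sample_id in vcf_samples:
            column = sample_id
        elif len(vcf_samples) == 1:
            column = vcf_samples[0]
        elif vcf_samples:
            raise DataError(
                f"sample {sample_id!r} not among VCF samples {vcf_samples} in {vcf_path}"
            )
        else:
            column = None
        for rec in vf:
            alts = rec.alts or ()
            gt = rec.samples[column].get("GT") if column is not None else None
            for ai, alt in enumerate(alts, start=1):
                if alt is None or alt.startswith("<") or set(alt.upper()) - VALID_BASES:
                    log.warning("%s: skipping symbolic/non-ACGT alt %r at %s:%s",
                                sample_id, alt, rec.chrom, rec.pos)
                    continue
                key = normalize_key(
                    VariantKey(canon(rec.chrom), rec.pos, rec.ref.upper(), alt.upper())
                )
                ann = annotation.get(key)
                if ann is None:
                    n_unannotated += 1
                    log.warning("%s: no annotation for %s; flagged unannotated", sample_id, key)
                    gene, cons, freqs, preds = "", frozenset({UNANNOTATED}), {}, ()
                else:
                    gene, cons, freqs, preds = ann
                variants.append(
                    AnnotatedVariant(
                        sample_id=sample_id,
                        key=key,
                        zygosity=_zygosity_from_gt(gt, ai),
                        gene=gene,
                        consequences=cons,
                        pop_freqs=freqs,
                        predictions=preds,
                    )
                )
                seen_keys.add(key)
    orphans = set(annotation) - seen_keys
    if orphans:
        log.warning("%s: %d annotation rows match no VCF record; skipped", sample_id, len(orphans))
    if n_unannotated:
        log.warning("%s: %d VCF alleles had no annotation row", sample_id, n_unannotated)
    return variants


# ---------------------------------------------------------------------------
# Variant-table round-trip (the package's per-sample report format)

_TABLE_COLUMNS = [
    "sample_id", "chrom", "pos", "ref", "alt", "zygosity", "variant_class",
    "gene", "consequences", "pop_freqs", "predictions",
]


def write_variant_table(variants: Iterable[AnnotatedVariant], path, list_sep: str = "&") -> None:
    """Write AnnotatedVariants to a lossless TSV (see :func:`read_variant_table`)."""
    rows = []
    for v in variants:
        rows.append(
            {
                "sample_id": v.sample_id,
                "chrom": v.key.chrom,
                "pos": v.key.pos,
                "ref": v.key.ref,
                "alt": v.key.alt,
                "zygosity": v.zygosity,
                "variant_class": v.variant_class,
                "gene": v.gene,
                "consequences": list_sep.join(sorted(v.consequences)),
                "pop_freqs": list_sep.join(
                    f"{src}:{f!r}" for src, f in sorted(v.pop_freqs.items())
                ),
                "predictions": list_sep.join(v.predictions),
            }
        )
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_variant_table(path, list_sep: str = "&") -> list:
    """Inverse of :func:`write_variant_table` (field-for-field round trip)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        freqs = {}
        if row.pop_freqs:
            for item in row.pop_freqs.split(list_sep):
                src, _, val = item.partition(":")
                freqs[src] = float(val)
        out.append(
            AnnotatedVariant(
                sample_id=row.sample_id,
                key=VariantKey(row.chrom, int(row.pos), row.ref, row.alt),
                zygosity=row.zygosity,
                gene=row.gene,
                consequences=frozenset(row.consequences.split(list_sep)),
                pop_freqs=freqs,
                predictions=tuple(row.predictions.split(list_sep)) if row.predictions else (),
            )
        )
    return out
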