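"""Case-exclusivity intersection.

A candidate progression driver is a gene (or, in variant mode, an exact
normalized variant) carried by *every* advanced-phase case sample and by
*no* chronic-phase or healthy control.  The incidence matrix is a boolean
genes x samples table; :func:`shared_exclusive` applies the intersection
rule, and :func:`exclusivity_oracle` is an independent brute-force
reference used in tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .errors import DataError
from .variant_io import AnnotatedVariant, CohortDesign

log = logging.getLogger(__name__)

GENE_MODE = "gene"
VARIANT_MODE = "variant"


@dataclass(frozen=True)
class Candidate:
    """One exclusivity hit: the gene (or variant) and the samples supporting it."""

    name: str
    case_support: tuple
    variants_by_sample: Mapping[str, tuple] = field(default_factory=dict)


@dataclass(frozen=True)
class CandidateReport:
    mode: str
    candidates: tuple

    @property
    def names(self) -> tuple:
        return tuple(c.name for c in self.candidates)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.candidates:
            for sid in c.case_support:
                for v in c.variants_by_sample.get(sid, ()):
                    rows.append(
                        {
                            "gene": v.gene,
                            "sample_id": sid,
                            "chrom": v.key.chrom,
                            "pos": v.key.pos,
                            "ref": v.key.ref,
                            "alt": v.key.alt,
                            "consequences": "&".join(sorted(v.consequences)),
                            "max_pop_freq": max(v.pop_freqs.values()) if v.pop_freqs else "",
                            "predictions": "&".join(v.predictions),
                            "mode": self.mode,
                        }
                    )
                if not c.variants_by_sample:
                    rows.append({"gene": c.name, "sample_id": sid, "mode": self.mode})
        columns = ["gene", "sample_id", "chrom", "pos", "ref", "alt",
                   "consequences", "max_pop_freq", "predictions", "mode"]
        return pd.DataFrame(rows, columns=columns)


def build_incidence(
    survivors_by_sample: Mapping[str, Sequence[AnnotatedVariant]],
    design: CohortDesign,
    mode: str = GENE_MODE,
) -> pd.DataFrame:
    """Boolean incidence matrix: rows genes (or variant keys), columns samples.

    Cell (g, s) is True iff sample s carries at least one surviving variant
    of gene g (gene mode) or that exact normalized variant (variant mode).
    Every design sample appears as a column even if it has no survivors;
    gene-mode variants with an empty gene symbol are skipped with a logged
    count.
    """
    if mode not in (GENE_MODE, VARIANT_MODE):
        raise DataError(f"unknown exclusivity mode {mode!r}")
    unknown = set(survivors_by_sample) - set(design.samples)
    if unknown:
        raise DataError(f"samples not in cohort design: {sorted(unknown)}")

    rows: set[str] = set()
    hits: dict[str, set] = {}
    n_skipped = 0
    for sid, variants in survivors_by_sample.items():
        for v in variants:
            if mode == GENE_MODE:
                if not v.gene:
                    n_skipped += 1
                    continue
                label = v.gene
            else:
                label = str(v.key)
            rows.add(label)
            hits.setdefault(label, set()).add(sid)
    if n_skipped:
        log.info("build_incidence: skipped %d gene-less variants in gene mode", n_skipped)

    index = sorted(rows)
    columns = list(design.samples)
    matrix = pd.DataFrame(False, index=index, columns=columns, dtype=bool)
    for label, sids in hits.items():
        matrix.loc[label, list(sids)] = True
    return matrix


def shared_exclusive(
    matrix: pd.DataFrame,
    design: CohortDesign,
    min_case_fraction: float = 1.0,
    max_control_count: int = 0,
    mode: str = GENE_MODE,
) -> CandidateReport:
    """Rows present in all cases and absent from all controls.

    The defaults implement the strict rule; ``min_case_fraction`` < 1 or
    ``max_control_count`` > 0 relax it (present in >= fraction of cases,
    tolerated in <= count of controls).  Output order is lexicographic.
    """
    design.require_cases_and_controls()
    cases = [s for s in design.cases if s in matrix.columns]
    controls = [s for s in design.controls if s in matrix.columns]
    if len(cases) != len(design.cases) or len(controls) != len(design.controls):
        missing = (set(design.cases) | set(design.controls)) - set(matrix.columns)
        raise DataError(f"incidence matrix lacks design samples: {sorted(missing)}")

    candidates = []
    for name in sorted(matrix.index):
        case_hits = [s for s in cases if matrix.at[name, s]]
        control_hits = [s for s in controls if matrix.at[name, s]]
        if len(case_hits) >= min_case_fraction * len(cases) and len(case_hits) > 0 \
                and len(control_hits) <= max_control_count:
            candidates.append(Candidate(name=name, case_support=tuple(case_hits)))
    return CandidateReport(mode=mode, candidates=tuple(candidates))


def exclusivity_oracle(
    matrix: pd.DataFrame,
    design: CohortDesign,
    mode: str = GENE_MODE,
) -> CandidateReport:
    """Brute-force reference for the strict rule: test every cell of every row.

    Test use only (exhaustive scan); same output contract as
    :func:`shared_exclusive` at default thresholds.
    """
    design.require_cases_and_controls()
    candidates = []
    for name in sorted(matrix.index):
        ok = True
        for s in design.cases:
            if not bool(matrix.at[name, s]):
                ok = False
        for s in design.controls:
            if bool(matrix.at[name, s]):
                ok = False
        if ok:
            candidates.append(
                Candidate(name=name, case_support=tuple(design.cases))
            )
    return CandidateReport(mode=mode, candidates=tuple(candidates))


def attach_support(
    report: CandidateReport,
    survivors_by_sample: Mapping[str, Sequence[AnnotatedVariant]],
) -> CandidateReport:
    """Fill each candidate's supporting variants from the survivor lists."""
    enriched = []
    for c in report.candidates:
        per_sample = {}
        for sid in c.case_support:
            if report.mode == GENE_MODE:
                vs = tuple(v for v in survivors_by_sample.get(sid, ()) if v.gene == c.name)
            else:
                vs = tuple(
                    v for v in survivors_by_sample.get(sid, ()) if str(v.key) == c.name
                )
            per_sample[sid] = vs
        enriched.append(Candidate(c.name, c.case_support, per_sample))
    return CandidateReport(mode=report.mode, candidates=tuple(enriched))
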