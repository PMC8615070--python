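"""End-to-end orchestration: ingest -> cascade -> exclusivity -> reports.

The pipeline is a pure function of its inputs and configuration: re-running
on identical inputs reproduces every report byte-for-byte (only the
manifest timestamp differs).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from fractions import Fraction
from pathlib import Path

import yaml

from . import __version__
from .errors import ConfigError, DataError
from .exclusivity import attach_support, build_incidence, shared_exclusive
from .filters import FilterParams, run_cascade, write_funnels
from .qc import class_counts, write_qc_table
from .variant_io import AnnotationDialect, read_design, read_sample

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths, thresholds and dialect for one pipeline run.

    ``vcf_dir`` and ``anno_dir`` must contain ``<sample>.vcf`` and
    ``<sample>.tsv`` for every sample named in the design file.
    """

    vcf_dir: str
    anno_dir: str
    design: str
    out_dir: str
    mode: str = "gene"
    max_pop_freq: float = 0.005
    consensus_threshold: float = 0.70
    min_case_fraction: float = 1.0
    max_control_count: int = 0
    harmonize_chr: bool = False
    strict_terms: bool = False
    columns: dict = field(default_factory=dict)  # AnnotationDialect overrides
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        missing = {"vcf_dir", "anno_dir", "design", "out_dir"} - set(raw)
        if missing:
            raise ConfigError(f"config missing required keys: {sorted(missing)}")
        return cls(**raw)

    def filter_params(self) -> FilterParams:
        try:
            return FilterParams(
                max_pop_freq=self.max_pop_freq,
                consensus_threshold=Fraction(self.consensus_threshold).limit_denominator(10**6),
                strict_terms=self.strict_terms,
            )
        except ConfigError:
            raise
        except Exception as exc:  # bad types from YAML
            raise ConfigError(f"invalid filter parameters: {exc}")

    def dialect(self) -> AnnotationDialect:
        if not self.columns:
            return AnnotationDialect()
        known = set(AnnotationDialect.__dataclass_fields__)
        unknown = set(self.columns) - known
        if unknown:
            raise ConfigError(f"unknown annotation column keys: {sorted(unknown)}")
        return AnnotationDialect(**self.columns)

    def validate_paths(self) -> None:
        for name in ("vcf_dir", "anno_dir", "design"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise ConfigError(f"{name} does not exist: {p}")


@dataclass
class PipelineResult:
    candidates: object  # CandidateReport
    funnels: dict
    qc: dict
    survivors_by_sample: dict
    out_paths: dict


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute the full prioritization on a cohort and write all reports.

    Writes ``funnel.tsv`` (per-sample stage counts), ``candidates.tsv``
    (exclusive genes/variants with supporting calls), ``qc_stats.tsv``
    (per-sample variant statistics) and ``manifest.yaml`` under
    ``out_dir``.  Succeeds (and still writes reports) when the candidate
    set is empty.
    """
    cfg.validate_paths()
    params = cfg.filter_params()
    dialect = cfg.dialect()
    if cfg.mode not in ("gene", "variant"):
        raise ConfigError(f"mode must be 'gene' or 'variant', got {cfg.mode!r}")

    design = read_design(cfg.design)
    design.require_cases_and_controls()

    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    survivors_by_sample, funnels, qc = {}, {}, {}
    for sid in design.samples:
        vcf_path = Path(cfg.vcf_dir) / f"{sid}.vcf"
        anno_path = Path(cfg.anno_dir) / f"{sid}.tsv"
        try:
            variants = read_sample(vcf_path, anno_path, sid, dialect, cfg.harmonize_chr)
        except DataError as exc:
            raise DataError(f"[ingest] sample {sid}: {exc}")
        qc[sid] = class_counts(variants)
        try:
            survivors, funnel = run_cascade(variants, params)
        except DataError as exc:
            raise DataError(f"[cascade] sample {sid}: {exc}")
        survivors_by_sample[sid] = survivors
        funnels[sid] = funnel

    try:
        matrix = build_incidence(survivors_by_sample, design, cfg.mode)
        report = shared_exclusive(
            matrix, design,
            min_case_fraction=cfg.min_case_fraction,
            max_control_count=cfg.max_control_count,
            mode=cfg.mode,
        )
    except DataError as exc:
        raise DataError(f"[exclusivity] {exc}")
    report = attach_support(report, survivors_by_sample)

    out_paths = {
        "funnel": out_dir / "funnel.tsv",
        "candidates": out_dir / "candidates.tsv",
        "qc": out_dir / "qc_stats.tsv",
        "manifest": out_dir / "manifest.yaml",
    }
    write_funnels(funnels.values(), out_paths["funnel"])
    report.to_frame().to_csv(out_paths["candidates"], sep="\t", index=False)
    write_qc_table(qc, out_paths["qc"])

    cfg_dict = asdict(cfg)
    manifest = {
        "package": "varsieve",
        "version": __version__,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
        "n_samples": len(design.samples),
        "n_candidates": len(report.candidates),
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    with open(out_paths["manifest"], "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)

    log.info("pipeline done: %d candidate %s(s)", len(report.candidates), cfg.mode)
    return PipelineResult(report, funnels, qc, survivors_by_sample, out_paths)
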