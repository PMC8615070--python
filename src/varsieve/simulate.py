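"""Seeded synthetic exome-cohort generator.

Emulates the *post-annotation* variant tables a case-control exome study
feeds into rare-variant prioritization: per-sample VCF + annotation TSV
with an exome-like consequence spectrum, a transition-rich SNV pool
(Ts/Tv ~ 2.3), a rare/common allele-frequency mixture, predictor label
vectors drawn from a latent neutral/damaging state — plus *planted truth*:
driver genes mutated in every case and no control, and one decoy gene per
way of almost-qualifying (shared but also in a control; shared by all but
one case; exclusive but synonymous; exclusive but common; exclusive but
benign by predictor consensus).  Every decoy violates exactly one rule, so
recovery tests can pin each pipeline stage to the class it must eliminate.

Generation is a pure function of the config (which includes the seed);
identical configs produce byte-identical files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .errors import ConfigError
from .filters import IMPACT_BY_TERM
from .variant_io import (
    AnnotatedVariant,
    CohortDesign,
    HETEROZYGOUS,
    HOMOZYGOUS,
    VariantKey,
    write_design,
)

log = logging.getLogger(__name__)

CONTIGS = ("1", "2", "3", "4", "5")
CONTIG_LENGTH = 20_000_000

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"), "G": ("C", "T"), "C": ("A", "G"), "T": ("A", "G"),
}

# Exome-like consequence spectra (term, probability), conditioned on class.
# Coding fractions reflect a typical exome annotation output: ~13% of SNVs
# synonymous, ~13% missense, rare stop events, ~7% of indels protein-altering.
SNV_TERMS = (
    ("synonymous_variant", 0.1337),
    ("missense_variant", 0.1256),
    ("stop_gained", 0.00117),
    ("stop_lost", 0.00048),
    ("splice_acceptor_variant", 0.0015),
    ("splice_donor_variant", 0.0015),
    ("splice_region_variant", 0.003),
    ("intron_variant", 0.50),
    ("5_prime_UTR_variant", 0.03),
    ("3_prime_UTR_variant", 0.04),
    ("intergenic_variant", 0.13285),
    ("upstream_gene_variant", 0.015),
    ("downstream_gene_variant", 0.0152),
)
INDEL_TERMS = (
    ("frameshift_variant", 0.03144),
    ("inframe_insertion", 0.01717),
    ("inframe_deletion", 0.01959),
    ("splice_region_variant", 0.002),
    ("intron_variant", 0.60),
    ("5_prime_UTR_variant", 0.03),
    ("3_prime_UTR_variant", 0.05),
    ("intergenic_variant", 0.2498),
)

DECOY_CLASSES = (
    "exclusivity-control-hit",      # qualifying variant in all cases AND one control
    "exclusivity-case-incomplete",  # qualifying variant in all but one case
    "consequence",                  # exclusive but synonymous
    "frequency",                    # exclusive but common (pop freq > cutoff)
    "consensus",                    # exclusive but >= 70% benign predictions
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of the simulated cohort.

    Defaults are the desk-scale test regime: 5 cases (2 AP + 3 BC, echoing
    a five-exome discovery set), 5 controls, 2,000 background variants per
    sample.  ``n_background_variants=90_000`` reproduces the full-scale
    annotated-exome regime, where the cascade's expected survivor count is
    ~124 per sample (see the frequency/consensus parameters below).
    Transition probability 2.3/3.3 makes the expected Ts/Tv ratio 2.3.
    """

    n_ap: int = 2
    n_bc: int = 3
    n_cp: int = 3
    n_healthy: int = 2
    n_background_variants: int = 2_000
    n_driver_genes: int = 3
    decoys_per_class: int = 1
    transition_prob: float = 2.3 / 3.3
    indel_fraction: float = 0.1005
    common_fraction: float = 0.97      # variants common in population databases
    novel_fraction: float = 0.5        # rare variants absent from every database
    p_het: float = 1.4 / 2.4           # gives het/hom ~ 1.4
    p_neutral: float = 0.93            # latent benign state prior
    predictor_count: int = 4
    neutral_label_probs: tuple = (0.70, 0.20, 0.05, 0.05)   # B, T, D, U
    damaging_label_probs: tuple = (0.10, 0.10, 0.70, 0.10)  # B, T, D, U
    n_background_genes: int = 8_000
    survivor_band: tuple = (90, 160)   # expected per-sample survivors at full scale
    seed: int = 42

    def __post_init__(self):
        for name in ("n_ap", "n_bc", "n_cp", "n_healthy", "n_background_variants",
                     "n_driver_genes", "decoys_per_class", "predictor_count",
                     "n_background_genes"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("transition_prob", "indel_fraction", "common_fraction",
                     "novel_fraction", "p_het", "p_neutral"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for probs in (self.neutral_label_probs, self.damaging_label_probs):
            if len(probs) != 4 or abs(sum(probs) - 1.0) > 1e-9:
                raise ConfigError(f"label probabilities must be 4 values summing to 1, got {probs}")

    @property
    def n_cases(self) -> int:
        return self.n_ap + self.n_bc

    @property
    def n_controls(self) -> int:
        return self.n_cp + self.n_healthy


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of a simulated cohort: drivers and per-decoy designed stage."""

    driver_genes: tuple
    decoys: Mapping[str, str]  # gene -> designed elimination stage


@dataclass
class SimulatedCohort:
    config: SyntheticConfig
    design: CohortDesign
    variants_by_sample: dict
    truth: PlantedTruth


def _design_from_config(cfg: SyntheticConfig) -> CohortDesign:
    assignments = {}
    for i in range(cfg.n_ap):
        assignments[f"AP{i + 1}"] = "AP"
    for i in range(cfg.n_bc):
        assignments[f"BC{i + 1}"] = "BC"
    for i in range(cfg.n_cp):
        assignments[f"CP{i + 1}"] = "CP"
    for i in range(cfg.n_healthy):
        assignments[f"HC{i + 1}"] = "HEALTHY"
    return CohortDesign(assignments)


def _ref_base(contig_index: int, pos: int) -> str:
    """Deterministic pseudo-reference base, consistent across samples."""
    return "ACGT"[(pos * 2654435761 + contig_index * 97) % 4]


def simulate_snv_keys(
    n: int, transition_prob: float, rng: np.random.Generator, contig: str = "1"
) -> list:
    """Draw ``n`` SNV keys with the given per-variant transition probability."""
    ci = CONTIGS.index(contig) if contig in CONTIGS else 0
    pos = rng.integers(1, CONTIG_LENGTH, size=n)
    is_ts = rng.random(n) < transition_prob
    pick = rng.integers(0, 2, size=n)
    keys = []
    for p, ts, k in zip(pos.tolist(), is_ts.tolist(), pick.tolist()):
        ref = _ref_base(ci, p)
        alt = _TRANSITION[ref] if ts else _TRANSVERSIONS[ref][k]
        keys.append(VariantKey(contig, int(p), ref, alt))
    return keys


def _draw_labels(n: int, k: int, cfg: SyntheticConfig, rng: np.random.Generator,
                 neutral_mask: np.ndarray) -> list:
    letters = np.array(["B", "T", "D", "U"])
    ln = rng.choice(4, size=(n, k), p=cfg.neutral_label_probs)
    ld = rng.choice(4, size=(n, k), p=cfg.damaging_label_probs)
    chosen = np.where(neutral_mask[:, None], ln, ld)
    return [tuple(letters[row]) for row in chosen]


def _background_variants(sample_id: str, cfg: SyntheticConfig,
                         rng: np.random.Generator, reserved_keys: set) -> list:
    """One sample's background: vectorized draws, then object construction."""
    n = cfg.n_background_variants
    if n == 0:
        return []
    m = int(n * 1.02) + 10  # oversample to absorb key collisions
    contig_idx = rng.integers(0, len(CONTIGS), size=m)
    pos = rng.integers(1, CONTIG_LENGTH, size=m)
    is_indel = rng.random(m) < cfg.indel_fraction
    is_ts = rng.random(m) < cfg.transition_prob
    tv_pick = rng.integers(0, 2, size=m)
    is_het = rng.random(m) < cfg.p_het
    is_common = rng.random(m) < cfg.common_fraction
    is_novel = rng.random(m) < cfg.novel_fraction
    common_freq = rng.uniform(0.006, 0.5, size=m)
    esp_scale = rng.uniform(0.5, 1.5, size=m)
    rare_freq = rng.uniform(1e-5, 0.005, size=m)
    neutral = rng.random(m) < cfg.p_neutral
    labels = _draw_labels(m, cfg.predictor_count, cfg, rng, neutral)
    gene_idx = rng.integers(0, max(cfg.n_background_genes, 1), size=m)

    snv_terms, snv_probs = zip(*SNV_TERMS)
    indel_terms, indel_probs = zip(*INDEL_TERMS)
    snv_p = np.asarray(snv_probs) / sum(snv_probs)
    indel_p = np.asarray(indel_probs) / sum(indel_probs)
    snv_term_idx = rng.choice(len(snv_terms), size=m, p=snv_p)
    indel_term_idx = rng.choice(len(indel_terms), size=m, p=indel_p)
    indel_is_ins = rng.random(m) < 0.5
    frameshift_len = rng.integers(1, 3, size=m)  # 1 or 2 nt

    out = []
    seen = set(reserved_keys)
    for i in range(m):
        if len(out) == n:
            break
        ci = int(contig_idx[i])
        p = int(pos[i])
        ref0 = _ref_base(ci, p)
        if not is_indel[i]:
            term = snv_terms[snv_term_idx[i]]
            alt = _TRANSITION[ref0] if is_ts[i] else _TRANSVERSIONS[ref0][tv_pick[i]]
            ref = ref0
        else:
            term = indel_terms[indel_term_idx[i]]
            if term == "frameshift_variant":
                length, ins = int(frameshift_len[i]), bool(indel_is_ins[i])
            elif term == "inframe_insertion":
                length, ins = 3, True
            elif term == "inframe_deletion":
                length, ins = 3, False
            else:
                length, ins = int(frameshift_len[i]), bool(indel_is_ins[i])
            tail = "".join(_ref_base(ci, p + j) for j in range(1, length + 1))
            if ins:
                ref, alt = ref0, ref0 + tail
            else:
                ref, alt = ref0 + tail, ref0
        key = VariantKey(CONTIGS[ci], p, ref, alt)
        if (key.chrom, key.pos) in seen:
            continue
        seen.add((key.chrom, key.pos))

        if term == "intergenic_variant":
            gene = ""
        else:
            gene = f"G{int(gene_idx[i]):05d}"
        if is_common[i]:
            f = float(common_freq[i])
            freqs = {"dbSNP": round(f, 6), "ESP": round(min(f * float(esp_scale[i]), 1.0), 6)}
        elif is_novel[i]:
            freqs = {}
        else:
            freqs = {"dbSNP": round(float(rare_freq[i]), 6)}

        out.append(
            AnnotatedVariant(
                sample_id=sample_id,
                key=key,
                zygosity=HETEROZYGOUS if is_het[i] else HOMOZYGOUS,
                gene=gene,
                consequences=frozenset({term}),
                pop_freqs=freqs,
                predictions=labels[i],
            )
        )
    if len(out) < n:
        log.warning("%s: generated %d background variants (requested %d)", sample_id, len(out), n)
    return out


def _planted_variant(sample_id: str, gene: str, key: VariantKey, consequence: str,
                     freqs: Mapping[str, float], predictions: tuple) -> AnnotatedVariant:
    return AnnotatedVariant(
        sample_id=sample_id,
        key=key,
        zygosity=HETEROZYGOUS,
        gene=gene,
        consequences=frozenset({consequence}),
        pop_freqs=dict(freqs),
        predictions=predictions,
    )


def simulate_cohort(cfg: SyntheticConfig) -> SimulatedCohort:
    """Generate the in-memory cohort: background + planted drivers and decoys."""
    design = _design_from_config(cfg)
    if cfg.n_driver_genes > 0 or cfg.decoys_per_class > 0:
        design.require_cases_and_controls()
    rng = np.random.default_rng(cfg.seed)

    # cohort-level planted structure (positions on the last contig, fixed
    # stride, disjoint from each other; the pseudo-reference gives the ref)
    plant_contig = CONTIGS[-1]
    ci = len(CONTIGS) - 1
    next_pos = 15_000_000
    damaging = tuple(
        ["D"] * (cfg.predictor_count - 1) + ["U"]
    ) if cfg.predictor_count > 1 else ("D",)
    benign = tuple(["B"] * cfg.predictor_count)

    def fresh_snv() -> VariantKey:
        nonlocal next_pos
        p = next_pos
        next_pos += 1_000
        ref = _ref_base(ci, p)
        return VariantKey(plant_contig, p, ref, _TRANSITION[ref])

    drivers = []
    for i in range(cfg.n_driver_genes):
        drivers.append((f"DRV{i + 1:02d}", fresh_snv()))

    decoys: dict[str, tuple] = {}  # gene -> (stage, key, consequence, freqs, preds, samples)
    cases, controls = list(design.cases), list(design.controls)
    for c in range(cfg.decoys_per_class):
        sfx = f"{c + 1:02d}"
        qualifying = ("missense_variant", {}, damaging)
        specs = {
            f"DCYCTRL{sfx}": ("exclusivity-control-hit", qualifying,
                              cases + controls[:1]),
            f"DCYPART{sfx}": ("exclusivity-case-incomplete", qualifying,
                              cases[1:] if len(cases) > 1 else []),
            f"DCYSYN{sfx}": ("consequence", ("synonymous_variant", {}, damaging), cases),
            f"DCYFREQ{sfx}": ("frequency",
                              ("missense_variant", {"dbSNP": 0.01, "ESP": 0.012}, damaging),
                              cases),
            f"DCYBEN{sfx}": ("consensus", ("missense_variant", {}, benign), cases),
        }
        for gene, (stage, (cons, freqs, preds), samples) in specs.items():
            if not samples:
                log.warning("decoy %s skipped: not enough samples for class %s", gene, stage)
                continue
            decoys[gene] = (stage, fresh_snv(), cons, freqs, preds, tuple(samples))

    reserved = {(plant_contig, k.pos) for _, k in drivers}
    reserved |= {(plant_contig, spec[1].pos) for spec in decoys.values()}

    variants_by_sample: dict[str, list] = {}
    for sid in design.samples:  # fixed order => reproducible
        sample_variants = _background_variants(sid, cfg, rng, reserved)
        if sid in design.cases:
            for gene, key in drivers:
                sample_variants.append(
                    _planted_variant(sid, gene, key, "missense_variant", {}, damaging)
                )
        for gene, (stage, key, cons, freqs, preds, samples) in decoys.items():
            if sid in samples:
                sample_variants.append(_planted_variant(sid, gene, key, cons, freqs, preds))
        sample_variants.sort(key=lambda v: (CONTIGS.index(v.key.chrom), v.key.pos, v.key.ref, v.key.alt))
        variants_by_sample[sid] = sample_variants

    truth = PlantedTruth(
        driver_genes=tuple(g for g, _ in drivers),
        decoys={g: spec[0] for g, spec in decoys.items()},
    )
    return SimulatedCohort(cfg, design, variants_by_sample, truth)


# ---------------------------------------------------------------------------
# Writing a cohort to disk (VCF + annotation TSV + design + truth manifest)

def _write_vcf(variants: Sequence[AnnotatedVariant], sample_id: str, path) -> None:
    header = pysam.VariantHeader()
    header.add_line("##source=varsieve-simulator")
    for contig in CONTIGS:
        header.add_line(f"##contig=<ID={contig},length={CONTIG_LENGTH}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_sample(sample_id)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for v in variants:
            rec = vf.new_record(
                contig=v.key.chrom,
                start=v.key.pos - 1,
                stop=v.key.pos - 1 + len(v.key.ref),
                alleles=(v.key.ref, v.key.alt),
            )
            rec.samples[sample_id]["GT"] = (0, 1) if v.zygosity == HETEROZYGOUS else (1, 1)
            vf.write(rec)


def _annotation_frame(variants: Sequence[AnnotatedVariant]) -> pd.DataFrame:
    rows = []
    for v in variants:
        impacts = [IMPACT_BY_TERM.get(t, "MODIFIER") for t in sorted(v.consequences)]
        order = ("HIGH", "MODERATE", "LOW", "MODIFIER")
        rows.append(
            {
                "chrom": v.key.chrom,
                "pos": v.key.pos,
                "ref": v.key.ref,
                "alt": v.key.alt,
                "gene": v.gene,
                "consequence": "&".join(sorted(v.consequences)),
                "impact": min(impacts, key=order.index),
                "dbsnp_af": v.pop_freqs.get("dbSNP", ""),
                "esp_af": v.pop_freqs.get("ESP", ""),
                "predictions": "&".join(v.predictions),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "gene", "consequence", "impact",
                 "dbsnp_af", "esp_af", "predictions"],
    )


def write_cohort(cohort: SimulatedCohort, outdir) -> dict:
    """Write per-sample VCF + annotation TSV, design file and truth manifest.

    Returns a dict of output paths.  Output is byte-identical for identical
    configs (no timestamps, fixed ordering).
    """
    outdir = Path(outdir)
    (outdir / "vcf").mkdir(parents=True, exist_ok=True)
    (outdir / "anno").mkdir(parents=True, exist_ok=True)
    paths = {"vcf": {}, "anno": {}}
    for sid, variants in cohort.variants_by_sample.items():
        vcf_path = outdir / "vcf" / f"{sid}.vcf"
        anno_path = outdir / "anno" / f"{sid}.tsv"
        _write_vcf(variants, sid, vcf_path)
        _annotation_frame(variants).to_csv(anno_path, sep="\t", index=False)
        paths["vcf"][sid] = vcf_path
        paths["anno"][sid] = anno_path

    design_path = outdir / "design.tsv"
    write_design(cohort.design, design_path)
    paths["design"] = design_path

    truth_rows = [
        {"gene": g, "role": "driver", "designed_stage": "survivor"}
        for g in cohort.truth.driver_genes
    ] + [
        {"gene": g, "role": "decoy", "designed_stage": stage}
        for g, stage in cohort.truth.decoys.items()
    ]
    truth_path = outdir / "truth.tsv"
    pd.DataFrame(truth_rows, columns=["gene", "role", "designed_stage"]).to_csv(
        truth_path, sep="\t", index=False
    )
    paths["truth"] = truth_path
    return paths


def generate_cohort(cfg: SyntheticConfig, outdir) -> tuple:
    """Simulate and write a cohort; returns ``(paths, PlantedTruth)``."""
    cohort = simulate_cohort(cfg)
    paths = write_cohort(cohort, outdir)
    log.info(
        "simulated cohort: %d samples, %d drivers, %d decoys -> %s",
        len(cohort.design.samples), len(cohort.truth.driver_genes),
        len(cohort.truth.decoys), outdir,
    )
    return paths, cohort.truth


# ---------------------------------------------------------------------------
# Hand-checkable 4-sample worked fixture (2 cases, 2 controls, 18 variants)

# (sample, chrom, pos, ref, alt, zygosity, gene, consequence, freqs, predictions)
_TRIO_ROWS = (
    ("AP1", "1", 1000, "A", "T", HETEROZYGOUS, "TRIOA", "missense_variant", {}, ("D", "D", "D")),
    ("AP1", "1", 2000, "G", "A", HETEROZYGOUS, "TRIOB", "synonymous_variant", {}, ()),
    ("AP1", "1", 3000, "C", "T", HOMOZYGOUS, "TRIOC", "missense_variant", {"dbSNP": 0.02}, ("D",)),
    ("AP1", "1", 4000, "T", "C", HETEROZYGOUS, "TRIOD", "missense_variant", {}, ("B", "B", "B")),
    ("AP1", "1", 5000, "A", "G", HETEROZYGOUS, "TRIOE", "missense_variant", {}, ("D", "D")),
    ("AP1", "1", 6000, "C", "A", HETEROZYGOUS, "TRIOF", "missense_variant", {}, ("D", "D")),
    ("AP1", "2", 500, "G", "T", HOMOZYGOUS, "TRIOG", "intron_variant", {}, ()),
    ("BC1", "1", 1000, "A", "T", HOMOZYGOUS, "TRIOA", "missense_variant", {}, ("D", "D", "U")),
    ("BC1", "1", 2000, "G", "A", HETEROZYGOUS, "TRIOB", "synonymous_variant", {}, ()),
    ("BC1", "1", 3000, "C", "T", HETEROZYGOUS, "TRIOC", "missense_variant", {"dbSNP": 0.02}, ("D",)),
    ("BC1", "1", 4000, "T", "C", HETEROZYGOUS, "TRIOD", "missense_variant", {}, ("B", "B", "B", "B")),
    ("BC1", "1", 5000, "A", "G", HETEROZYGOUS, "TRIOE", "missense_variant", {}, ("D", "D")),
    ("BC1", "2", 600, "T", "A", HETEROZYGOUS, "TRIOH", "stop_gained", {"dbSNP": 0.0001}, ("D", "D")),
    ("CP1", "1", 5000, "A", "G", HETEROZYGOUS, "TRIOE", "missense_variant", {}, ("D", "D")),
    ("CP1", "2", 100, "A", "G", HETEROZYGOUS, "TRIOI", "intron_variant", {}, ()),
    ("CP1", "2", 200, "C", "T", HETEROZYGOUS, "TRIOJ", "missense_variant", {"dbSNP": 0.1, "ESP": 0.08}, ("B",)),
    ("HC1", "2", 300, "G", "C", HETEROZYGOUS, "TRIOK", "synonymous_variant", {}, ()),
    ("HC1", "2", 400, "A", "C", HETEROZYGOUS, "TRIOL", "missense_variant", {"dbSNP": 0.001}, ("T", "T", "T")),
)

TRIO_DESIGN = {"AP1": "AP", "BC1": "BC", "CP1": "CP", "HC1": "HEALTHY"}

#: Expected funnel counts (input, after consequence, after frequency, after consensus).
TRIO_EXPECTED_FUNNELS = {
    "AP1": (7, 5, 4, 3),
    "BC1": (6, 5, 4, 3),
    "CP1": (3, 2, 1, 1),
    "HC1": (2, 1, 1, 0),
}

#: The only gene mutated in both cases and neither control after filtering.
TRIO_EXPECTED_CANDIDATES = ("TRIOA",)


def trio_cohort() -> SimulatedCohort:
    """The packaged 4-sample worked example as an in-memory cohort."""
    design = CohortDesign(TRIO_DESIGN)
    by_sample: dict[str, list] = {sid: [] for sid in design.samples}
    for sid, chrom, pos, ref, alt, zyg, gene, cons, freqs, preds in _TRIO_ROWS:
        by_sample[sid].append(
            AnnotatedVariant(
                sample_id=sid,
                key=VariantKey(chrom, pos, ref, alt),
                zygosity=zyg,
                gene=gene,
                consequences=frozenset({cons}),
                pop_freqs=dict(freqs),
                predictions=preds,
            )
        )
    truth = PlantedTruth(
        driver_genes=("TRIOA",),
        decoys={
            "TRIOB": "consequence",
            "TRIOC": "frequency",
            "TRIOD": "consensus",
            "TRIOE": "exclusivity-control-hit",
            "TRIOF": "exclusivity-case-incomplete",
        },
    )
    cfg = SyntheticConfig(n_ap=1, n_bc=1, n_cp=1, n_healthy=1,
                          n_background_variants=0, n_driver_genes=1, seed=0)
    return SimulatedCohort(cfg, design, by_sample, truth)


def generate_trio_fixture(outdir) -> dict:
    """Write the worked 4-sample fixture (static-file twin lives in examples/)."""
    return write_cohort(trio_cohort(), outdir)
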