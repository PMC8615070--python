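# varsieve

Rare-variant prioritization for case-control exome cohorts.

`varsieve` re-implements, as a tested and reusable pipeline, the
variant-prioritization strategy used in whole-exome studies of disease
progression — for example, nominating a gene as a progression biomarker of
chronic myeloid leukemia (CML) because it is mutated in *every*
advanced-phase (accelerated/blast-crisis) patient and in *no* chronic-phase
patient or healthy control. It is aimed at analysts who start from
**annotated** per-sample variant tables (VCF + annotation TSV) rather than
raw reads: alignment, variant calling and functional annotation are upstream
and out of scope.

## What it does

1. **Filter cascade** — per sample, an ordered, auditable sequence of three
   pure predicates:
   * *consequence/impact*: keep variants with HIGH or MODERATE
     (protein-altering) impact or any splice-site term; drop synonymous,
     intronic, intergenic and other MODIFIER calls;
   * *population frequency*: drop variants with allele frequency
     > 0.005 in **any** population database (dbSNP, ESP, …); variants absent
     from every database are kept;
   * *predictor consensus*: with predictor verdicts
     B (benign) / T (tolerated) / D (damaging) / U (unknown), drop a variant
     when `#B / #known ≥ 0.70` or `#T / #known ≥ 0.70`, computed with exact
     rational arithmetic so that 7/10 is eliminated and 2/3 is retained.

   Each stage records in/out counts in a per-sample **funnel** (at exome
   scale: ~90,000 annotated variants → ~12,000 protein-altering → a few
   hundred rare → ~10² final survivors per sample).

2. **Case-exclusivity intersection** — build a boolean gene × sample
   incidence matrix from the survivors and report genes (or exact variants,
   `--mode variant`) present in **all** cases (AP, BC) and **no** control
   (CP, HEALTHY). A brute-force oracle implementation is shipped and tested
   equivalent for auditability.

3. **Coding-consequence engine** — parse HGVS-style `c.` notation
   (substitution, deletion, duplication, insertion, delins), apply several
   variants *simultaneously* against original CDS coordinates
   (right-to-left), translate with the standard genetic code, and diff the
   proteins.

4. **QC statistics** — per-sample variant class counts, het/hom ratio and
   Ts/Tv ratio, plus report-style cohort percentages.

5. **Synthetic cohort simulator** — a seeded generator of VCF + annotation
   tables with exome-like structure (Ts/Tv ≈ 2.3, rare/common frequency
   mixture, realistic consequence spectrum) and *planted truth*: driver
   genes exclusive to the cases, and one decoy gene per way of
   almost-qualifying, so every pipeline stage is testable without any
   external download.

## Worked example

The engine reproduces the protein-level effect of the two confirmed
ANKRD36 coding mutations — a GC deletion at CDS 1183–1184 and a TT
duplication at 1187–1188. No public reference CDS for the transcript is
bundled; `build_cds` reconstructs the minimal consistent context (codon
395 = GCT/Ala, codon 396 = GTT/Val — the unique assignment under which the
two edits yield the reported Cys/Phe outcome):

```python
from varsieve import build_cds, parse_hgvs_c, predict_effect

cds = build_cds(396, {395: "GCT", 396: "GTT"})
diff = predict_effect(cds, [parse_hgvs_c("c.1183_1184delGC"),
                            parse_hgvs_c("c.1187_1188dupTT")])
print(diff.summary)          # p.A395C; p.V396F
print(diff.length_change)    # 0
```

or on the command line:

```
$ varsieve consequence --cds cds.fa --variant c.1183_1184delGC --variant c.1187_1188dupTT
p.A395C; p.V396F
residue 395: A -> C
residue 396: V -> F
protein length change: 0 residues
```

The −2 nt deletion and +2 nt duplication cancel, so the frame is preserved
and exactly two consecutive residues change: Ala→Cys at 395 and Val→Phe at
396.

End-to-end on a simulated cohort (2 AP + 3 BC cases, 3 CP + 2 healthy
controls, 2,000 background variants each, 3 planted drivers, 5 decoys):

```
$ varsieve simulate --out demo --seed 42
planted drivers: DRV01, DRV02, DRV03
decoy DCYCTRL01: eliminated at exclusivity-control-hit
decoy DCYPART01: eliminated at exclusivity-case-incomplete
decoy DCYSYN01: eliminated at consequence
decoy DCYFREQ01: eliminated at frequency
decoy DCYBEN01: eliminated at consensus

$ varsieve run --config demo.yaml
candidates (gene mode): DRV01, DRV02, DRV03
reports written to demo_out
```

`funnel.tsv` then shows each sample's cascade, e.g. `AP1: 2007 → 246 → 12 →
8`: of 2,007 annotated variants, 246 are protein-altering/splice, 12 are
also rare, and 8 survive the predictor-consensus vote. The candidate report
contains exactly the three planted driver genes — every decoy was removed
at the stage it was designed to violate.

A hand-checkable 4-sample fixture with one driver and all five decoy
classes lives in `examples/trio/` (expectation table in
`docs/methods.md`).

## Layout

```
src/varsieve/
  variant_io.py    VCF + annotation ingest, key normalization, cohort design
  filters.py       the three-stage cascade and funnel audit
  exclusivity.py   incidence matrix, shared-exclusive rule, brute-force oracle
  consequence.py   HGVS c. parsing, joint application, translation, protein diff
  qc.py            class counts, het/hom, Ts/Tv, cohort fractions
  simulate.py      seeded cohort generator with planted truth
  pipeline.py      orchestration and reports
  cli.py           varsieve run | simulate | consequence | stats
```
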