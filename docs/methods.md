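# Methods

## Problem and model

Given per-sample annotated exome variant calls from a case-control cohort
(cases: accelerated-phase and blast-crisis CML; controls: chronic-phase CML
and healthy donors), the pipeline prioritizes candidate progression drivers
in two steps: a per-sample **filter cascade** that reduces ~10⁵ annotated
variants to a small set of rare, protein-altering, not-predicted-benign
survivors, followed by a **case-exclusivity intersection** that keeps only
genes (or exact variants) carried by every case and by no control. The
logic is purely set-theoretic: no recurrence statistics or permutation
p-values are computed, because the underlying design argues from strict
presence/absence, not from enrichment.

### Filter cascade

Stages run in a fixed order and each is a pure per-variant predicate, so
the cascade is idempotent, every stage is monotone non-increasing, and the
surviving *set* is invariant under stage permutation (the funnel counts are
not — they are an audit trail of the configured order).

1. **Consequence/impact.** Consequence terms follow the Sequence Ontology
   vocabulary; impact classes follow the standard VEP/SnpEff-style
   taxonomy. A variant is retained iff *any* of its terms is HIGH
   (stop gained/lost, start lost, frameshift, splice donor/acceptor),
   MODERATE (missense, inframe indel, protein-altering) — the
   "high and intermediate protein effect" classes — or any splice term
   (including `splice_region_variant`, despite its LOW impact). "Deep
   intronic" is therefore operationalized as: `intron_variant` with no
   accompanying splice term ⇒ excluded. No base-pair window is computed;
   the pipeline consumes pre-annotated terms. Unknown terms are treated as
   MODIFIER with a warning (strict mode errors instead).
2. **Population frequency.** Excluded iff max over *available* sources
   (default dbSNP and ESP columns) is strictly greater than 0.005. The
   inequality is strict: a variant at exactly 0.005 survives. Absence from
   every database is a defined state and retains the variant — novel
   variants are precisely the prioritized ones, so missing data must never
   be imputed as 0 or as common.
3. **Predictor consensus.** Verdicts are aggregated per variant across all
   predictors/transcripts (union of calls, one vote each). Frequencies are
   computed over *known* calls only — U drops out of numerator and
   denominator — as exact `Fraction`s, so the ≥ 70% boundary is not subject
   to floating-point artifacts (7/10 eliminates, 2/3 retains). A B
   consensus and a T consensus both eliminate; with a threshold above 50%
   the two cannot hold simultaneously, so the test order B-then-T is
   immaterial. No analogous D-consensus rule exists: damaging-consensus
   variants are simply retained. Empty or all-U vectors retain.

### Variant identity and ingest

Variants are joined between VCF and annotation table, and compared across
samples, by a *normalized* key: multi-allelic records are split per alt
allele, common trailing bases are trimmed, then common leading bases are
trimmed while both alleles keep ≥ 1 base (anchor-base convention), with the
position advanced accordingly. Normalization is idempotent and preserves
the encoded substitution (property-tested by applying raw and normalized
keys to random reference contexts). Chromosome names are compared verbatim
by default; an opt-in switch strips a `chr` prefix on both sides, because
silent contig-name mismatches are a classic source of empty joins.

VCF alleles with no annotation row are *flagged* (`unannotated`, excluded at
the consequence stage) rather than dropped, so the ingest count always
equals the VCF allele count; annotation rows matching no VCF record are
logged and skipped; malformed frequencies abort with the row number.

### Exclusivity

The incidence matrix is boolean (gene × sample; ≥ 1 surviving variant in
that sample). The strict rule — true in all case columns, false in all
control columns — is implemented vector-free as an explicit scan, plus an
independent brute-force oracle with the same contract; the two are tested
equivalent on every boolean matrix up to 3 × 3 and on 1,000 random 10 × 6
matrices. Gene mode is the default (different qualifying variants in the
same gene across patients still count, which is how gene-level findings are
phrased); variant mode requires the identical normalized allele. Relaxed
thresholds (`min_case_fraction < 1`, `max_control_count > 0`) exist but are
off by default. Chronic-phase and healthy samples are pooled as controls.

### Coding-consequence engine

HGVS-style `c.` grammar supported: substitution, deletion, duplication,
insertion (two flanking positions), deletion-insertion. Coordinates are
1-based inclusive CDS positions; codon *i* spans 3i−2 … 3i. Intronic
offsets (`+`/`−`), UTR (`*`) positions and complex alleles raise an
explicit unsupported-notation error rather than a parse failure.

Several variants are applied **simultaneously against original
coordinates**: edits are sorted by start position and applied right to
left, so no edit shifts the coordinates of another. Overlapping variants
are rejected. Stated reference bases are validated against the CDS by
default (mismatch ⇒ error naming position, expected and found; a
`check_ref=False` / `--no-ref-check` escape hatch exists because annotation
and transcript versions drift). Translation uses the standard genetic code
(NCBI table 1), stops at the first stop codon, warns on a trailing partial
codon. The protein diff reports 1-based substitutions up to the shorter
length; a frameshift is flagged from the caller-supplied net CDS length
change (mod 3 ≠ 0) at the first differing residue.

No reference CDS is bundled for the worked ANKRD36 example. `build_cds`
reconstructs the minimal consistent context — codon 395 = GCT (Ala),
codon 396 = GTT (Val), filler codons elsewhere — which is the unique
assignment under which `c.1183_1184delGC` + `c.1187_1188dupTT` yield
Cys395 + Phe396 with no length change. The Abstract-style variant
`c.1187_1185dupTT` is an invalid inverted range and is rejected by the
parser; the package uses 1187_1188 throughout.

## Synthetic cohort generator

The generator emulates the **post-annotation** data regime the pipeline
consumes; all randomness flows from one `numpy` generator seeded from the
config, and generation is a pure function of the config (byte-identical
outputs for identical configs).

* **Cohort shape.** Default 2 AP + 3 BC cases (a five-exome discovery set)
  and 3 CP + 2 healthy controls. Any sizes are accepted with ≥ 1 case and
  ≥ 1 control when planting is requested.
* **Background variants.** Default 2,000/sample for tests; 90,000/sample
  reproduces exome scale. SNV:indel ≈ 0.90:0.10. Consequence terms are
  drawn from class-conditional spectra chosen to match a typical annotated
  exome (≈ 13% of SNVs synonymous, ≈ 13% missense, ~0.1% stop gained,
  ≈ 3% of indels frameshift, ≈ 2% each inframe), giving a
  consequence-stage retention of ≈ 12.7%.
* **Ts/Tv.** Each SNV is a transition with probability 2.3/3.3, so the
  expected Ts/Tv ratio is (2.3/3.3)/(1/3.3) = 2.3, the usual exome value.
* **Zygosity.** Heterozygous with probability 1.4/2.4 ⇒ expected het/hom
  ratio 1.4.
* **Population frequency.** Two-component mixture: with probability 0.97 a
  variant is "common" (uniform 0.006–0.5, present in both databases —
  matching the ~97% found-in-dbSNP typical of exomes); otherwise rare, and
  half of the rare variants are absent from every database (novel). Only
  the common/rare dichotomy matters to the filter, so no effort is made to
  match a realistic site-frequency spectrum.
* **Predictor labels.** Four predictors per variant, drawn i.i.d. from a
  latent state: neutral (prior 0.93) ⇒ B/T/D/U with probabilities
  .70/.20/.05/.05; damaging ⇒ .10/.10/.70/.10. Exact enumeration of the
  4-predictor outcome space gives a ≥ 70% B-or-T consensus probability of
  0.687 for neutral and 0.009 for damaging variants; combined with the
  retention fractions above, the expected full-scale funnel is
  90,000 → ≈ 11,400 → ≈ 343 → ≈ 123 survivors per sample, i.e. the
  ~124-rare-variants regime (accepted band 90–160, configurable).
* **Pseudo-reference.** Reference bases are a deterministic hash of
  (contig, position), so the same locus has the same reference allele in
  every sample without storing a genome; contigs are five 20-Mb dummies —
  enough for valid, sorted VCF, with no biological content.
* **Planted truth.** Driver genes get the same qualifying SNV (missense,
  absent from databases, D-consensus labels) in every case and no control.
  One decoy gene per class: (a) qualifying in all cases *and* one control,
  (b) qualifying in all but the first case, (c) exclusive but synonymous,
  (d) exclusive but at frequency 0.01, (e) exclusive but unanimously
  benign. Planted variants sit at reserved positions excluded from the
  background draw; driver/decoy gene symbols are disjoint from the
  background gene pool, so recovery is exact rather than probabilistic.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: linkage between variants, per-gene mutation-rate
heterogeneity, realistic allele-frequency spectra, annotation errors,
caller-specific artifacts (strand bias, low-complexity false positives),
multi-transcript consequence conflicts, and sample contamination or
relatedness. Recovery being exact on simulation says the *logic* is
correct, not that real discovery lists will be clean.

## Numerical and degenerate-input choices

* Consensus threshold comparison uses exact rationals; population-frequency
  comparison uses plain floats with a strict `>` (the threshold is a
  round decimal; no boundary ambiguity arises in practice).
* Undefined ratios (Ts/Tv with no transversions, het/hom with no
  homozygotes) are `None` in memory and `NA` in TSV — never 0 or ∞.
* Cohort percentages are half-up rounded to one decimal (`Decimal`
  arithmetic), matching clinical-table style (e.g. 18/141 → 12.8).
* Empty inputs: empty VCF ⇒ empty collection; empty cascade input ⇒ all-zero
  funnel; all-false incidence matrix ⇒ empty candidate report; the pipeline
  exits 0 with reports written even when the candidate set is empty.
* Exit codes: 2 for configuration errors, 3 for data errors.

## Problem sizes in the shipped tests

The default test suite runs the end-to-end recovery at 2,000 background
variants/sample and seed 42, 50 recovery seeds at 200 variants/sample, 100
cascade-property cohorts at 60 variants/sample, one full-scale (90,000
variants) funnel check, and the Ts/Tv calibration at 50,000 SNVs — sizes
chosen so the whole suite completes in well under a minute per concern
while keeping every planted-truth class exercised.

## Worked 4-sample fixture (`examples/trio/`)

Two cases (AP1, BC1), two controls (CP1, HC1), 18 variants; static files
are byte-identical to `generate_trio_fixture()` output. Expectations:

| sample | input | after consequence | after frequency | after consensus | survivors |
|--------|------:|------:|------:|------:|-----------|
| AP1 | 7 | 5 | 4 | 3 | TRIOA, TRIOE, TRIOF |
| BC1 | 6 | 5 | 4 | 3 | TRIOA, TRIOE, TRIOH |
| CP1 | 3 | 2 | 1 | 1 | TRIOE |
| HC1 | 2 | 1 | 1 | 0 | — |

Gene roles: TRIOA — driver (reported candidate); TRIOB — synonymous decoy;
TRIOC — common decoy (dbSNP 0.02); TRIOD — benign-consensus decoy;
TRIOE — control-hit decoy (also in CP1); TRIOF — case-incomplete decoy
(AP1 only); TRIOG/TRIOI/TRIOJ/TRIOK/TRIOL/TRIOH — background. Candidate
report: **TRIOA** only.

## Known limitations

* The annotation ingest trusts the provided consequence terms; it performs
  no re-annotation and no transcript selection.
* The HGVS subset excludes intronic/UTR positions, inversions and alleles
  in brackets; genomic→CDS projection is out of scope.
* Exclusivity is presence/absence only; it does not model zygosity,
  somatic vs germline status, or sequencing depth at wild-type sites (a
  gene can look "absent in controls" simply because the site was not
  callable there — upstream QC must guarantee callability).
* `cohort_fraction` and the QC table are descriptive; no inferential
  statistics are provided by design.
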