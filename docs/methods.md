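# Methods

This note records the models, conventions and numerical choices behind
`strseek`, and what the synthetic-data generators do and do not emulate.

## Coordinates, motifs and the catalogue filters

All internal coordinates are 0-based half-open. RepeatMasker `.out` rows are
1-based inclusive and converted at the parsing boundary; strand `C`
(complement) maps to `-`; motifs are uppercased and restricted to ACGT
(rows with ambiguity codes are skipped with a warning rather than rejected,
since they occur sporadically in real annotations).

The exclusion filters run in a fixed order: period-1 (mono-nucleotide)
repeats first — capillary fragment analysis cannot resolve 1 bp allele
differences — then the divergence rule. "Over 5%" is read as *strictly
greater than 5* on **any** of the three divergence fields (substitutions,
deletions, insertions); a `sum` mode (total divergence > 5) is provided
because the phrasing is ambiguous in the source material for this kind of
filter, and the `any` reading is the default. The boundary value 5.0 is
kept. `FilterReport` enforces that kept + excluded partitions the input.

Motif GC percent is computed on the repeat unit, not the genomic span: the
unit is what characterises the repeat family, and the span's composition is
just the unit's up to edge effects.

## Motif equivalence and cross-matching

Two motifs name the same repeat if one is the other, its reverse, or its
reverse complement (`basic` mode — an annotation and a caller may read the
same repeat from opposite strands or directions). An `extended` mode closes
the set under complementation and all cyclic rotations (the canonical
repeat-family closure); it is not the default because plain
reverse/reverse-complement matching is the narrower, more conservative rule.

A catalogue locus matches a call when they share a chromosome, overlap by
≥ 1 bp (configurable), and their equivalence sets intersect. When several
calls match, attributes transfer from the call with the largest overlap,
ties broken by smaller call start — invented plumbing chosen purely for
determinism. Matching uses per-chromosome interval trees and is verified
against an all-pairs scan in the tests.

## Expression

The read filter keeps a SAM record iff the proper-pair bit (0x2) is set,
the secondary (0x100), duplicate (0x400) and supplementary/chimeric (0x800)
bits are clear, and the read maps uniquely. Uniqueness uses the NH-style
alignment count when present regardless of the originating tag name (HI and
NH are both seen in the wild for hit bookkeeping); the secondary bit is
excluded as well because hit-count-based deduplication is incoherent
without it.

Alleles supported by fewer than 10 reads are dropped (boundary kept;
idempotent). "FPKM" for an STR locus is defined as
`reads × 10⁹ / (locus_length_bp × total_mapped_reads)` — the closest
standard reading of normalising STR reads against library size with a
length term — with an `rpm` scheme (`reads × 10⁶ / total_mapped`) as the
length-free alternative; the two differ exactly by the locus length in kb.
Allele labels (repeat counts or bp offsets) are carried through opaquely;
an offset→repeat-count converter is provided for when the reference allele
is known.

qPCR: ΔΔCt fold change is `2^−[(target−hk)_treated − (target−hk)_control]`
and requires exactly one housekeeping gene; the 2^−ΔCt quantity normalises
against the geometric mean of any number of housekeepers and reduces to
plain ΔCt for one.

## Feature classification

Precedence is CDS > 5′UTR > 3′UTR > intron > promoter > intergenic:
most-specific-feature-wins, coding before regulatory. A locus takes the
highest-precedence class attained *anywhere* in its overlap with any
transcript (not at its midpoint), so a CDS-touching STR counts as CDS. The
promoter is the strand-aware 2 kb window upstream of the TSS (configurable)
and applies only when no transcript overlaps the locus. Exons of non-coding
transcripts have no CDS to polarise a UTR call; they are classed by a
configurable label defaulting to 3′UTR (a lncRNA exon is functionally
untranslated sequence), with `intron`/`UTR5` as alternatives. The indexed
classifier is verified against a per-base brute-force oracle, and a
strand-mirror symmetry property guards the 5′/3′ logic.

## Prioritisation metric

For each STR over paired samples:
`score = (Σ_pairs fold change) × n_expressed`, with fold change
`tumor / adjacent` per pair. A pair with both values zero neither
contributes a term nor counts as expressing; a single zero gets a
pseudocount ε = 0.01 (FPKM scale, configurable) so ratios stay finite.
The raw ratio is the default because that is the plain reading of
"tumor ÷ non-cancer"; a log2 mode is offered since raw ratios compress
under-expression into (0, 1) and "lowest score" then conflates weak
expression with down-regulation. "Expressed" means non-zero in either
member of the pair (a tumor-only variant is available by flag).
Candidate selection takes the k largest and k smallest scores with
lexicographic id tie-breaking for determinism.

## Association statistics

Tabulation works on unordered allele pairs; each homozygote contributes two
copies of its allele, each heterozygote one per constituent, so allele
totals are exactly 2N. Display rounding is half-up, matching published
table style. On the shipped TG-PCA3 case-control table the crude
cross-product odds ratios vs 11/11 are 0.7928 (11/12) and 0.6023 (12/12);
the corresponding published regression values are 0.80 and 0.61 — within
2%, a discrepancy consistent with fitting-procedure differences and left
as is rather than calibrated away. Rare genotypes (outside 11/11, 11/12,
12/12) are excluded before regression; tabulation keeps all genotypes.

- **Crude OR**: cross-product with Wald 95% CI; any zero cell triggers the
  Haldane–Anscombe +0.5 correction (flagged), a fully zero margin is an
  error.
- **Logistic regression**: maximum likelihood via statsmodels (Newton/IRLS,
  tol 1e−8, ≤ 50 iterations); OR = exp(coef), Wald CI and p per term, the
  intercept reported last. The unadjusted single-predictor fit reproduces
  the cross-product OR to 1e−6 (saturated-model identity, enforced in
  tests). Non-convergence and separation raise naming the terms.
- **Allelic analysis** is offered in per-allele (two observations per
  subject) and carrier (dominant) codings; neither is privileged, because
  a published allelic OR is generally not recoverable from printed counts
  without knowing the coding.
- **HWE**: chi-square of observed genotype counts against p², 2pq, q²
  expectations from observed allele frequencies over all constructible
  genotypes; classes with expected < 5 are pooled into one (flagged);
  df = #classes − #alleles, clamped to ≥ 1 after pooling; Wald-style
  simplicity over exact tests by design.
- **Bootstrap**: resampling with replacement stratified within case and
  control arms; percentile 2.5/97.5 CI; two-tailed
  p = 2·min(frac ≤ 0, frac ≥ 0) of the resampled statistic (log-OR scale by
  default), floored at 2/n_resamples. Resamples on which the statistic is
  undefined (empty cell) are redrawn and counted. For the default genotype
  log-OR the stratified resampling is executed as multinomial draws over
  (exposed, reference, other) category counts — an exact, vectorised
  equivalent of per-subject resampling. `n_resamples` (default 1,000) and
  the seed are explicit parameters; results are bit-reproducible per seed.
- **Survival**: Kaplan–Meier product-limit curves and the log-rank
  (Mantel-Cox) chi-square via lifelines; the two-group hazard ratio is
  (O₁/E₁)/(O₂/E₂) with expected counts accumulated over distinct event
  times from at-risk proportions (computed in-package; lifelines does not
  expose O/E). The log-rank chi-square is pinned in tests to a hand-worked
  four-event example (O_A = 2, E_A = 4/3, V = 13/18 ⇒ χ² = 8/13). No
  events at all, or an empty group, is an error. The HR is undefined
  (reported as None) when a group has zero observed or expected events.
- **KS**: scipy's asymptotic two-sample Kolmogorov–Smirnov, checked against
  a brute-force ECDF sweep.

Gleason scores dichotomise at 8: < 8 less aggressive, ≥ 8 aggressive.

## Synthetic data: what it emulates, and what it does not

Every generator is a pure function of (config, seed); identical seeds give
byte-identical outputs.

- **Catalogue** (`gen_catalog`): RepeatMasker-dialect text whose
  Simple_repeat rows have known class/period/divergence truth. Defaults:
  60% simple repeats among annotation rows; period mix dominated by
  dinucleotides with 6.5% mono-repeats; per-field divergences exponential
  with scale 2.8% — chosen so that ~58% of non-mono loci survive the joint
  5% rule, the survivorship regime the filter is designed around.
  Divergences are generated at the 1-decimal precision the format prints,
  so parse→generate round-trips are exact.
- **Call set** (`gen_callset`): each locus detected independently with
  probability 0.75; detections are coordinate-jittered within overlap,
  motif-swapped to a reverse/reverse-complement equivalent half the time
  (exercising the equivalence logic), and flagged polymorphic with
  probability 0.99. The 75%/99% defaults are the detection and
  polymorphism rates the cross-reference stage is expected to reproduce.
- **Expression study** (`gen_expression_study`): 8 tumor/adjacent pairs;
  null STRs draw both sides i.i.d. log-normal around 5 FPKM with σ = 0.5
  (natural log, ≈ 1.6-fold one-sigma spread — a realistic biological
  variation for repeated measures of one locus across tissue pairs);
  planted-up STRs have the tumor side multiplied 8-fold, planted-down the
  adjacent side; optional sparsity zeroes values at random. 4 up + 4 down
  among 200 nulls is the default recovery problem.
- **Cohort** (`gen_cohort`): 1,153 cases / 1,210 controls; genotypes drawn
  under Hardy–Weinberg within each arm from the arm-specific allele
  frequencies (the shipped table's: allele 11 at 76% in cases, 71% in
  controls); ages normal (63.1 / 61.8, σ = 8); Gleason ≥ 8 odds scale with
  the number of 11-repeat copies (OR 2 per copy by default); survival is
  exponential with genotype-dependent hazards (12/12 at one third of the
  baseline 8 × 10⁻⁴/month), censored at 120 months, with a fraction of
  deaths flagged disease-specific. An optional per-genotype odds-ratio
  tilt replaces the case-arm frequencies for calibration studies (planted
  OR cohorts).

Limitations worth keeping in mind: an arm generated under HWE is an
idealisation (a case arm ascertained on genotype is not exactly HWE);
expression noise is i.i.d. log-normal with no sample-level or locus-level
covariance; survival has no competing risks or age dependence; there is no
linkage structure around the STR; and the synthetic RepeatMasker text uses
a small motif pool per period. Passing the recovery and calibration tests
therefore demonstrates correctness of the *methods* under their stated
models, not performance on real sequencing data.

## Problem sizes

The test suite and the acceptance script run everything at desk scale, as a
deliberate design choice: catalogues of 10³–2.7 × 10⁴ loci, 10³ × 10³
cross-match oracle comparisons, 100-seed recovery and CI-coverage studies,
and 200-seed × 1,000-resample bootstrap calibration. The full-genome
catalogue check lives in `examples/full_scale_hg19.py` and needs a network
download; it is the only stage whose published tallies (413,414 records;
223,742 survivors) require the full-scale input.
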