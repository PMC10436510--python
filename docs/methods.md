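# Methods

## The screening model

`p450screen` implements a candidate-gene, case-control screen for rare
variants in the 60-gene human cytochrome P450 panel (the 57 *CYP*
genes plus the redox partners *POR*, *Adx* and *AdR*). Each variant is
tested independently for differential carrier frequency between two
cohorts of a Parkinson's-disease study design: genetically predisposed
patients (GPD, n = 317), genetically predisposed unaffected
individuals (GUN, n = 344) and healthy controls (HC, n = 193), in the
ordered comparisons GPD/HC, GUN/HC and GPD/GUN.

For a variant and an ordered cohort pair, subjects collapse to a
binary carrier state under one of three modes — heterozygotes only,
homozygous-alternate only, or any carrier — giving the 2×2 table
(a, b; c, d) with *a*/*b* the numerator cohort's subjects with/without
the variant and *c*/*d* the same for the denominator cohort. Subjects
with a missing genotype at that variant are excluded from both counts,
so per-variant denominators fluctuate below the nominal cohort sizes.
The statistics are

- OR = (a·d)/(b·c),
- SE = √(1/a + 1/b + 1/c + 1/d),
- 95% CI = exp(ln OR ± z·SE) with z = Φ⁻¹(0.975) ≈ 1.959964,
- p = 2·(1 − Φ(|ln OR|/SE)), two-sided.

For a single binary predictor this closed-form Wald statistic is
algebraically identical to an unadjusted logistic regression, which is
how such screens are conventionally reported; we use the closed form
rather than an iterative fit because it is exact, fast, and
third-decimal-reproducible. The test suite cross-checks it against
statsmodels' independent `Table2x2` implementation over all small
tables. p-values are raw: the screen is exploratory and deliberately
applies no multiple-testing adjustment (a Benjamini–Hochberg column
can be emitted downstream but never filters).

### Zero cells

A table with a zero cell has an infinite or zero OR estimate and an
undefined Wald SE. The default policy flags such results undefined and
excludes them from banding; the Haldane–Anscombe +0.5 correction is
available behind a flag (`zero_cell_policy: haldane`) for users who
prefer finite estimates. The default was chosen because every
strongly associated variant in the reference screen has all cells
positive, so the correction never affects the headline numbers.

## Band stratification and gene categories

Significant odds ratios (p < α, default α = 0.05) are stratified into
five bands: OR < 0.2, 0.2–0.5, 0.5 < OR < 2, 2–5 and OR > 5. The five
bands partition (0, ∞); the shared boundaries 0.2, 0.5, 2.0 and 5.0
are assigned to the closed outer bands (0.2–0.5 and 2.0–5.0) and the
central band is open. No reference odds ratio falls exactly on a
boundary, so the choice is unfalsifiable, but it must be fixed and
this reading follows the closed-interval notation of the source
tables. Per-gene band counts feed a set of deliberately non-exclusive
strength-of-association categories (no effect, marginal, 2–5 with or
without >5, >5, <0.2, >5-without-<0.2, <0.2-without->5, >10); the >10
category requires the maximum significant OR, which the gene summary
carries alongside the counts.

Concordance between two comparisons (typically GPD/GUN and GPD/HC)
takes the variant identity as (variant id, collapse mode) — the
het-only and hom-only collapses of one rsID are distinct tests — and
keeps variants significant in both with odds ratios strictly on the
same side of 1.

## Inverse reconstruction of carrier tables

Published screens print OR, CI and p but not counts. Because the
cohort sizes are known, carrier counts are small, and the Wald
statistics are smooth in the four integers, the generating table is
usually *uniquely* recoverable: enumerate a and c up to a carrier
bound (default 60), allow up to `max_missing` (default 2) dropped
genotypes per cohort, recompute OR/CI/p forward, and keep tables whose
values — rounded half-up at the printed precision (3 decimals, the
convention of SPSS-style report tables) — reproduce the printed row.
Soundness is by construction (every solution forward-checks); the
oracle reports whether the exact solution is unique. Rows with no
exact solution return ranked best-residual candidates instead of
failing: such rows can arise from extra missing genotypes, a different
genotype coding, or different rounding internals in the original
analysis, and the oracle reports rather than adjudicates. In the
packaged reference table three statistic patterns resist exact
reconstruction (residuals 0.04–0.67 at the third decimal); their best
candidates still land in the published neighbourhood (OR > 5,
p < 0.05), so gene-level aggregates are unaffected.

One reference row is printed with the cohorts inverted (GUN/GPD). The
default table reconstruction (`fold_to_gpd_gun=True`) solves it in
GPD/GUN orientation because the published gene-level summary counts
that variant in the GPD/GUN OR > 5 band; without folding, the
gene-level aggregate would contradict the summary's own count of 10
genes. The fold is opt-out and the packaged TSV preserves the printed
label.

## Supplement intake

Fish-oil and vitamin-D intake between GUN and GPD is compared with the
Pearson chi-square test on the 2×2 intake table, one degree of
freedom, two-sided, without the Yates continuity correction. The
uncorrected variant is the one that reproduces both reference
p-values (0.056 and 0.087) from the printed counts; the corrected
variant reproduces neither, which pins down the implementation.
Proportions are reported as 100·x/n rounded half-up to one decimal.

## The synthetic cohort generator

The generator emulates the structure of the emulated study's
whole-genome-sequencing arm: the three cohort sizes above; rare
variants with per-cohort carrier counts of order 1–20; heterozygous or
homozygous carrier states (`hom_fraction`, rounded to the nearest
whole carrier); missing genotype calls; and binary supplement
covariates. Carriers are drawn per subject (`carrier_prob`) or forced
to exact per-cohort counts (`fixed_counts`), which makes downstream
tables exactly reproducible. Missingness is applied after carrier
assignment, independently per call (`missing_rate`); `fixed_missing`
additionally forces an exact number of missing calls among
non-carriers, reproducing the per-variant denominator fluctuation
(316 vs 317 typed subjects) visible in reconstructed reference rows.
Sample ids are cohort-prefixed (`GPD_0001`), for auditability.

Supplement defaults are the reference intake counts for GPD (49 fish
oil, 105 vitamin D of 317) and GUN (73 and 136 of 344) drawn as exact
subsets, and rates of 0.18/0.36 for HC, for which no reference
proportions exist; intake is independent of genotype (the screen
models no such linkage). Enrolment age is drawn normal with means
58.2 (GPD) / 57.6 (GUN) years and a common SD of 8 years — a typical
spread for PD study cohorts; age enters no statistic in this package.

What the generator does **not** model: linkage disequilibrium,
phasing, population structure, per-site sequencing error, genotype
uncertainty, or covariate–genotype correlation. Tests passing on
synthetic cohorts therefore validate the *counting and statistics*,
not robustness to real-data artefacts such as batch effects or
differential missingness between cohorts.

### Monte-Carlo calibration of the estimator

With carrier probabilities 0.2 (GPD) vs 0.02 (GUN) the population
odds ratio is (0.2/0.8)/(0.02/0.98) = 12.25. Across 500 replicate
cohorts the *geometric* mean of the per-replicate OR estimates
recovers this within 15% (observed ≈ 13.6, i.e. ≈ +11%, the expected
finite-sample bias of E[ln OR] with ~7 expected denominator carriers).
The geometric mean is the appropriate location summary for an OR —
the estimator is log-normal and the Wald machinery operates on ln OR
throughout. The arithmetic mean is *not* a consistent summary here:
it inherits the heavy right tail of the ratio statistic
(E[1/c] > 1/E[c]) and overshoots the population value by ≈ 30% at
these frequencies, which is a property of the estimator, not an
implementation defect. Replicates with a zero cell (≈ 0.1%) are
undefined and excluded.

## Numerical choices

- z is the double-precision normal quantile (1.95996398…), not 1.96;
  the difference is visible in the third decimal of wide CIs.
- Reported OR/CI/p are rounded half-up at 3 decimals (ties away from
  zero), matching report-table conventions; all internal computation
  is full precision, and the reciprocal-symmetry invariant
  OR(A/B)·OR(B/A) = 1 holds exactly in rational arithmetic before
  rounding.
- The two-sided normal tail is computed as erfc(x/√2) for speed and
  accuracy in the reconstruction search's inner loop.
- The reconstruction search bound of 60 carriers per cohort provably
  covers the packaged reference rows (all reconstructed counts ≤ 19)
  and keeps a full search under half a second; it is a parameter, not
  a constant, for screens of commoner variants.

## Problem sizes

The demo study realises the 16 reconstructed reference variants in a
full-size cohort (854 subjects); a pipeline run on it takes ~3 s. The
Monte-Carlo calibration uses 500 replicate single-variant cohorts
(~15 s). The reconstruction oracle searches ~3×10⁵ tables per row
(~0.4 s).

## Known limitations

- The screen is per-variant and marginal: no covariate adjustment, no
  allelic/trend tests, no Fisher exact test, no haplotype or
  variant-combination analysis.
- Annotation (SnpEff-style ANN impact) is consumed as metadata only
  and never computed or used to gate statistics.
- The reconstruction oracle assumes the printed values came from the
  same Wald closed form at half-up rounding; rows produced by a
  different pipeline internals can only be bracketed, not recovered.
- Real panel genomic coordinates are not shipped; the demo panel
  places genes at synthetic coordinates, which is irrelevant to the
  statistics but means the demo VCF cannot be intersected with real
  annotation tracks.
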