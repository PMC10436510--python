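# p450screen

Per-variant case-control screening, gene-level stratification, and
inverse reconstruction of carrier tables for the human cytochrome
P450 gene panel.

## The scientific problem

Cytochrome P450 enzymes metabolise drugs, fatty acids, eicosanoids,
vitamins and sterols, and several have been implicated in Parkinson's
disease through neurotoxin activation and neuroprotectant synthesis.
`p450screen` implements the statistics of a candidate-gene screen
over the 60-gene panel (57 *CYP* genes plus the redox partners *POR*,
*Adx*, *AdR*) in a three-cohort design: genetically predisposed
patients (**GPD**, n = 317), genetically predisposed unaffected
individuals (**GUN**, n = 344), and healthy controls (**HC**,
n = 193), compared pairwise as GPD/HC, GUN/HC and GPD/GUN.

For each variant and ordered cohort pair, subjects collapse to a
binary carrier state (heterozygous-only, homozygous-only, or any
carrier; missing genotypes excluded), giving a 2×2 table
(a, b; c, d). The association statistics are

```
OR  = (a·d) / (b·c)
SE  = sqrt(1/a + 1/b + 1/c + 1/d)
CI  = exp(ln OR ± z·SE),  z = Φ⁻¹(0.975)
p   = 2·(1 − Φ(|ln OR| / SE))
```

— the closed-form Wald statistics, identical to a single-predictor
logistic regression. Significant odds ratios are stratified into
bands (<0.2, 0.2–0.5, 0.5–2, 2–5, >5), aggregated per gene into
strength-of-association categories, and checked for concordance
across comparisons.

The package also solves the *inverse* problem: published screens
print OR, CI and p but not the underlying counts. Because cohort
sizes are known and carrier counts are small, an exhaustive search
over candidate tables usually recovers the generating 2×2 table
**uniquely** from the printed three-decimal values. This makes
published association rows machine-checkable end to end.

Finally, a synthetic cohort generator emits realistic multi-sample
VCFs (rare variants, het/hom carrier states, missing calls,
supplement covariates) with deterministic seeding, so the entire
pipeline — generate → write VCF → read → screen → stratify — is
testable without access to restricted cohort data. See
[docs/methods.md](docs/methods.md) for the full methods note.

## Worked example

Reconstruct a carrier table from printed statistics:

```bash
$ p450screen reconstruct --or 10.023 --ci-low 1.263 --ci-high 79.564 --p 0.029
a   b    c  d    OR      CI_low  CI_high  p      residual  exact
9   308  1  343  10.023  1.263   79.564   0.029  0.0       True
```

The search proves this table is the *unique* integer solution: 9 of
317 GPD subjects carry the variant versus 1 of 344 GUN subjects.

Generate the demo study (the 16 reference variants realised as a
full-size synthetic cohort of 854 subjects) and screen it:

```bash
$ p450screen simulate --demo --seed 1 --out-dir demo
wrote 16 variants x 854 subjects to demo

$ p450screen screen --vcf demo/cohort.vcf --bed demo/panel.bed \
    --subjects demo/subjects.tsv --out-dir demo/report
concordant: demo/report/concordant.tsv
gene_categories: demo/report/gene_categories.tsv
gene_summary: demo/report/gene_summary.tsv
manifest: demo/report/manifest.json
results: demo/report/results.tsv
results_json: demo/report/results.json
supplements: demo/report/supplements.tsv

$ head -4 demo/report/results.tsv
variant_id   gene    comparison  mode      a  b    c  d    OR      CI_low  CI_high  p      defined
rs138504382  CYP4V2  GPD/HC      het_only  9  308  0  193                                  False
rs138504382  CYP4V2  GUN/HC      het_only  1  343  0  193                                  False
rs138504382  CYP4V2  GPD/GUN     het_only  9  308  1  343  10.023  1.263   79.564   0.029  True
```

(The HC comparisons have a zero cell — no control carries the
variant — so under the default policy they are flagged undefined
rather than Haldane-corrected.)

The gene summary shows exactly 10 genes with a GPD/GUN variant in the
OR > 5 band, with *CYP7B1* contributing five:

```bash
$ awk -F'\t' '$3=="GPD/GUN" && $9>=1' demo/report/gene_summary.tsv
CYP4V2   FattyAcids   GPD/GUN  1  0  0  0  0  1  1
CYP4F3   Eicosanoids  GPD/GUN  1  0  0  0  0  1  1
CYP4F8   Eicosanoids  GPD/GUN  1  0  0  0  0  1  1
CYP8A1   Eicosanoids  GPD/GUN  1  0  0  0  0  1  1
CYP24A1  Vitamins     GPD/GUN  1  0  0  0  0  1  1
CYP26B1  Vitamins     GPD/GUN  1  0  0  0  0  1  1
CYP27C1  Vitamins     GPD/GUN  1  0  0  0  0  1  1
CYP7B1   Sterols      GPD/GUN  5  0  0  0  0  5  5
CYP39A1  Sterols      GPD/GUN  2  0  0  0  0  2  2
CYP20A1  Unknown      GPD/GUN  2  0  0  0  0  2  2
```

and the supplement report reproduces the reference intake comparison
with the uncorrected Pearson chi-square:

```bash
$ cat demo/report/supplements.tsv
covariate  cohort_1  x1   n1   pct1  cohort_2  x2   n2   pct2  chi2   p
fish_oil   GUN       73   344  21.2  GPD       49   317  15.5  3.641  0.056
vitamin_d  GUN       136  344  39.5  GPD       105  317  33.1  2.928  0.087
```

The same is available from Python:

```python
from p450screen.association import CarrierTable, odds_ratio, wald_interval

table = CarrierTable(9, 308, 1, 343)
lo, hi, p = wald_interval(table)
print(odds_ratio(table), lo, hi, p)
# 10.022727... 1.2629... 79.5642... 0.02862...
```

## Package layout

| Module | Purpose |
| --- | --- |
| `p450screen.association` | 2×2 carrier tables, OR / Wald CI / p, multi-comparison screen |
| `p450screen.variant_io` | cyvcf2-based VCF ingestion, BED gene panel, genotype collapse codes |
| `p450screen.synthetic` | deterministic synthetic cohort generator and VCF/TSV writers |
| `p450screen.strata` | OR bands, gene summaries, category classification, concordance |
| `p450screen.reconstruction` | exhaustive inverse search from printed statistics to counts |
| `p450screen.supplements` | intake proportions and uncorrected Pearson chi-square |
| `p450screen.reference` | packaged reference tables, demo panel and demo study config |
| `p450screen.pipeline` / `p450screen.cli` | orchestration and the `p450screen` command |
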