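# famcc

Combined family-trio and case-control genetic association testing with
independent conditional-power screening and a top-K multiple-testing
reduction.

Many association cohorts contain both unrelated cases/controls and
parent-offspring trios. `famcc` implements a two-step strategy for using
both: each subset is first *screened* with information that is statistically
independent of its association test — predicted (conditional) power from
parental genotypes and offspring phenotypes on the family side, a
contingency-table partition with null-imputed testing cells on the
case-control side — the two screening rankings are aggregated by mean log
rank (order-equivalent to the rank product), and only the top K aggregate
SNPs are tested, combining the two subsets' independent p-values with
Fisher's method at the reduced per-test level `alpha / K`.

## What's inside

| module | contents |
| --- | --- |
| `famcc.core_data` | PED/MAP I/O, pedigree/genotype data model, trio assembly, Mendelian-error and marker QC filters |
| `famcc.population_tests` | Cochran-Armitage trend test, stratum-combined (CMH-style) trend, per-SNP scans |
| `famcc.family_tests` | Mendelian transmission model, offset-weighted trio transmission test (offset = trait prevalence, default 0.3) |
| `famcc.screening` | conditional-power screen (never reads offspring genotypes), contingency-split screen/test (default testing fractions 0.75/0.50/0.25 for minor-hom/het/major-hom) |
| `famcc.combination` | Fisher's combined probability, sample-size-weighted-Z meta-analysis, log-rank aggregation, top-K decision |
| `famcc.simulate` | trio + case-control cohort simulator (HWE parents, Mendelian transmission, logistic disease model, optional two-subpopulation confounding) |
| `famcc.pipeline` / `famcc.cli` | end-to-end orchestration and the `famcc` command |

## CLI

Simulate a cohort and analyse it:

```bash
famcc simulate --n-snps 2000 --n-trios 300 --n-cases 400 --n-controls 400 \
    --causal "0:2.0:0.3" --seed 42 --out scratch/demo

famcc run --ped scratch/demo.ped --map scratch/demo.map \
    --pheno scratch/demo.cov.tsv \
    --offset 0.3 --top-k 10 --alpha 0.05 --seed 42 --out scratch/results
```

`famcc run` writes per-strategy TSVs (`singletons_only.tsv`, `pooled.tsv`,
`fbat.tsv`, `fisher_all.tsv`, `weighted_z.tsv`, `two_step.tsv`), QC reports,
a `manifest.json` with config/seed/versions, and a log. Identical
config + seed produces byte-identical outputs. Each result file's header
records the SNP count and the Bonferroni/suggestive thresholds used.

`famcc simulate` also accepts `--config file` with flat `key = value` lines
mirroring the option names.

## Statistical notes

- Trend-test variance uses the `N^2` (binomial) denominator by default; the
  hypergeometric `N/(N-1)` correction is available via `variance=`.
- The family screen receives parental genotypes and offspring phenotypes
  only — by interface, not just by convention — so the transmission test on
  offspring genotypes is exactly orthogonal to the screening ranks.
- The case-control screen samples the testing table by genotype class
  ignoring phenotype and imputes testing cells under the null with
  margin-exact sequential hypergeometric draws.
- The final Fisher combination pairs the full-trio transmission p with the
  testing-table-only trend p; using the full-sample trend p would break the
  independence the reduced penalty relies on.
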