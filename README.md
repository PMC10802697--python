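# cnvburden

Rare copy-number-variant (CNV) burden analysis for array-based
case/control studies, built for cohorts like the Scandinavian
obsessive-compulsive disorder (OCD) case/control samples it was designed
around: two CNV callers per sample, pronounced genotyping-batch structure,
country substructure on the principal components, and heavily
sex-imbalanced control collections.

The package implements the full analysis chain:

1. **Consensus calling contract** — per-sample intersection of two
   PennCNV-style callsets, with probe counts recomputed from the array
   manifest.
2. **Sample QC** — per-dataset 3-SD outlier pruning on LRR standard
   deviation, absolute waviness factor and BAF drift, hard caps
   (LRRSD ≤ 0.2, absWF ≤ 0.02, BAF drift ≤ 0.001), and removal of samples
   with > 20 raw calls or > 20 Mb of raw call footprint.
3. **Call filter cascade** — size (≥ 15 probes, ≥ 30 kb), telomere /
   centromere / polyN / segmental-duplication / repeat masks (> 30%
   coverage), any-overlap removal at TCR/immunoglobulin and
   lymphoblastoid-artifact loci, < 1% frequency internally (combined and
   per input dataset) and against an external reference, marker-level
   B-allele-frequency validation of each call against its reported copy
   state, and an iterative screen that excises small-deletion loci bearing
   a single-dataset batch signature when they inflate the permutation
   genomic-inflation factor. Every filter writes an audit flag; filters
   are computed on the full consensus callset so flag assignment is
   order-independent.
4. **Global burden models** — statsmodels-style `CnvBurdenModel` /
   `CnvBurdenResults`: logistic regression of case status on covariates
   plus a burden metric (odds ratio per metric unit), or OLS of the metric
   on covariates plus case status (excess per case), with data-driven
   covariate screening (a candidate PC or LRRSD joins PC1–PC5 + sex when
   associated with both raw call count and case status), Wald intervals,
   separation detection, and leave-one-out refits by dataset and by
   covariate. Metrics cover counts, genomic extent, gene counts, pLI and
   neurodevelopmental gene-set partitions, size and frequency partitions,
   and constrained-base content.
5. **Locus association** — gene- and probe-based units clumped by the
   "> 50% of overlapping CNVs shared" rule, an exact stratified
   Cochran–Mantel–Haenszel test over the four (country, sex) strata
   (convolution of central hypergeometrics, two-sided by the
   minimum-likelihood rule), Benjamini–Hochberg FDR, a permutation
   estimate of the genomic inflation factor, and a label-permutation test
   for deletion recurrence in cases.
6. **Carrier analyses** — deterministic carrier flags (high-pLI deletion,
   neurodevelopmental deletion/duplication), polygenic-score association
   in carriers, comorbidity contingency tests, treatment-response t-test
   on percent YBOCS improvement, and the case-only single-gene CNV set
   with exact Poisson enrichment against external exome summary counts.
7. **Synthetic data** — a first-class generator
   (`SimConfig` / `simulate_study`) producing cohorts, annotations,
   marker-level signal and two-caller callsets with *planted* effects
   (burden odds ratios, excess rates, common CNVs, batch artifacts,
   diploid-BAF false calls, clinical shifts), so every stage is testable
   against ground truth. See `docs/methods.md` for what the generator does
   and does not emulate.

## Worked example

Simulate the default full-scale study (2,248 cases / 3,608 controls, four
phenotype-pure batches, planted deletion burden in loss-of-function
intolerant genes, a 0.07 excess call rate per case, a 19-call / 3-locus
batch artifact, and planted clinical effects), then run the whole pipeline:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

prints (abridged):

```
cohort: 2203 cases / 3526 controls after QC (127 removed)
calls: 7455 consensus, 3018 analysis-ready (0.53 per sample); 3 batch-effect
  loci excluded, band inflation 1.72 -> 1.04
covariates: PC1, PC2, PC3, PC4, PC5, SEX, LRRSD
burden cnv_count: OR=1.158 CI=(1.075,1.248) P=1.15e-04
burden del_count: OR=1.232 CI=(1.105,1.372) P=1.62e-04
excess rate: 0.080 per case CI=(0.040,0.120) P=9.34e-05
gene-based tests: 1438 units, 0 at FDR<0.05, inflation factor 1.21
PRS vs deleterious deletions: estimate=-0.420 P=1.62e-25 (699 carriers)
ASD vs NDD duplications: chi2=248.1 P=6.75e-56
treatment response: carriers 16% vs non-carriers 47% improvement, t=-8.14
```

Reading the output: the QC-pass call rate (0.53/sample) lands in the
regime a stringent rare-CNV cascade produces from a ~1.3 raw calls/sample
input; the batch-artifact screen finds exactly the three planted loci and
restores a controlled inflation factor (1.72 → 1.04); the global burden
odds ratio and the covariate-adjusted excess rate recover the planted
signal (true excess 0.07/case); no single locus reaches FDR significance
at this cohort size even though the burden is real — the gene-based
inflation factor above 1 here reflects that genuine polygenic signal, not
batch structure; and the carrier-level analyses recover the planted
polygenic-score shift (−0.45 SD planted) and the planted treatment-response
gap (16% vs 47% mean YBOCS improvement).

The same stages are scriptable via the `cnvburden` CLI
(`simulate`, `sample-qc`, `filter`, `burden`, `assoc`, `downstream`) on
tab-separated files, or directly from Python:

```python
import cnvburden as cb

study = cb.simulate_study(cb.SimConfig.toy(600, 600), seed=7)
consensus = cb.intersect_callsets(study.calls_a, study.calls_b, study.probe_map)
kept, report = cb.run_sample_qc(study.samples, consensus)
keep = set(kept["sample_id"])
res = cb.run_filter_cascade(
    [c for c in study.calls_a if c.sample_id in keep],
    [c for c in study.calls_b if c.sample_id in keep],
    kept, study.probe_map, study.annotation.masks, study.annotation.freq_ref)
metrics = cb.compute_burden_metrics(res["survivors"], kept,
                                    study.annotation.genes,
                                    study.annotation.constraint,
                                    res["clusters"])
print(cb.logistic_burden_test(metrics["cnv_count"], kept).summary())
```

## What `scripts/acceptance.py` does

It regenerates the default synthetic study from `--seed`, runs every
pipeline stage (QC, consensus, filter cascade with the inflation screen,
covariate screening, global burden models, clumped exact locus tests with
FDR and the permutation inflation factor, recurrence permutation test, and
the carrier-level clinical analyses), prints a one-line summary per stage,
and writes the JSON report to `--out`.
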