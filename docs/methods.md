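# Methods

This note documents the models and procedures `cnvburden` implements, the
numerical and design choices made where the design was genuinely open, and
what the synthetic-data generator does and does not establish.

## Coordinates, calls and scope

All internal arithmetic is 1-based inclusive (`length = end − start + 1`),
matching the callers' native tabular output; BED input is converted on
read. A call is by definition non-diploid: copy states {0, 1, 3, 4} are
accepted, CN = 2 records are rejected so the deletion/duplication dichotomy
is total. Only autosomes 1–22 are analysed (configurable): the control
collections are heavily sex-imbalanced and caller behaviour on sex
chromosomes is not modelled, so excluding them is the conservative choice.

## Consensus

For each sample, every pair of same-direction overlapping calls from the
two callers contributes its interval intersection, with the probe count
recomputed over the intersection; overlapping consensus pieces of the same
direction merge. Intersection is the conservative reading of a
two-callset consensus: a base is called only if both callers called it.
When the two callers report different non-diploid magnitudes, the state
nearer diploid is kept (CN 1 over 0, CN 3 over 4).

## Sample QC

Outlier pruning on LRRSD, absWF and BAF drift is a *single pass* per
dataset: means and SDs are computed once and not recomputed after
removals, which makes the procedure deterministic and idempotent on its
own output. The 3-SD rule uses mean ± 3·SD as printed (not median-based
fences). Hard caps (LRRSD ≤ 0.2, absWF ≤ 0.02, BAF drift ≤ 0.001) are then
enforced on survivors. Raw call load uses the *union* of a sample's call
intervals — "occupied basepairs" denotes genomic footprint, so nested
calls count once — with strict thresholds (> 20 Mb, > 20 calls).

## Filter cascade

Every filter runs on the full consensus callset and appends audit flags;
the analysis-ready set is the calls with no removal flag. This makes flag
assignment order-independent and the cascade fully auditable.

* **Size**: < 15 probes or < 30 kb removed; the bounds are inclusive on
  the keep side (15 probes / 30,000 bp survive).
* **Region masks**: coverage strictly above 30% removes against
  telomere/centromere buffers, polyN, segmental duplications and repeat
  classes; TCR/immunoglobulin and lymphoblastoid-artifact loci remove on
  any overlap — the latter rule is the literal reading of "calls
  overlapping these regions were removed" without a percentage.
* **Frequency**: same-direction calls are single-linkage clustered at
  ≥ 50% reciprocal overlap (the field-standard CNV matching rule; the
  clustering granularity is a config knob). A cluster's frequency is
  distinct carriers over QC-pass samples, evaluated against the combined
  cohort and against each input dataset with that dataset's denominator;
  ≥ 1% anywhere removes. External matching uses the same direction +
  ≥ 50% reciprocal-overlap rule against reference records with any listed
  frequency ≥ 1%. QC-pass samples are the denominator (the spec left
  all-samples vs QC-pass open; QC-pass is the self-consistent choice since
  removed samples contribute no calls).
* **BAF validation**: a deletion carrier has no heterozygous genotypes,
  so the call is rejected if more than `del_het_max` (default 0.10) of its
  marker BAFs fall in the diploid het band (0.25–0.75). A duplication's
  heterozygous markers sit near 1/3 and 2/3, so among mid-range BAFs
  (0.10–0.90) at least `dup_band_min` (default 0.60) must fall in
  (0.20–0.45) ∪ (0.55–0.80). Calls with fewer than 10 informative markers
  pass with a `BAF_UNTESTED` annotation rather than being removed: lack of
  evidence is not evidence of artifact. All thresholds are `BafParams`
  fields; the published validation procedure this emulates is not fully
  specified, so these defaults are calibrated on the generator (clean
  calls ≥ 95% accepted, diploid-signal false calls ≥ 90% rejected at BAF
  noise σ = 0.03).

### Batch-artifact inflation screen

Small (30–100 kb) deletions are particularly prone to batch effects.
The screen clusters the qualifying small deletions, estimates the
permutation genomic-inflation factor λ over the multi-carrier clusters,
and, while λ > 1.10, excludes the clusters bearing a batch signature,
defined as: ≥ 4 carriers in one input dataset, ≥ 80% of all carriers in
that dataset, and a binomial concentration tail p < 0.01 given the
dataset's cohort share. Candidacy is deliberately a test of *dataset
composition*, not of case/control association: for a phenotype-pure batch
the association follows automatically, while chance case-control
imbalance at a genuine locus does not qualify. Singleton and two-carrier
clusters never qualify (a pair lands in one dataset ~30% of the time by
chance). All qualifying clusters are excluded as a set per iteration,
ordered by exact-test p for the audit trail: removing one cluster at a
time gated on the λ threshold is unstable against the estimator's
granularity (λ moves in jumps of ~0.1–0.3 per removed cluster at
realistic unit counts).

## Permutation genomic-inflation factor

Each unit's exact p is mapped to its χ²(1) quantile x = Q(1 − p); labels
are permuted within the four (country, sex) strata preserving stratum
case counts, and every unit is retested. Because the per-stratum margins
are permutation-invariant, only the total case-carrier count varies, so
each unit's full p-lookup is precomputed once and permutations reduce to
one matrix product.

Two normalisations are available. The classical summary —
median(x_obs) / median over permutations of median(x_perm) — is provided
(`method="median_ratio"`), but with a few hundred heavily discrete
rare-carrier exact tests it is ill-conditioned: the median of x sits on
an atom at zero (p = 1) in a large fraction of null cohorts, and even for
perfectly uniform p-values the sampling noise of a ratio of medians over
~400 tests exceeds ±0.1. The default (`method="qq_slope"`) is the
through-origin regression slope of the observed order statistics of x on
their permutation expectations — the slope of the permutation QQ plot. It
shares the atoms between numerator and denominator, concentrates near 1
under the null (measured sd ≈ 0.06 at ~110 units), and responds strongly
to a handful of extreme loci, which is exactly what the batch screen
needs. Units with fewer than two carriers are excluded from either
estimate: a singleton's two-sided exact p equals 1 with probability at
least the majority-class share and carries no inflation information.

## Exact stratified association

Units are formed by clumping: neighbouring genes (or array probes) merge
when more than 50% of the calls overlapping either overlap both,
transitively along genomic order, separately for deletions and
duplications; units no call touches are dropped. Each unit is tested
conditionally on all margins: the total case-carrier count S over the
four strata is a convolution of central hypergeometrics, and the
two-sided p sums the probabilities of all S no more likely than the
observed one (minimum-likelihood rule, with the same 1 + 10⁻⁷ tie
tolerance common Fisher-exact implementations use). The common odds
ratio is the Mantel–Haenszel estimate. Benjamini–Hochberg q-values use
the standard step-up with monotonicity enforcement.

## Recurrence permutation test

T = number of deletion loci carried by at least two distinct cases; the
null permutes case/control labels within strata; the reported p is the
conservative (1 + #{T_perm ≥ T_obs}) / (1 + B). Because T is a coarse
integer statistic this p is super-uniform under the null *by
construction* — valid for inference, but it cannot pass a distributional
uniformity check. A seeded randomized-tie-break p (uniform under the
null, the standard construction for calibration checking of discrete
tests) is returned alongside and is what the calibration suite examines.
A single extreme locus cannot move T appreciably (a permuted
multi-carrier locus usually retains ≥ 2 case carriers); the test's power
comes from aggregation over many case-concentrated loci.

## Burden models

The logistic model regresses case status on covariates plus the metric
(OR per metric unit, Wald 95% CI and p); the linear model regresses the
metric on covariates plus case status (covariate-adjusted excess per
case). Wald inference matches the conventional "OR, P" reporting style.
Separation is detected (non-convergence, |coef| > 20 or SE > 50) and
reported with an unbounded CI rather than raised. Covariate screening
admits a candidate (PCs 6–20, LRRSD) when univariate regressions give
p < 0.05 against both raw call count and case status; 0.05 is a default,
not a claim about the optimal threshold. "Coding" means ≥ 1 bp overlap
with an annotated gene; constraint metrics count impacted bases above
each score threshold in kb; both the pLI thresholds {0.5, 0.9, 0.995} and
the constraint-score bin edges are configuration.

## Clinical and carrier analyses

The Fisher-vs-chi-square switch for 2×2 comorbidity tables is at minimum
expected count < 1 (not the textbook 5): rare-carrier tables routinely
have one expected cell between 1 and 5, and the uncorrected Pearson
statistic is what this literature reports for them — the reference worked
example (χ² = 24.38 on a table with minimum expected count 1.09) fixes
the convention. The chi-square carries no continuity correction (the
Yates-corrected value does not reproduce the printed statistic). The
treatment-response test is a pooled-variance t on percent symptom
improvement, 100·(pre − post)/pre (the reported degrees of freedom in the
reference analysis imply pooled, not Welch; Welch is a flag away in
scipy if wanted). Poisson enrichment is the exact upper tail
P(X ≥ observed).

## The synthetic world

The generator emulates, at roughly 1:10 scale (5 chromosomes × 30 Mb,
50,000 evenly spaced probes, ~1,800 genes placed off-mask on a jittered
grid), the structure the analysis assumes: phenotype-pure genotyping
batches over two countries (full-scale default: 2,248 cases / 3,608
controls), country separation on PC5, majority-female controls,
log-normal intensity metrics with a 2% planted outlier fraction, risk-CNV
carriage logistic in case status (so each planted OR is the exact
generative parameter and parameter recovery is well-posed), a planted
excess call rate per case, rare recurrence hotspots (800 loci of
50–250 kb, 35% of background calls; 2–4 carriers per locus at full cohort
scale), common CNV loci at ≥ 1% frequency mirrored in the external
reference, batch-artifact small deletions (19 calls, near-evenly split
over 3 novel 65–95 kb loci, confined to one dataset), calls planted
inside repeat/segdup masks, diploid-BAF false calls, two-caller emission
with ±2-probe boundary jitter and 3% per-callset dropout, and marker BAF
band structure per copy state at call sites plus flanks. Risk CNVs are
120 kb–1 Mb: pathogenic CNVs are large, and this keeps the 30–100 kb
inflation-screen band free of planted risk signal. Clinical effects
(comorbidity odds ratio for neurodevelopmental-duplication carriers,
treatment-response shift for neurodevelopmental-deletion carriers,
polygenic-score shift for deleterious-deletion carriers) attach to
carriage of a qualifying *true* variant, whatever its provenance, so the
pipeline's own carrier analysis can recover them.

Scale artifacts worth knowing about:

* The per-dataset < 1% frequency rule bites at 2 carriers in a
  ~150-sample batch. With phenotype-pure batches this couples a
  label-agnostic filter to case status and makes permutation nulls
  conservative; it is negligible at full cohort size. The toy calibration
  cohort (`SimConfig.toy`) therefore uses phenotype-mixed batches, while
  the full-scale default keeps the study-like pure batches. Below ~300
  samples per arm the rule removes essentially every call — use larger
  toys.
* Gene and gene-set density per Mb is higher than a real genome, so
  partitioned burden metrics (e.g. deletions hitting high-pLI genes) are
  diluted by background hits and show attenuated odds ratios relative to
  the planted per-carrier effects.

What a green calibration run establishes: type-I error of the logistic
burden test at nominal level, inflation factor centred on 1, uniform
(randomized) recurrence p-values, CI coverage for planted effects, and
complete, specific recovery of every planted artifact class by its
intended filter. What it does not establish: behaviour under array noise
regimes the generator does not model (wave artifacts correlated along
chromosomes, probe-density variation, caller-specific breakpoint biases
beyond symmetric jitter), nor external validity of any threshold to a
particular real dataset.

Known stochastic limits: the batch-artifact screen can miss a locus when
caller dropout removes ≥ 3 of its ~6 calls (~0.3% per locus per cohort),
and a chance hotspot cluster with ≥ 4 same-dataset carriers is
compositionally indistinguishable from a small artifact locus (~0.1 per
cohort); both are visible in the audit output when they occur.
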