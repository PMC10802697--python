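"""Synthetic cohorts, annotations and CNV callsets with planted effects.

The generator emulates the statistical structure a rare-CNV case/control
burden analysis assumes, at roughly 1:10 scale from a genotyping-array
study (toy genome: 5 chromosomes x 30 Mb, 50,000 evenly spaced probes,
2,000 genes), so every downstream stage is testable in seconds without
external data.  What is emulated:

* a case/control cohort split over datasets with country structure (PC5
  separates Swedish from Norwegian samples), sex imbalance (controls
  majority female), log-normal intensity metrics with a planted outlier
  fraction;
* risk CNVs whose carriage follows a logistic model in case status with
  configurable log odds ratios, so each planted OR is the true generative
  parameter and parameter recovery is a well-posed oracle;
* an excess rate of clean rare CNVs per case (the linear-burden signal);
* background rare CNVs, partly recurring at hotspot loci; common CNV loci
  at >=1% frequency; batch-artifact small deletions confined to one
  dataset; calls placed inside repeat/segdup masks; and "false" calls
  whose marker-level BAF is diploid-like;
* two caller callsets (A, B) per sample, each true CNV emitted with
  independent boundary jitter of +/-J probes and dropped with a per-dataset
  noise probability, plus per-probe BAF/LRR signal consistent with copy
  state at call sites;
* clinical phenotypes: comorbidity flags with a planted odds ratio against
  neurodevelopmental-duplication carriage, treatment response (percent
  YBOCS improvement) shifted in neurodevelopmental-deletion carriers, and
  normalised polygenic scores shifted in deleterious-deletion carriers.

Everything is a deterministic function of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .types import ProbeMap, RegionSet

__all__ = [
    "DatasetSpec", "GenomeConfig", "ClinicalConfig", "SimConfig",
    "Annotation", "SimTruth", "SimulatedStudy",
    "generate_cohort", "generate_annotation", "generate_cnv_calls",
    "generate_clinical", "simulate_study",
]


class ConfigError(ValueError):
    """An internally inconsistent simulation configuration."""


@dataclass(frozen=True)
class DatasetSpec:
    """One input dataset (genotyping batch) in the cohort."""
    name: str
    country: str                 # "SWE" | "NOR"
    n_cases: int = 0
    n_controls: int = 0
    caller_noise: float = 0.03   # P(a true CNV is missing from one callset)
    female_frac_cases: float = 0.64
    female_frac_controls: float = 0.80


@dataclass(frozen=True)
class GenomeConfig:
    """Toy genome: scaled ~1:10 from a 537k-probe genome-wide array."""
    n_chroms: int = 5
    chrom_length: int = 30_000_000
    n_probes: int = 50_000
    n_genes: int = 2_000

    @property
    def chroms(self) -> tuple:
        return tuple(str(i + 1) for i in range(self.n_chroms))

    @property
    def total_length(self) -> int:
        return self.n_chroms * self.chrom_length


@dataclass(frozen=True)
class ClinicalConfig:
    """Planted clinical-effect sizes (case cohort only)."""
    asd_base_rate: float = 0.091       # ~147/1612 comorbid-ASD fraction
    asd_dup_or: float = 10.0           # OR between NDD-dup carriage and ASD
    other_comorbidity_rates: tuple = (("adhd", 0.20), ("tics", 0.10),
                                      ("scz", 0.02), ("bd", 0.03))
    ybocs_pre_mean: float = 26.0
    ybocs_pre_sd: float = 5.0
    improvement_mean: float = 0.47     # non-carrier mean fractional improvement
    improvement_sd: float = 0.30
    ybocs_del_shift: float = -0.31     # carrier shift (0.47 -> 0.16)
    prs_del_shift: float = -0.45       # SD-units shift in psychiatric PRS
    treatment_data_frac: float = 0.525  # fraction of cases with pre/post YBOCS


# effect-metric name -> (cnv_type, gene eligibility predicate)
_EFFECT_KINDS = {
    "del_highpli": ("del", lambda g: g["pli"] > 0.995),
    "del_coding": ("del", lambda g: np.ones(len(g), dtype=bool)),
    "dup_coding": ("dup", lambda g: np.ones(len(g), dtype=bool)),
    "del_ndd": ("del", lambda g: (g["ndd_kendall"] | g["ndd_fu"]).to_numpy(dtype=bool)),
    "dup_ndd": ("dup", lambda g: (g["ndd_kendall"] | g["ndd_fu"]).to_numpy(dtype=bool)),
}


@dataclass(frozen=True)
class SimConfig:
    """Full description of one simulated study.

    Defaults mirror the cohort the pipeline was designed around: 2,248
    cases and 3,608 controls from Sweden and Norway, planted deletion
    burden in loss-of-function-intolerant genes (OR 4.12), duplication
    burden in neurodevelopmental genes (OR 2.5), an excess of 0.07 clean
    rare CNVs per case, and a 19-call / 3-locus small-deletion batch
    artifact confined to one dataset.
    """
    datasets: tuple = (
        DatasetSpec("swe_cases", "SWE", n_cases=1612),
        DatasetSpec("nor_cases", "NOR", n_cases=636),
        DatasetSpec("swe_controls", "SWE", n_controls=2008),
        DatasetSpec("nor_controls", "NOR", n_controls=1600),
    )
    genome: GenomeConfig = GenomeConfig()
    # planted log odds ratios and base (control) carrier rates per metric
    effects: dict = field(default_factory=lambda: {
        "del_highpli": math.log(4.12),
        "dup_ndd": math.log(2.5),
    })
    effect_base_rates: dict = field(default_factory=lambda: {
        "del_highpli": 0.005,
        "dup_ndd": 0.005,
    })
    excess_rate: float = 0.07      # extra clean rare CNVs per case
    background_rate: float = 0.6   # clean rare background CNVs per sample
    hotspot_frac: float = 0.35     # fraction of background calls at hotspot loci
    n_hotspots: int = 800          # dense enough for 2-4 carriers per locus
    hotspot_len_range: tuple = (50_000, 250_000)  # log-uniform
    small_call_rate: float = 0.5   # sub-threshold (<15 probes) calls per sample
    mask_artifact_rate: float = 0.05  # calls planted inside repeat/segdup masks
    n_common_loci: int = 5
    common_cnv_rate: float = 0.03  # per-locus carrier frequency (>= 1%)
    false_call_rate: float = 0.02  # diploid-BAF "false" calls per sample
    batch_artifact: tuple | None = ("swe_cases", 3, 19)  # (dataset, loci, calls)
    mask_frac: float = 0.08        # genome fraction under random masks
    outlier_frac: float = 0.02     # samples pushed past hard intensity bounds
    jitter_probes: int = 2         # per-callset boundary jitter (+/- probes)
    baf_noise: float = 0.03
    emit_signal: bool = True       # per-probe BAF/LRR at call sites
    clinical: ClinicalConfig = ClinicalConfig()
    # optional confounding (used to mimic covariate selection in the source
    # cohort: a PC and the intensity noise metric associated with both case
    # status and raw call count)
    lrrsd_case_shift: float = 0.0  # log-scale shift of lrrsd in cases
    pc7_case_shift: float = 0.0
    rate_slope_lrrsd: float = 0.0  # log-rate slope of raw calls on z(lrrsd)
    rate_slope_pc7: float = 0.0

    def __post_init__(self):
        for name, rate in [("common_cnv_rate", self.common_cnv_rate),
                           ("false_call_rate", self.false_call_rate),
                           ("hotspot_frac", self.hotspot_frac),
                           ("outlier_frac", self.outlier_frac),
                           ("mask_frac", self.mask_frac)]:
            if not 0 <= rate <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {rate}")
        if self.n_common_loci and self.common_cnv_rate < 0.01:
            raise ConfigError("common CNV loci must be planted at >= 1% frequency")
        for metric in self.effects:
            if metric not in _EFFECT_KINDS:
                raise ConfigError(f"unknown effect metric {metric!r}; "
                                  f"known: {sorted(_EFFECT_KINDS)}")
            if metric not in self.effect_base_rates:
                raise ConfigError(f"no base carrier rate for effect {metric!r}")

    @property
    def n_cases(self) -> int:
        return sum(d.n_cases for d in self.datasets)

    @property
    def n_controls(self) -> int:
        return sum(d.n_controls for d in self.datasets)

    @classmethod
    def toy(cls, n_cases: int = 600, n_controls: int = 600, **overrides) -> "SimConfig":
        """A small cohort on the default toy genome, for calibration runs.

        Unlike the full-scale default, the toy's four batches each contain
        both cases and controls.  At 1:10 scale the per-dataset < 1%
        frequency rule bites at two same-batch carriers; with
        phenotype-pure batches that couples a label-agnostic filter to
        case status and visibly biases permutation nulls — a pure scale
        artifact, negligible at full cohort size.  Batch-confounded
        scenarios are exercised by the full-scale config instead.
        """
        sc = int(round(n_cases * 0.72))       # SWE share of cases
        so = int(round(n_controls * 0.56))    # SWE share of controls
        datasets = (
            DatasetSpec("swe_a", "SWE", n_cases=sc // 2, n_controls=so // 2),
            DatasetSpec("swe_b", "SWE", n_cases=sc - sc // 2,
                        n_controls=so - so // 2),
            DatasetSpec("nor_a", "NOR", n_cases=(n_cases - sc) // 2,
                        n_controls=(n_controls - so) // 2),
            DatasetSpec("nor_b", "NOR",
                        n_cases=(n_cases - sc) - (n_cases - sc) // 2,
                        n_controls=(n_controls - so) - (n_controls - so) // 2),
        )
        base = dict(datasets=datasets, batch_artifact=None)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def null(cls, n_cases: int = 600, n_controls: int = 600, **overrides) -> "SimConfig":
        """Toy cohort with every planted effect switched off."""
        base = dict(effects={}, effect_base_rates={}, excess_rate=0.0,
                    batch_artifact=None, mask_artifact_rate=0.0)
        base.update(overrides)
        return cls.toy(n_cases, n_controls, **base)

    @classmethod
    def paper_like(cls, **overrides) -> "SimConfig":
        """Full-scale cohort with PC7/LRRSD confounded with case status and
        raw call rate, mimicking the covariate-selection regime of the
        source cohort."""
        base = dict(lrrsd_case_shift=0.06, pc7_case_shift=0.15,
                    rate_slope_lrrsd=0.15, rate_slope_pc7=0.08)
        base.update(overrides)
        return cls(**base)


# ---------------------------------------------------------------------------
# cohort


def generate_cohort(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Generate the sample sheet: IDs, case status, dataset/country/sex,
    intensity metrics, PCs 1-20.

    PC5 is offset by country (+1.5 for SWE, -1.5 for NOR) so that country
    separates on it; all other PCs are standard normal.  Intensity metrics
    are log-normal with an ``outlier_frac`` of samples pushed past the hard
    QC bounds (LRRSD 0.2, absWF 0.02, BAF drift 0.001).
    """
    rows = []
    for ds in cfg.datasets:
        if ds.n_cases + ds.n_controls <= 0:
            raise ConfigError(f"dataset {ds.name!r} declared with zero samples")
        for is_case, n, female_frac in [(True, ds.n_cases, ds.female_frac_cases),
                                        (False, ds.n_controls, ds.female_frac_controls)]:
            if n == 0:
                continue
            sex = np.where(rng.random(n) < female_frac, "F", "M")
            rows.append(pd.DataFrame({
                "sample_id": [f"{ds.name}_{i:05d}_{'ca' if is_case else 'co'}"
                              for i in range(n)],
                "is_case": is_case,
                "dataset": ds.name,
                "country": ds.country,
                "sex": sex,
            }))
    samples = pd.concat(rows, ignore_index=True)
    n = len(samples)
    is_case = samples["is_case"].to_numpy()

    pcs = rng.standard_normal((n, 20))
    pcs[:, 4] += np.where(samples["country"] == "SWE", 1.5, -1.5)
    pcs[:, 6] += cfg.pc7_case_shift * is_case
    for i in range(20):
        samples[f"PC{i + 1}"] = pcs[:, i]

    lrrsd = np.exp(rng.normal(math.log(0.10), 0.20, n) + cfg.lrrsd_case_shift * is_case)
    abs_wf = np.exp(rng.normal(math.log(0.006), 0.30, n))
    baf_drift = np.exp(rng.normal(math.log(2e-4), 0.40, n))
    # planted outliers: push one metric well past its hard bound
    out = rng.random(n) < cfg.outlier_frac
    which = rng.integers(0, 3, n)
    lrrsd = np.where(out & (which == 0), np.maximum(lrrsd * 4.0, 0.25), lrrsd)
    abs_wf = np.where(out & (which == 1), np.maximum(abs_wf * 6.0, 0.03), abs_wf)
    baf_drift = np.where(out & (which == 2), np.maximum(baf_drift * 10.0, 0.002), baf_drift)
    samples["lrrsd"] = lrrsd
    samples["abs_wf"] = abs_wf
    samples["baf_drift"] = baf_drift
    samples["planted_outlier"] = out
    return samples


# ---------------------------------------------------------------------------
# annotation

MASK_NAMES = ("telomere", "centromere", "polyN", "segdup", "repeats",
              "tcr_ig", "lcl_artifact")


@dataclass
class Annotation:
    """Toy-genome annotation bundle consumed by the filter cascade."""
    genome: GenomeConfig
    probe_map: ProbeMap
    genes: RegionSet
    masks: dict                    # name -> RegionSet, in cascade order
    constraint: RegionSet
    freq_ref: pd.DataFrame         # external frequency reference records
    common_loci: pd.DataFrame      # planted common loci (chrom,start,end,cnv_type,freq)
    hotspots: pd.DataFrame         # rare recurrent background loci


def _random_intervals(rng, genome: GenomeConfig, count: int,
                      min_len: int, max_len: int) -> pd.DataFrame:
    chroms = rng.integers(0, genome.n_chroms, count)
    lengths = rng.integers(min_len, max_len + 1, count)
    starts = (rng.random(count) * (genome.chrom_length - lengths - 2e6) + 1e6).astype(np.int64)
    return pd.DataFrame({
        "chrom": [str(c + 1) for c in chroms],
        "start": starts,
        "end": starts + lengths - 1,
    })


def generate_annotation(cfg: SimConfig, rng: np.random.Generator) -> Annotation:
    """Build the toy genome: probes, genes, masks, constraint track and the
    external frequency reference.

    Probes are evenly spaced; genes are placed on a jittered grid (hence
    pairwise disjoint) and dropped where they intersect a mask; pLI is drawn
    from a U-shaped Beta(0.2, 0.2); gene-set flags mark random subsets.
    """
    g = cfg.genome
    # --- probes: even spacing with deterministic offset
    per_chrom = g.n_probes // g.n_chroms
    spacing = g.chrom_length // per_chrom
    probe_rows = []
    for ci, chrom in enumerate(g.chroms):
        pos = spacing // 2 + spacing * np.arange(per_chrom, dtype=np.int64)
        probe_rows.append(pd.DataFrame({
            "chrom": chrom, "pos": pos,
            "probe_id": [f"p{ci}_{i}" for i in range(per_chrom)],
        }))
    probes = pd.concat(probe_rows, ignore_index=True)

    # --- masks
    telo = []
    centro = []
    for chrom in g.chroms:
        telo.append((chrom, 1, 500_000))
        telo.append((chrom, g.chrom_length - 499_999, g.chrom_length))
        mid = g.chrom_length // 2
        centro.append((chrom, mid - 1_000_000, mid + 1_000_000))
    masks = {
        "telomere": RegionSet("telomere", pd.DataFrame(telo, columns=["chrom", "start", "end"])),
        "centromere": RegionSet("centromere", pd.DataFrame(centro, columns=["chrom", "start", "end"])),
    }
    # random masks sized to occupy roughly mask_frac of the genome in total
    budget = cfg.mask_frac * g.total_length
    specs = [("polyN", 0.10, 50_000, 150_000), ("segdup", 0.45, 150_000, 500_000),
             ("repeats", 0.35, 50_000, 200_000), ("tcr_ig", 0.05, 200_000, 400_000),
             ("lcl_artifact", 0.05, 150_000, 300_000)]
    for name, share, lo, hi in specs:
        count = max(1, int(budget * share / ((lo + hi) / 2)))
        masks[name] = RegionSet(name, _random_intervals(rng, g, count, lo, hi))
    total_mask_bp = sum(
        int(np.sum(m.merged_intervals(c)[:, 1] - m.merged_intervals(c)[:, 0] + 1))
        for m in masks.values() for c in g.chroms if m.merged_intervals(c).size
    )
    if total_mask_bp > 0.9 * g.total_length:
        raise ConfigError("masks would cover more than 90% of the genome")

    # --- genes on a jittered grid, disjoint by construction, off-mask
    genes_per_chrom = g.n_genes // g.n_chroms
    pitch = g.chrom_length // (genes_per_chrom + 1)
    rows = []
    gid = 0
    for chrom in g.chroms:
        anchors = pitch * (1 + np.arange(genes_per_chrom, dtype=np.int64))
        lengths = rng.integers(5_000, int(pitch * 0.6), genes_per_chrom)
        jitter = rng.integers(0, int(pitch * 0.3), genes_per_chrom)
        starts = anchors + jitter
        for s, ln in zip(starts, lengths):
            e = int(s + ln - 1)
            if any(m.covered_bp(chrom, int(s), e) > 0 for m in masks.values()):
                continue
            rows.append({"gene_id": f"G{gid:05d}", "chrom": chrom,
                         "start": int(s), "end": e})
            gid += 1
    gene_df = pd.DataFrame(rows)
    ng = len(gene_df)
    if ng == 0:
        raise ConfigError("no genes could be placed outside masks")
    gene_df["pli"] = rng.beta(0.2, 0.2, ng)
    for flag, frac in [("ndd_kendall", 0.03), ("ndd_fu", 0.035),
                       ("haplosensitive", 0.05), ("triplosensitive", 0.05)]:
        gene_df[flag] = rng.random(ng) < frac
    genes = RegionSet("genes", gene_df, merge=False)

    # --- constraint track: short scored elements, denser inside genes
    n_elem = 3_000
    elems = _random_intervals(rng, g, n_elem, 200, 2_000)
    elems["score"] = rng.gamma(1.5, 2.0, n_elem)  # right-skewed, range ~0-15
    constraint = RegionSet("constraint", elems, merge=False)

    # --- common CNV loci (>= 1% carrier frequency) and external reference
    common = _random_intervals(rng, g, cfg.n_common_loci, 60_000, 300_000)
    common["cnv_type"] = rng.choice(["del", "dup"], cfg.n_common_loci)
    common["freq"] = 0.01 + rng.random(cfg.n_common_loci) * (cfg.common_cnv_rate * 2 - 0.01)
    ref_rows = common.rename(columns={"freq": "freq_global"}).copy()
    ref_rows["freq_subpop_1"] = ref_rows["freq_global"] * (0.8 + 0.4 * rng.random(len(ref_rows)))
    # plus rare reference records that must NOT trigger the frequency filter
    rare_ref = _random_intervals(rng, g, 20, 60_000, 300_000)
    rare_ref["cnv_type"] = rng.choice(["del", "dup"], 20)
    rare_ref["freq_global"] = rng.random(20) * 0.002
    rare_ref["freq_subpop_1"] = rng.random(20) * 0.002
    freq_ref = pd.concat([ref_rows, rare_ref], ignore_index=True)

    # --- hotspot loci: rare recurrent background CNV positions
    lo, hi = cfg.hotspot_len_range
    lengths = np.exp(rng.uniform(np.log(lo), np.log(hi),
                                 cfg.n_hotspots)).astype(np.int64)
    chrom_idx = rng.integers(0, g.n_chroms, cfg.n_hotspots)
    starts = (rng.random(cfg.n_hotspots) * (g.chrom_length - lengths - 2e6)
              + 1e6).astype(np.int64)
    hotspots = pd.DataFrame({
        "chrom": [str(c + 1) for c in chrom_idx],
        "start": starts, "end": starts + lengths - 1,
        "cnv_type": rng.choice(["del", "dup"], cfg.n_hotspots),
    })

    return Annotation(genome=g, probe_map=ProbeMap(probes), genes=genes,
                      masks=masks, constraint=constraint, freq_ref=freq_ref,
                      common_loci=common, hotspots=hotspots)


# ---------------------------------------------------------------------------
# CNV calls


@dataclass
class SimTruth:
    """Ground truth of a simulated callset.

    ``calls`` holds one row per true planted CNV (before caller emission)
    with a ``kind`` label: background, small, common, excess, risk:<metric>,
    batch_artifact, mask_artifact or false. ``carrier_flags`` holds one
    boolean column per planted effect metric plus ``excess_n``.
    """
    calls: pd.DataFrame
    carrier_flags: pd.DataFrame
    artifact_loci: pd.DataFrame


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _clip_interval(start: int, length: int, chrom_len: int) -> tuple[int, int]:
    start = max(1, min(start, chrom_len - length))
    return start, start + length - 1


def _mask_fraction(annotation: Annotation, chrom, start, end) -> float:
    """Largest single-mask coverage fraction of an interval (quick screen)."""
    length = end - start + 1
    best = 0.0
    for m in annotation.masks.values():
        best = max(best, m.covered_bp(chrom, start, end) / length)
    return best


def _place_clean(rng, annotation: Annotation, min_len: int, max_len: int,
                 max_mask_frac: float = 0.25, tries: int = 12):
    """Uniform placement re-drawn until no mask covers > max_mask_frac."""
    g = annotation.genome
    for _ in range(tries):
        length = int(np.exp(rng.uniform(math.log(min_len), math.log(max_len))))
        chrom = str(rng.integers(1, g.n_chroms + 1))
        start, end = _clip_interval(int(rng.integers(1, g.chrom_length)), length,
                                    g.chrom_length)
        if _mask_fraction(annotation, chrom, start, end) <= max_mask_frac:
            return chrom, start, end
    return chrom, start, end  # give up; downstream filters may flag it


def generate_cnv_calls(cohort: pd.DataFrame, annotation: Annotation,
                       cfg: SimConfig, rng: np.random.Generator
                       ) -> tuple[list, list, ProbeMap, SimTruth]:
    """Generate true CNVs, emit them through two noisy callers and simulate
    marker-level BAF/LRR signal.

    Returns ``(calls_A, calls_B, probe_map_with_signal, truth)``.  Caller
    emission drops a true call from each callset independently with the
    dataset's ``caller_noise`` and jitters each boundary by up to
    ``jitter_probes`` array probes; the consensus step downstream recovers
    approximately the true interval as the intersection.
    """
    from .types import CnvCall  # local import to avoid cycle at module load

    g = annotation.genome
    sample_ids = cohort["sample_id"].to_numpy()
    is_case = cohort["is_case"].to_numpy()
    ds_of = dict(zip(cohort["sample_id"], cohort["dataset"]))
    noise_of = {d.name: d.caller_noise for d in cfg.datasets}
    n = len(cohort)
    gene_df = annotation.genes.df

    truth_rows: list[dict] = []

    def add_truth(sid, chrom, start, end, copy_state, kind, locus_id=""):
        truth_rows.append(dict(sample_id=sid, chrom=str(chrom), start=int(start),
                               end=int(end), copy_state=int(copy_state),
                               kind=kind, locus_id=locus_id))

    # --- risk CNVs: carrier status logistic in case status (planted OR is
    # the exact generative parameter; OR symmetry makes the retrospective
    # case/control fit recover it)
    flags = pd.DataFrame({"sample_id": sample_ids})
    for metric, ln_or in cfg.effects.items():
        cnv_type, eligible_fn = _EFFECT_KINDS[metric]
        eligible = gene_df[np.asarray(eligible_fn(gene_df), dtype=bool)]
        if len(eligible) == 0:
            raise ConfigError(f"effect {metric!r}: no eligible genes in annotation")
        base = cfg.effect_base_rates[metric]
        p = _sigmoid(math.log(base / (1 - base)) + ln_or * is_case)
        carrier = rng.random(n) < p
        flags[metric] = carrier
        copy_state = 1 if cnv_type == "del" else 3
        idx = eligible.index.to_numpy()
        # pathogenic CNVs are large: 120 kb - 1 Mb keeps them clear of the
        # 30-100 kb band used by the batch-effect inflation screen
        for sid in sample_ids[carrier]:
            # re-draw gene/length if the interval strays too far into a mask
            for _ in range(12):
                row = eligible.loc[rng.choice(idx)]
                length = int(np.exp(rng.uniform(math.log(120_000), math.log(1_000_000))))
                center = (int(row["start"]) + int(row["end"])) // 2
                start, end = _clip_interval(center - length // 2, length,
                                            g.chrom_length)
                if _mask_fraction(annotation, row["chrom"], start, end) <= 0.25:
                    break
            add_truth(sid, row["chrom"], start, end, copy_state, f"risk:{metric}")

    # --- excess clean rare CNVs in cases (linear burden signal)
    if cfg.excess_rate > 0:
        counts = rng.poisson(cfg.excess_rate * is_case)
        flags["excess_n"] = counts
        for sid, k in zip(sample_ids, counts):
            for _ in range(int(k)):
                chrom, start, end = _place_clean(rng, annotation, 60_000, 400_000)
                add_truth(sid, chrom, start, end, int(rng.choice([1, 3])), "excess")
    else:
        flags["excess_n"] = 0

    # --- background rare CNVs (uniform or hotspot placement)
    log_rate = np.log(cfg.background_rate) if cfg.background_rate > 0 else -np.inf
    z_lrrsd = (np.log(cohort["lrrsd"].to_numpy()) - math.log(0.10)) / 0.20
    rates = np.exp(log_rate + cfg.rate_slope_lrrsd * z_lrrsd
                   + cfg.rate_slope_pc7 * cohort["PC7"].to_numpy())
    bg_counts = rng.poisson(np.where(np.isfinite(rates), rates, 0.0))
    hot = annotation.hotspots
    for sid, k in zip(sample_ids, bg_counts):
        for _ in range(int(k)):
            if cfg.n_hotspots and rng.random() < cfg.hotspot_frac:
                h = hot.iloc[int(rng.integers(0, len(hot)))]
                copy_state = 1 if h["cnv_type"] == "del" else 3
                add_truth(sid, h["chrom"], h["start"], h["end"], copy_state,
                          "background", locus_id=f"hot{h.name}")
            else:
                length = int(np.exp(rng.uniform(math.log(50_000), math.log(1_000_000))))
                chrom = str(rng.integers(1, g.n_chroms + 1))
                start, end = _clip_interval(int(rng.integers(1, g.chrom_length)),
                                            length, g.chrom_length)
                add_truth(sid, chrom, start, end, int(rng.choice([1, 3])), "background")

    # --- sub-threshold small calls (exercise the size filter)
    small_counts = rng.poisson(cfg.small_call_rate, n)
    for sid, k in zip(sample_ids, small_counts):
        for _ in range(int(k)):
            length = int(rng.integers(8_000, 40_000))
            chrom = str(rng.integers(1, g.n_chroms + 1))
            start, end = _clip_interval(int(rng.integers(1, g.chrom_length)),
                                        length, g.chrom_length)
            add_truth(sid, chrom, start, end, int(rng.choice([1, 3])), "small")

    # --- common CNV loci at >= 1% carrier frequency
    for li, locus in annotation.common_loci.iterrows():
        carriers = rng.random(n) < locus["freq"]
        copy_state = 1 if locus["cnv_type"] == "del" else 3
        for sid in sample_ids[carriers]:
            add_truth(sid, locus["chrom"], locus["start"], locus["end"],
                      copy_state, "common", locus_id=f"common{li}")

    # --- batch artifact: small deletions at few loci in one dataset
    artifact_loci = pd.DataFrame(columns=["chrom", "start", "end", "locus_id"])
    if cfg.batch_artifact is not None:
        ds_name, n_loci, n_calls = cfg.batch_artifact
        members = cohort.loc[cohort["dataset"] == ds_name, "sample_id"].to_numpy()
        if len(members) == 0:
            raise ConfigError(f"batch_artifact dataset {ds_name!r} has no samples")
        loci = []
        del_hot = annotation.hotspots[annotation.hotspots["cnv_type"] == "del"]
        for j in range(n_loci):
            # technical artifacts arise at novel loci: re-draw if the locus
            # would blend into a recurrent background (hotspot) deletion.
            # 65-95 kb keeps the calls inside the 30-100 kb band and above
            # the 15-probe floor even after consensus boundary shrinkage.
            for _ in range(20):
                chrom, start, end = _place_clean(rng, annotation, 65_000, 95_000)
                near = del_hot[(del_hot["chrom"] == chrom)
                               & (del_hot["start"] <= end)
                               & (del_hot["end"] >= start)]
                from .intervals import reciprocal_overlap
                if all(reciprocal_overlap(start, end, int(h.start), int(h.end)) < 0.3
                       for h in near.itertuples()):
                    break
            loci.append(dict(chrom=chrom, start=start, end=end,
                             locus_id=f"artifact{j}"))
        artifact_loci = pd.DataFrame(loci)
        # near-even allocation: 19 calls over 3 loci -> (7, 6, 6)
        per_locus = np.full(n_loci, n_calls // n_loci)
        per_locus[: n_calls % n_loci] += 1
        for j, cnt in enumerate(per_locus):
            loc = loci[j]
            chosen = rng.choice(members, size=min(int(cnt), len(members)),
                                replace=False)
            for sid in chosen:
                add_truth(sid, loc["chrom"], loc["start"], loc["end"], 1,
                          "batch_artifact", locus_id=loc["locus_id"])

    # --- calls planted inside repeat/segdup masks (region-filter fodder)
    if cfg.mask_artifact_rate > 0:
        mask_pool = pd.concat([annotation.masks["segdup"].df,
                               annotation.masks["repeats"].df], ignore_index=True)
        big = mask_pool[(mask_pool["end"] - mask_pool["start"] + 1) >= 100_000]
        counts = rng.poisson(cfg.mask_artifact_rate, n)
        for sid, k in zip(sample_ids, counts):
            for _ in range(int(k)):
                m = big.iloc[int(rng.integers(0, len(big)))]
                mlen = int(m["end"] - m["start"] + 1)
                length = int(rng.integers(60_000, min(mlen, 250_000) + 1))
                start = int(m["start"]) + int(rng.integers(0, mlen - length + 1))
                add_truth(sid, m["chrom"], start, start + length - 1,
                          int(rng.choice([1, 3])), "mask_artifact")

    # --- false calls: pass positional filters but carry diploid BAF
    if cfg.false_call_rate > 0:
        counts = rng.poisson(cfg.false_call_rate, n)
        for sid, k in zip(sample_ids, counts):
            for _ in range(int(k)):
                chrom, start, end = _place_clean(rng, annotation, 60_000, 200_000)
                add_truth(sid, chrom, start, end, int(rng.choice([1, 3])), "false")

    truth_calls = pd.DataFrame(
        truth_rows, columns=["sample_id", "chrom", "start", "end",
                             "copy_state", "kind", "locus_id"])

    # --- caller emission with boundary jitter, plus marker-level signal
    calls_a: list = []
    calls_b: list = []
    signal: dict[str, dict[str, list]] = {}
    pos_by_chrom = {c: annotation.probe_map._pos[c] for c in g.chroms}
    J = cfg.jitter_probes

    # probe index span of every true call, vectorised per chromosome
    tc = truth_calls
    i0 = np.empty(len(tc), dtype=np.int64)
    i1 = np.empty(len(tc), dtype=np.int64)
    for chrom in g.chroms:
        sel = (tc["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        pos = pos_by_chrom[chrom]
        i0[sel] = np.searchsorted(pos, tc.loc[sel, "start"].to_numpy(), side="left")
        i1[sel] = np.searchsorted(pos, tc.loc[sel, "end"].to_numpy(), side="right") - 1
    visible = i1 >= i0  # no probes inside: the callers cannot see it
    noise = tc["sample_id"].map(ds_of).map(noise_of).fillna(0.03).to_numpy()

    sid_arr = tc["sample_id"].to_numpy()
    chrom_arr = tc["chrom"].to_numpy()
    state_arr = tc["copy_state"].to_numpy()
    for caller, out in (("A", calls_a), ("B", calls_b)):
        dropped = rng.random(len(tc)) < noise
        if J:
            j0 = i0 + rng.integers(-J, J + 1, len(tc))
            j1 = i1 + rng.integers(-J, J + 1, len(tc))
        else:
            j0, j1 = i0.copy(), i1.copy()
        lo = np.minimum(j0, j1)
        hi = np.maximum(j0, j1)
        for r in np.flatnonzero(visible & ~dropped):
            pos = pos_by_chrom[chrom_arr[r]]
            a = int(np.clip(lo[r], 0, len(pos) - 1))
            b = int(np.clip(hi[r], 0, len(pos) - 1))
            out.append(CnvCall(sample_id=sid_arr[r], chrom=chrom_arr[r],
                               start=int(pos[a]), end=int(pos[b]),
                               copy_state=int(state_arr[r]),
                               n_probes=b - a + 1, caller=caller))

    if cfg.emit_signal:
        kind_arr = tc["kind"].to_numpy()
        for r in np.flatnonzero(visible):
            pos = pos_by_chrom[chrom_arr[r]]
            fl0, fl1 = max(0, i0[r] - 5), min(len(pos) - 1, i1[r] + 5)
            n_in = int(i1[r] - i0[r] + 1)
            n_flank = int(fl1 - fl0 + 1 - n_in)
            baf_in, lrr_in = _simulate_signal(rng, n_in, int(state_arr[r]),
                                              kind_arr[r] == "false", cfg.baf_noise)
            baf_fl, lrr_fl = _simulate_signal(rng, n_flank, 2, True, cfg.baf_noise)
            idx = np.arange(fl0, fl1 + 1)
            inside = (idx >= i0[r]) & (idx <= i1[r])
            baf = np.empty(len(idx))
            lrr = np.empty(len(idx))
            baf[inside], lrr[inside] = baf_in, lrr_in
            baf[~inside], lrr[~inside] = baf_fl, lrr_fl
            parts = signal.setdefault(sid_arr[r], {"chrom": [], "pos": [],
                                                   "lrr": [], "baf": []})
            parts["chrom"].append(np.repeat(chrom_arr[r], len(idx)))
            parts["pos"].append(pos[idx])
            parts["lrr"].append(lrr)
            parts["baf"].append(baf)

    signal_frames = {
        sid: pd.DataFrame({k: np.concatenate(v) for k, v in parts.items()})
             .drop_duplicates(subset=["chrom", "pos"])
        for sid, parts in signal.items()
    }
    for df in signal_frames.values():
        df["pos"] = df["pos"].astype(np.int64)
        df["lrr"] = df["lrr"].astype(float)
        df["baf"] = df["baf"].astype(float)
    probe_map = ProbeMap(annotation.probe_map.probes, signal_frames)
    truth = SimTruth(calls=truth_calls, carrier_flags=flags,
                     artifact_loci=artifact_loci)
    return calls_a, calls_b, probe_map, truth


def _simulate_signal(rng, n_probes: int, copy_state: int, diploid: bool,
                     sigma: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-probe BAF/LRR for one call, consistent with copy state.

    CN=1: only homozygous bands (0, 1); CN=0: noisy mid-range BAF with very
    low LRR; CN=3/4: bands at m/CN for allele dosages m; diploid (CN=2 or a
    "false" call): bands at 0, 1/2, 1.
    """
    if n_probes == 0:
        return np.empty(0), np.empty(0)
    if diploid or copy_state == 2:
        centers = rng.choice([0.0, 0.5, 1.0], n_probes, p=[0.25, 0.5, 0.25])
        lrr_mu = 0.0
    elif copy_state == 0:
        centers = rng.random(n_probes)  # no allelic signal: noise
        lrr_mu = -2.0
    elif copy_state == 1:
        centers = rng.choice([0.0, 1.0], n_probes)
        lrr_mu = -0.45
    else:
        cn = copy_state
        dosages = rng.binomial(cn, 0.5, n_probes)
        centers = dosages / cn
        lrr_mu = 0.30 if cn == 3 else 0.55
    baf = np.clip(centers + rng.normal(0.0, sigma, n_probes), 0.0, 1.0)
    lrr = rng.normal(lrr_mu, 0.20, n_probes)
    return baf, lrr


# ---------------------------------------------------------------------------
# clinical phenotypes


def generate_clinical(cohort: pd.DataFrame, carrier_flags: pd.DataFrame,
                      cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Attach clinical columns (cases only) and polygenic scores (everyone).

    ``carrier_flags`` must carry boolean ``ndd_dup`` and ``ndd_del`` columns
    (derivable from truth or from the pipeline's own carrier analysis);
    comorbid ASD follows a logistic model in NDD-duplication carriage with
    the planted odds ratio, percent YBOCS improvement is shifted in NDD-
    deletion carriers, and the psychiatric PRS column is shifted in
    deleterious-deletion carriers.
    """
    cc = cfg.clinical
    out = cohort.merge(carrier_flags, on="sample_id", how="left")
    for col in ("ndd_dup", "ndd_del", "deleterious_del"):
        if col not in out.columns:
            out[col] = False
        out[col] = out[col].fillna(False).astype(bool)
    n = len(out)
    is_case = out["is_case"].to_numpy()
    n_cases = int(is_case.sum())
    if n_cases and cc.asd_base_rate * n_cases < 1:
        raise ConfigError("requested ASD prevalence yields < 1 expected case")

    # comorbidities (cases only; NaN for controls)
    base_logit = math.log(cc.asd_base_rate / (1 - cc.asd_base_rate))
    p_asd = _sigmoid(base_logit + math.log(cc.asd_dup_or) * out["ndd_dup"].to_numpy())
    asd = rng.random(n) < p_asd
    out["asd"] = np.where(is_case, asd.astype(float), np.nan)
    for name, rate in cc.other_comorbidity_rates:
        out[name] = np.where(is_case, (rng.random(n) < rate).astype(float), np.nan)

    # treatment response: percent YBOCS improvement shifted in NDD-del carriers
    pre = np.maximum(rng.normal(cc.ybocs_pre_mean, cc.ybocs_pre_sd, n), 10.0)
    improvement = rng.normal(cc.improvement_mean, cc.improvement_sd, n)
    improvement += cc.ybocs_del_shift * out["ndd_del"].to_numpy()
    improvement = np.clip(improvement, -1.0, 1.0)
    post = pre * (1.0 - improvement)
    has_treat = is_case & (rng.random(n) < cc.treatment_data_frac)
    out["ybocs_pre"] = np.where(has_treat, np.round(pre, 1), np.nan)
    out["ybocs_post"] = np.where(has_treat, np.round(post, 1), np.nan)

    # polygenic scores: standard normal; psychiatric PRS shifted in carriers
    out["prs_height"] = rng.standard_normal(n)
    out["prs_ocd"] = rng.standard_normal(n)
    out["prs_xdx"] = rng.standard_normal(n) + cc.prs_del_shift * out["deleterious_del"].to_numpy()
    return out


# ---------------------------------------------------------------------------
# one-call orchestration


@dataclass
class SimulatedStudy:
    """Everything one simulated study produces, plus its ground truth."""
    config: SimConfig
    samples: pd.DataFrame
    annotation: Annotation
    calls_a: list
    calls_b: list
    probe_map: ProbeMap
    truth: SimTruth


def truth_carrier_flags(truth: SimTruth, genes: RegionSet,
                        sample_ids) -> pd.DataFrame:
    """Deleterious / neurodevelopmental carrier flags from the true callset.

    Clinical effects attach to *carrying* a qualifying rare variant,
    whatever its provenance (planted risk CNV or rare background CNV), so
    carriage is derived from the true calls with the same rules the
    pipeline's carrier analysis applies: spurious calls (``false``,
    ``batch_artifact``, ``mask_artifact``), sub-threshold ``small`` calls
    and ``common`` variants do not count.
    """
    from .downstream import carrier_status
    from .types import CnvCall

    real = truth.calls[~truth.calls["kind"].isin(
        ("false", "small", "common", "batch_artifact", "mask_artifact"))]
    calls = [CnvCall(r.sample_id, r.chrom, int(r.start), int(r.end),
                     int(r.copy_state), max(1, (int(r.end) - int(r.start)) // 1000))
             for r in real.itertuples(index=False)]
    samples = pd.DataFrame({"sample_id": list(sample_ids)})
    flags = carrier_status(calls, samples, genes)
    return flags[["sample_id", "ndd_dup", "ndd_del", "deleterious_del"]]


def simulate_study(cfg: SimConfig, seed: int) -> SimulatedStudy:
    """Run the whole generator with one seed: cohort, annotation, callsets,
    marker signal and clinical fields, all byte-reproducible."""
    root = np.random.default_rng(seed)
    r_cohort, r_annot, r_calls, r_clin = root.spawn(4)
    cohort = generate_cohort(cfg, r_cohort)
    annotation = generate_annotation(cfg, r_annot)
    calls_a, calls_b, probe_map, truth = generate_cnv_calls(cohort, annotation,
                                                            cfg, r_calls)
    flags = truth_carrier_flags(truth, annotation.genes, cohort["sample_id"])
    samples = generate_clinical(cohort, flags, cfg, r_clin)
    return SimulatedStudy(config=cfg, samples=samples, annotation=annotation,
                          calls_a=calls_a, calls_b=calls_b,
                          probe_map=probe_map, truth=truth)
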