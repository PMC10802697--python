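"""Carrier-centred secondary analyses.

Carriers of "deleterious" CNVs — deletions hitting loss-of-function
intolerant genes (pLI > 0.995) or CNVs hitting curated neurodevelopmental
gene sets — are compared against non-carriers on polygenic scores,
psychiatric comorbidity and treatment response, and the case-only
single-gene CNV set is tested for enrichment against external exome
summary statistics with an exact Poisson tail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .types import CnvCall, RegionSet

__all__ = [
    "carrier_status", "case_only_single_gene_set", "poisson_enrichment",
    "prs_carrier_association", "comorbidity_association",
    "treatment_response_test",
]


def carrier_status(calls: list[CnvCall], samples: pd.DataFrame,
                   genes: RegionSet, pli_threshold: float = 0.995) -> pd.DataFrame:
    """Deterministic carrier flags per sample from the surviving callset.

    Columns: ``del_highpli`` (a deletion overlapping a gene above the pLI
    threshold), ``ndd_del_kendall``/``ndd_dup_kendall``,
    ``ndd_del_fu``/``ndd_dup_fu``, and the unions ``ndd_del``, ``ndd_dup``
    and ``deleterious_del`` (del_highpli or ndd_del).  Raising the pLI
    threshold can only remove carriers (monotone).
    """
    flags = pd.DataFrame({"sample_id": samples["sample_id"]})
    cols = ["del_highpli", "ndd_del_kendall", "ndd_dup_kendall",
            "ndd_del_fu", "ndd_dup_fu"]
    for c in cols:
        flags[c] = False
    flags = flags.set_index("sample_id")
    gdf = genes.df
    high = (gdf["pli"] > pli_threshold).to_numpy()
    kendall = gdf["ndd_kendall"].to_numpy(dtype=bool)
    fu = gdf["ndd_fu"].to_numpy(dtype=bool)
    known = set(flags.index)
    for call in calls:
        if call.sample_id not in known:
            continue
        rows = genes.overlapping_rows(call.chrom, call.start, call.end)
        if len(rows) == 0:
            continue
        t = call.cnv_type
        if t == "del" and high[rows].any():
            flags.loc[call.sample_id, "del_highpli"] = True
        if kendall[rows].any():
            flags.loc[call.sample_id, f"ndd_{t}_kendall"] = True
        if fu[rows].any():
            flags.loc[call.sample_id, f"ndd_{t}_fu"] = True
    flags["ndd_del"] = flags["ndd_del_kendall"] | flags["ndd_del_fu"]
    flags["ndd_dup"] = flags["ndd_dup_kendall"] | flags["ndd_dup_fu"]
    flags["deleterious_del"] = flags["del_highpli"] | flags["ndd_del"]
    return flags.reset_index()


def case_only_single_gene_set(calls: list[CnvCall], samples: pd.DataFrame,
                              genes: RegionSet) -> set:
    """Genes hit by >= 1 single-gene case CNV and by no single-gene control CNV.

    A call is "single-gene" iff it overlaps exactly one annotated gene;
    calls spanning two or more genes contribute to none.
    """
    is_case = dict(zip(samples["sample_id"], samples["is_case"]))
    case_hit: set = set()
    control_hit: set = set()
    for c in calls:
        hit = genes.overlapping(c.chrom, c.start, c.end)
        if len(hit) != 1 or c.sample_id not in is_case:
            continue
        gene = hit.iloc[0]["gene_id"]
        (case_hit if is_case[c.sample_id] else control_hit).add(gene)
    return case_hit - control_hit


def poisson_enrichment(observed: int, expected: float) -> float:
    """One-sided exact Poisson tail: P(X >= observed) with X ~ Poisson(expected)."""
    if expected <= 0:
        raise ValueError("expected count must be > 0")
    if observed < 0 or observed != int(observed):
        raise ValueError("observed must be a non-negative integer")
    if observed == 0:
        return 1.0
    return float(stats.poisson.sf(observed - 1, expected))


@dataclass
class PrsResult:
    prs: str
    carrier_flag: str
    estimate: float
    se: float
    p_value: float
    n_carriers: int
    skipped: bool = False


def prs_carrier_association(prs_column: str, carrier_flag: str,
                            samples: pd.DataFrame,
                            covariates: tuple = ("PC1", "PC2", "PC3", "PC4",
                                                 "PC5", "SEX")) -> PrsResult:
    """Linear regression of the normalised PRS on carrier status + covariates.

    The PRS is standardised (mean 0, SD 1) within the analysis set; a
    constant PRS column is an error, and a flag with no carriers is
    flagged and skipped.
    """
    from .burden import _column

    prs = samples[prs_column].to_numpy(dtype=float)
    if np.nanstd(prs) == 0:
        raise ValueError(f"PRS column {prs_column!r} is constant; cannot normalise")
    prs = (prs - np.nanmean(prs)) / np.nanstd(prs, ddof=0)
    carrier = samples[carrier_flag].to_numpy(dtype=float)
    n_carriers = int(carrier.sum())
    if n_carriers == 0:
        return PrsResult(prs_column, carrier_flag, np.nan, np.nan, np.nan, 0,
                         skipped=True)
    cols = {"const": np.ones(len(samples)), "carrier": carrier}
    for name in covariates:
        cols[name] = _column(samples, name)
    X = pd.DataFrame(cols)
    keep = np.isfinite(prs)
    res = sm.OLS(prs[keep], X[keep]).fit()
    return PrsResult(prs_column, carrier_flag, float(res.params["carrier"]),
                     float(res.bse["carrier"]), float(res.pvalues["carrier"]),
                     n_carriers)


@dataclass
class ContingencyResult:
    statistic: float     # chi-square, or the odds ratio for Fisher
    df: int
    p_value: float
    method: str          # "chi2" | "fisher"
    table: np.ndarray


def comorbidity_association(carrier_flag: str, comorbidity_flag: str,
                            samples: pd.DataFrame,
                            min_expected: float = 1.0) -> ContingencyResult:
    """2x2 association between carrier status and a comorbidity flag.

    Pearson chi-square without continuity correction when every expected
    count reaches ``min_expected``; otherwise a two-sided Fisher exact
    test.  The default switch is at expected < 1 rather than the textbook
    5: rare-carrier tables routinely have one small expected cell, and the
    chi-square is the reported statistic for them in this literature (a
    comorbidity table with a minimum expected count of ~1.1 is reported as
    chi-square).  Rows with a missing comorbidity value are excluded.
    """
    sub = samples.dropna(subset=[comorbidity_flag])
    a = sub[carrier_flag].astype(bool)
    b = sub[comorbidity_flag].astype(bool)
    table = np.array([[int((a & b).sum()), int((a & ~b).sum())],
                      [int((~a & b).sum()), int((~a & ~b).sum())]])
    if table.sum() == 0:
        raise ValueError("empty contingency table")
    expected = stats.contingency.expected_freq(table)
    if (expected >= min_expected).all():
        chi2_stat, p, df, _ = stats.chi2_contingency(table, correction=False)
        return ContingencyResult(float(chi2_stat), int(df), float(p), "chi2", table)
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return ContingencyResult(float(odds), 1, float(p), "fisher", table)


@dataclass
class TreatmentResult:
    t: float
    df: int
    p_value: float
    carrier_mean: float      # mean percent improvement among carriers
    noncarrier_mean: float
    n_carriers: int
    n_noncarriers: int
    skipped: bool = False


def treatment_response_test(samples: pd.DataFrame, carrier_flag: str,
                            pre_col: str = "ybocs_pre",
                            post_col: str = "ybocs_post") -> TreatmentResult:
    """Pooled-variance two-sided t-test of percent symptom improvement.

    Improvement = 100 * (pre - post) / pre, computed on samples with both
    scores; requires pre > 0. A group with fewer than 2 samples is flagged
    and no test is run.
    """
    sub = samples.dropna(subset=[pre_col, post_col])
    pre = sub[pre_col].to_numpy(dtype=float)
    if (pre <= 0).any():
        raise ValueError("pre-treatment score must be > 0 for all included samples")
    improvement = 100.0 * (pre - sub[post_col].to_numpy(dtype=float)) / pre
    carrier = sub[carrier_flag].to_numpy(dtype=bool)
    g1, g0 = improvement[carrier], improvement[~carrier]
    if len(g1) < 2 or len(g0) < 2:
        return TreatmentResult(np.nan, 0, np.nan,
                               float(np.mean(g1)) if len(g1) else np.nan,
                               float(np.mean(g0)) if len(g0) else np.nan,
                               len(g1), len(g0), skipped=True)
    if np.var(g1) == 0 and np.var(g0) == 0:
        # degenerate: no within-group variance; equal means -> no signal
        t, p = (0.0, 1.0) if np.mean(g1) == np.mean(g0) else (np.inf, 0.0)
    else:
        t, p = stats.ttest_ind(g1, g0, equal_var=True)
    return TreatmentResult(float(t), len(g1) + len(g0) - 2, float(p),
                           float(np.mean(g1)), float(np.mean(g0)),
                           len(g1), len(g0))
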