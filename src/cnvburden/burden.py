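"""Per-sample burden metrics and covariate-adjusted global burden tests.

The modelling surface follows the statsmodels idiom: build a
:class:`CnvBurdenModel` from a sample sheet plus one burden metric, call
``fit()`` and get a :class:`CnvBurdenResults` carrying the estimate on its
reported scale (odds ratio per metric unit for the logistic model, excess
per case for the linear model), its Wald 95% interval, p-value, diagnostics
and a ``summary()`` table; leave-one-out refits hang off the model.

The logistic burden model regresses case status on the covariates plus the
metric; the linear model regresses the metric on the covariates plus case
status, so its case coefficient is the covariate-adjusted excess per case.
The default covariate set is PC1-PC5 and sex, optionally augmented by
:func:`select_covariates`, which admits a candidate (PCs 6-20, LRRSD) only
if it is associated (p < 0.05) with both the raw call count and case
status.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .types import CnvCall, RegionSet

__all__ = [
    "BASE_COVARIATES", "CANDIDATE_COVARIATES", "BurdenConfig",
    "compute_burden_metrics", "select_covariates",
    "CnvBurdenModel", "CnvBurdenResults",
    "logistic_burden_test", "linear_excess_test", "leave_one_out_burden",
]

BASE_COVARIATES = ("PC1", "PC2", "PC3", "PC4", "PC5", "SEX")
CANDIDATE_COVARIATES = tuple(f"PC{i}" for i in range(6, 21)) + ("LRRSD",)

# column spellings used in model formulas vs the sample sheet
_COLUMN_OF = {"SEX": "sex", "LRRSD": "lrrsd"}


@dataclass(frozen=True)
class BurdenConfig:
    """Partition thresholds for the burden-metric table."""
    pli_thresholds: tuple = (0.5, 0.9, 0.995)
    gene_sets: tuple = ("ndd_kendall", "ndd_fu", "haplosensitive", "triplosensitive")
    size_bins: tuple = ((30_000, 100_000), (100_000, 1_000_000), (1_000_000, None))
    constraint_thresholds: tuple = (2.0, 4.0, 6.0)


def _size_bin_name(lo, hi):
    def fmt(x):
        return f"{x // 1_000_000}mb" if x % 1_000_000 == 0 else f"{x // 1000}kb"
    return f"{fmt(lo)}_{fmt(hi)}" if hi else f"gt_{fmt(lo)}"


def compute_burden_metrics(calls: list[CnvCall], samples: pd.DataFrame,
                           genes: RegionSet, constraint: RegionSet,
                           clusters=None,
                           cfg: BurdenConfig = BurdenConfig()) -> pd.DataFrame:
    """Per-sample burden-metric table (samples x metrics).

    ``calls`` must be cascade survivors; ``clusters`` (from the frequency
    filter) supply carrier counts for the singleton partition.  Every
    metric is a deterministic function of a sample's surviving calls and
    the annotation. Emitted metric families:

    * counts: ``cnv_count``, ``del_count``, ``dup_count``;
    * genomic extent per 100 kb: ``del_bp_100kb``, ``dup_bp_100kb``;
    * distinct genes overlapped: ``del_genes``, ``dup_genes``;
    * calls overlapping >= 1 gene above each pLI threshold and in each gene
      set, per CNV type (``del_pli_gt_0.995`` ...);
    * size-bin counts, coding/noncoding split (>= 1 bp of any gene vs
      none), singleton counts (cluster carrier count 1);
    * constrained kb impacted above each constraint-score threshold, per
      CNV type (``del_constrained_kb_ge_4.0`` ...).
    """
    if genes is None or constraint is None:
        raise ValueError("gene and constraint annotation are required")
    gene_df = genes.df
    # per-call cluster carrier count (for the singleton metric)
    carrier_count_of_call: dict[int, int] = {}
    if clusters is not None:
        # clusters index the *flagged* callset; map via identity of calls
        for cl in clusters:
            for i in cl.member_idx:
                carrier_count_of_call[i] = cl.n_carriers

    sids = samples["sample_id"].tolist()
    cols: dict[str, dict] = {}

    def bump(metric, sid, by=1.0):
        cols.setdefault(metric, {})[sid] = cols.get(metric, {}).get(sid, 0.0) + by

    by_type_geneset = [(t, f"pli_gt_{thr}",
                        (gene_df["pli"] > thr).to_numpy())
                       for t in ("del", "dup") for thr in cfg.pli_thresholds]
    by_type_geneset += [(t, gs, gene_df[gs].to_numpy(dtype=bool))
                        for t in ("del", "dup") for gs in cfg.gene_sets]

    cons_start = constraint.df["start"].to_numpy()
    cons_end = constraint.df["end"].to_numpy()
    cons_score = constraint.df["score"].to_numpy()

    call_list = calls if not isinstance(calls, tuple) else list(calls)
    for idx, c in enumerate(call_list):
        t = c.cnv_type
        sid = c.sample_id
        bump("cnv_count", sid)
        bump(f"{t}_count", sid)
        bump(f"{t}_bp_100kb", sid, c.length_bp / 1e5)
        hit_rows = genes.overlapping_rows(c.chrom, c.start, c.end)
        if len(hit_rows):
            bump(f"{t}_genes", sid, float(len(hit_rows)))
            bump("coding_count", sid)
            bump(f"{t}_coding_count", sid)
        else:
            bump("noncoding_count", sid)
            bump(f"{t}_noncoding_count", sid)
        for tt, name, eligible in by_type_geneset:
            if tt == t and len(hit_rows) and eligible[hit_rows].any():
                bump(f"{t}_{name}", sid)
        for lo, hi in cfg.size_bins:
            if c.length_bp >= lo and (hi is None or c.length_bp < hi):
                bump(f"size_{_size_bin_name(lo, hi)}", sid)
                bump(f"{t}_size_{_size_bin_name(lo, hi)}", sid)
        if carrier_count_of_call.get(idx, 0) == 1:
            bump("singleton_count", sid)
            bump(f"{t}_singleton_count", sid)
        # constrained bases impacted, in kb, above each score threshold
        crows = constraint.overlapping_rows(c.chrom, c.start, c.end)
        if len(crows):
            ov = (np.minimum(cons_end[crows], c.end)
                  - np.maximum(cons_start[crows], c.start) + 1)
            sc = cons_score[crows]
            for thr in cfg.constraint_thresholds:
                bp = float(ov[sc >= thr].sum())
                if bp > 0:
                    bump(f"{t}_constrained_kb_ge_{thr}", sid, bp / 1000.0)

    metric_names = sorted(cols)
    out = pd.DataFrame(index=pd.Index(sids, name="sample_id"))
    for m in metric_names:
        out[m] = pd.Series(cols[m])
    expected = (["cnv_count", "del_count", "dup_count", "del_bp_100kb",
                 "dup_bp_100kb", "del_genes", "dup_genes", "coding_count",
                 "noncoding_count", "singleton_count"]
                + [f"{t}_{name}" for t, name, _ in by_type_geneset]
                + [f"size_{_size_bin_name(lo, hi)}" for lo, hi in cfg.size_bins]
                + [f"{t}_constrained_kb_ge_{thr}" for t in ("del", "dup")
                   for thr in cfg.constraint_thresholds])
    for m in expected:
        if m not in out.columns:
            out[m] = 0.0
    return out.fillna(0.0)


# ---------------------------------------------------------------------------
# covariate screening


def _column(samples: pd.DataFrame, name: str) -> np.ndarray:
    col = _COLUMN_OF.get(name, name)
    if col == "sex":
        return (samples["sex"] == "M").to_numpy(dtype=float)
    return samples[col].to_numpy(dtype=float)


def select_covariates(samples: pd.DataFrame, raw_call_counts: pd.Series,
                      candidates: tuple = CANDIDATE_COVARIATES,
                      base: tuple = BASE_COVARIATES,
                      alpha: float = 0.05) -> list[str]:
    """Screen candidate covariates into the burden model.

    A candidate joins the model when it is associated (p < ``alpha``) with
    the raw CNV call count (univariate linear regression) AND with case
    status (univariate logistic regression).  Constant columns are skipped
    with a warning.  Returns base + selected, in order.
    """
    y_count = raw_call_counts.reindex(samples["sample_id"]).to_numpy(dtype=float)
    y_case = samples["is_case"].to_numpy(dtype=float)
    chosen = list(base)
    for cand in candidates:
        x = _column(samples, cand)
        if np.ptp(x) == 0:
            warnings.warn(f"candidate covariate {cand} is constant; skipped")
            continue
        X = sm.add_constant(x)
        p_lin = sm.OLS(y_count, X).fit().pvalues[1]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p_log = sm.Logit(y_case, X).fit(disp=0).pvalues[1]
        except Exception:
            p_log = 0.0  # perfect separation: maximally associated
        if p_lin < alpha and p_log < alpha:
            chosen.append(cand)
    return chosen


# ---------------------------------------------------------------------------
# the burden model


@dataclass
class CnvBurdenResults:
    """Fit results for one burden metric.

    ``estimate`` is on the reported scale: an odds ratio per metric unit
    for the logistic model, the covariate-adjusted excess per case for the
    linear model; ``ci_95`` brackets it on the same scale.
    """
    metric: str
    model: str                       # "logistic" | "linear"
    estimate: float
    ci_95: tuple
    p_value: float
    n_cases: int
    n_controls: int
    covariates: tuple
    coef: float = np.nan             # raw coefficient (log-odds for logistic)
    se: float = np.nan
    separation: bool = False
    label: str = ""                  # e.g. the held-out dataset in LOO
    sm_results: object = None

    def summary(self) -> str:
        scale = "OR" if self.model == "logistic" else "excess/case"
        lines = [
            f"CNV burden test: {self.metric} [{self.model}]"
            + (f" ({self.label})" if self.label else ""),
            f"  n = {self.n_cases} cases / {self.n_controls} controls",
            f"  covariates: {', '.join(self.covariates) or 'none'}",
            f"  {scale} = {self.estimate:.4g}  "
            f"95% CI ({self.ci_95[0]:.4g}, {self.ci_95[1]:.4g})  "
            f"P = {self.p_value:.3g}",
        ]
        if self.separation:
            lines.append("  WARNING: separation detected; CI unbounded")
        return "\n".join(lines)


class CnvBurdenModel:
    """Covariate-adjusted global burden model for one metric.

    Parameters
    ----------
    samples : sample sheet DataFrame (one row per QC-pass sample)
    metric : per-sample metric values, aligned to ``samples`` by sample_id
        (a Series indexed by sample_id, or a column name already present).
    covariates : model covariates (sample-sheet spellings; ``SEX`` and
        ``LRRSD`` map to the sex/lrrsd columns). Default PC1-PC5 + SEX.
    model : "logistic" (case status ~ covariates + metric) or "linear"
        (metric ~ covariates + case status).
    """

    def __init__(self, samples: pd.DataFrame, metric, metric_name: str | None = None,
                 covariates: tuple = BASE_COVARIATES, model: str = "logistic"):
        if model not in ("logistic", "linear"):
            raise ValueError("model must be 'logistic' or 'linear'")
        self.samples = samples.reset_index(drop=True)
        if isinstance(metric, str):
            self.metric_name = metric
            self.metric = self.samples[metric].to_numpy(dtype=float)
        else:
            self.metric_name = metric_name or getattr(metric, "name", "metric")
            self.metric = (metric.reindex(self.samples["sample_id"]).to_numpy(dtype=float)
                           if isinstance(metric, pd.Series)
                           else np.asarray(metric, dtype=float))
        if not np.isfinite(self.metric).all():
            raise ValueError("metric contains non-finite values")
        self.covariates = tuple(covariates)
        self.model = model
        y = self.samples["is_case"].to_numpy(dtype=float)
        if model == "logistic" and len(np.unique(y)) < 2:
            raise ValueError("case status has a single class")

    @classmethod
    def from_metrics(cls, samples: pd.DataFrame, metrics: pd.DataFrame,
                     metric: str, **kw) -> "CnvBurdenModel":
        """Build from the table produced by :func:`compute_burden_metrics`."""
        return cls(samples, metrics[metric], metric_name=metric, **kw)

    # -- design ----------------------------------------------------------
    def _design(self, samples: pd.DataFrame, metric: np.ndarray):
        cols = {"const": np.ones(len(samples))}
        for name in self.covariates:
            cols[name] = _column(samples, name)
        if self.model == "logistic":
            cols[self.metric_name] = metric
            X = pd.DataFrame(cols)
            y = samples["is_case"].to_numpy(dtype=float)
            key = self.metric_name
        else:
            cols["is_case"] = samples["is_case"].to_numpy(dtype=float)
            X = pd.DataFrame(cols)
            y = metric
            key = "is_case"
        return y, X, key

    @staticmethod
    def _check_rank(X: pd.DataFrame):
        arr = X.to_numpy()
        if np.linalg.matrix_rank(arr) == arr.shape[1]:
            return
        bad = []
        for j in range(1, arr.shape[1]):
            sub = arr[:, : j + 1]
            if np.linalg.matrix_rank(sub) < sub.shape[1]:
                bad.append(X.columns[j])
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")

    # -- fitting ---------------------------------------------------------
    def fit(self, label: str = "") -> CnvBurdenResults:
        return self._fit(self.samples, self.metric, label)

    def _fit(self, samples: pd.DataFrame, metric: np.ndarray,
             label: str = "") -> CnvBurdenResults:
        y, X, key = self._design(samples, metric)
        n_cases = int(samples["is_case"].sum())
        n_controls = len(samples) - n_cases
        if self.model == "linear":
            self._check_rank(X)
            res = sm.OLS(y, X).fit()
            coef, se = res.params[key], res.bse[key]
            lo, hi = coef - 1.96 * se, coef + 1.96 * se
            return CnvBurdenResults(
                metric=self.metric_name, model="linear", estimate=float(coef),
                ci_95=(float(lo), float(hi)), p_value=float(res.pvalues[key]),
                n_cases=n_cases, n_controls=n_controls,
                covariates=self.covariates, coef=float(coef), se=float(se),
                label=label, sm_results=res)
        separation = False
        res = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            except Exception:
                separation = True
        if res is not None:
            coef, se = float(res.params[key]), float(res.bse[key])
            if not np.isfinite(se) or se > 50 or abs(coef) > 20 or not res.mle_retvals.get("converged", True):
                separation = True
        if separation:
            coef = np.inf if res is None else float(res.params[key])
            return CnvBurdenResults(
                metric=self.metric_name, model="logistic",
                estimate=float(np.exp(coef)) if np.isfinite(coef) else np.inf,
                ci_95=(0.0, np.inf), p_value=np.nan, n_cases=n_cases,
                n_controls=n_controls, covariates=self.covariates,
                coef=coef, se=np.inf, separation=True, label=label,
                sm_results=res)
        lo, hi = coef - 1.96 * se, coef + 1.96 * se
        return CnvBurdenResults(
            metric=self.metric_name, model="logistic",
            estimate=float(np.exp(coef)),
            ci_95=(float(np.exp(lo)), float(np.exp(hi))),
            p_value=float(res.pvalues[key]), n_cases=n_cases,
            n_controls=n_controls, covariates=self.covariates,
            coef=coef, se=se, label=label, sm_results=res)

    # -- robustness refits ----------------------------------------------
    def leave_one_out(self) -> list[CnvBurdenResults]:
        """One refit per held-out dataset plus one per dropped covariate.

        A held-out fit whose outcome collapses to a single class is
        flagged (separation=True result with NaN estimate) and skipped.
        """
        datasets = self.samples["dataset"].unique()
        if len(datasets) < 2:
            raise ValueError("leave-one-out requires >= 2 datasets")
        results = []
        for ds in datasets:
            keep = self.samples["dataset"] != ds
            sub = self.samples[keep].reset_index(drop=True)
            metric = self.metric[keep.to_numpy()]
            if sub["is_case"].nunique() < 2:
                results.append(CnvBurdenResults(
                    metric=self.metric_name, model=self.model,
                    estimate=np.nan, ci_95=(np.nan, np.nan), p_value=np.nan,
                    n_cases=int(sub["is_case"].sum()),
                    n_controls=int((~sub["is_case"]).sum()),
                    covariates=self.covariates, separation=True,
                    label=f"drop_dataset:{ds}"))
                continue
            results.append(self._fit(sub, metric, label=f"drop_dataset:{ds}"))
        for cov in self.covariates:
            reduced = CnvBurdenModel(self.samples, pd.Series(self.metric,
                                     index=self.samples["sample_id"]),
                                     metric_name=self.metric_name,
                                     covariates=tuple(c for c in self.covariates
                                                      if c != cov),
                                     model=self.model)
            results.append(reduced.fit(label=f"drop_covariate:{cov}"))
        return results


# ---------------------------------------------------------------------------
# functional wrappers


def logistic_burden_test(metric, samples: pd.DataFrame,
                         covariates: tuple = BASE_COVARIATES,
                         metric_name: str | None = None) -> CnvBurdenResults:
    """Logistic fit of case status on covariates + metric; OR per unit."""
    return CnvBurdenModel(samples, metric, metric_name=metric_name,
                          covariates=covariates, model="logistic").fit()


def linear_excess_test(metric, samples: pd.DataFrame,
                       covariates: tuple = BASE_COVARIATES,
                       metric_name: str | None = None) -> CnvBurdenResults:
    """OLS of metric on covariates + case status; excess per case."""
    return CnvBurdenModel(samples, metric, metric_name=metric_name,
                          covariates=covariates, model="linear").fit()


def leave_one_out_burden(metric, samples: pd.DataFrame,
                         covariates: tuple = BASE_COVARIATES,
                         model: str = "logistic") -> list[CnvBurdenResults]:
    return CnvBurdenModel(samples, metric, covariates=covariates,
                          model=model).leave_one_out()
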