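"""Sample-level QC on intensity metrics and raw CNV call load.

Two pruning stages, mirroring array-CNV practice:

1. :func:`prune_intensity_outliers` — within each dataset, a sample is an
   outlier if any of LRRSD, absolute waviness factor or BAF drift falls
   beyond 3 standard deviations of the dataset mean (single pass: the mean
   and SD are computed once, never recomputed after removals).  Any
   survivor violating the hard bounds (LRRSD <= 0.2, absWF <= 0.02,
   BAF drift <= 0.001) is additionally removed.
2. :func:`prune_call_outliers` — a sample is removed if the genomic
   footprint of its raw consensus calls (the union of intervals, not their
   sum) exceeds 20 Mb, or if it has more than 20 separate raw calls.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .intervals import union_length
from .types import CnvCall

__all__ = ["QcReport", "prune_intensity_outliers", "prune_call_outliers",
           "run_sample_qc", "HARD_BOUNDS"]

#: Hard per-sample bounds every retained sample must satisfy.
HARD_BOUNDS = {"lrrsd": 0.2, "abs_wf": 0.02, "baf_drift": 0.001}

_REASON_OF_METRIC = {"lrrsd": "LRRSD_OUTLIER", "abs_wf": "WF_OUTLIER",
                     "baf_drift": "DRIFT_OUTLIER"}

MAX_RAW_CALL_BP = 20_000_000
MAX_RAW_CALLS = 20


@dataclass
class QcReport:
    """Per-sample QC outcome; ``removed`` iff ``reasons`` is non-empty."""
    sample_id: str
    removed: bool = False
    reasons: set = field(default_factory=set)
    dataset_stats: dict = field(default_factory=dict)

    def add(self, reason: str) -> None:
        self.reasons.add(reason)
        self.removed = True


def prune_intensity_outliers(samples: pd.DataFrame,
                             n_sd: float = 3.0) -> dict[str, QcReport]:
    """Flag per-dataset 3-SD outliers on intensity metrics, then enforce
    the hard bounds on survivors.

    Raises ``ValueError`` naming any dataset with fewer than 2 samples
    (its SD is undefined).
    """
    reports = {sid: QcReport(sid) for sid in samples["sample_id"]}
    for ds, sub in samples.groupby("dataset"):
        if len(sub) < 2:
            raise ValueError(f"dataset {ds!r} has fewer than 2 samples; SD undefined")
        stats = {}
        for metric, reason in _REASON_OF_METRIC.items():
            x = sub[metric].to_numpy(dtype=float)
            mean, sd = float(x.mean()), float(x.std(ddof=1))
            stats[metric] = (mean, sd)
            flagged = np.abs(x - mean) > n_sd * sd
            for sid in sub["sample_id"].to_numpy()[flagged]:
                reports[sid].add(reason)
        for sid in sub["sample_id"]:
            reports[sid].dataset_stats = stats
        # hard bounds on survivors of the SD rule
        for metric, bound in HARD_BOUNDS.items():
            x = sub[metric].to_numpy(dtype=float)
            for sid, v in zip(sub["sample_id"], x):
                if not reports[sid].removed and v > bound:
                    reports[sid].add(_REASON_OF_METRIC[metric])
    return reports


def prune_call_outliers(samples: pd.DataFrame,
                        raw_calls: Iterable[CnvCall]) -> dict[str, QcReport]:
    """Flag samples whose raw call load is extreme.

    Footprint is the union of call intervals per sample ("occupied"
    basepairs), so fully overlapping calls count once. Thresholds are
    strict: > 20 Mb of footprint or > 20 separate calls.
    """
    by_sample: dict[str, list[CnvCall]] = defaultdict(list)
    for call in raw_calls:
        by_sample[call.sample_id].append(call)
    reports = {sid: QcReport(sid) for sid in samples["sample_id"]}
    for sid, calls in by_sample.items():
        if sid not in reports:
            continue
        if len(calls) > MAX_RAW_CALLS:
            reports[sid].add("CALL_COUNT")
        total_bp = 0
        by_chrom: dict[str, list] = defaultdict(list)
        for c in calls:
            by_chrom[c.chrom].append((c.start, c.end))
        for ivs in by_chrom.values():
            total_bp += union_length(ivs)
        if total_bp > MAX_RAW_CALL_BP:
            reports[sid].add("CALL_BP")
    return reports


def run_sample_qc(samples: pd.DataFrame, raw_calls: Iterable[CnvCall],
                  n_sd: float = 3.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Both stages combined.

    Returns ``(kept_samples, report_table)`` where the report table has one
    row per input sample with ``removed`` and comma-joined ``reasons``.
    """
    intensity = prune_intensity_outliers(samples, n_sd=n_sd)
    load = prune_call_outliers(samples, raw_calls)
    rows = []
    for sid in samples["sample_id"]:
        reasons = intensity[sid].reasons | load[sid].reasons
        rows.append({"sample_id": sid, "removed": bool(reasons),
                     "reasons": ",".join(sorted(reasons))})
    report = pd.DataFrame(rows)
    kept = samples[~samples["sample_id"].isin(
        report.loc[report["removed"], "sample_id"])].reset_index(drop=True)
    return kept, report
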