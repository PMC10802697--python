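"""Core domain containers for the CNV burden pipeline.

A *call* is a non-diploid copy-number segment in one sample.  Calls travel
through the pipeline as lists of :class:`CnvCall`; region annotations
(genes, repeat masks, constraint tracks) as :class:`RegionSet`; per-probe
positions and signal as :class:`ProbeMap`.  Sample metadata (case status,
dataset, country, sex, intensity metrics, principal components, polygenic
scores, clinical fields) lives in a pandas sample-sheet DataFrame validated
by :func:`validate_sample_sheet`.

Coordinates are 1-based inclusive everywhere inside the package; BED input
is converted on read.  Only autosomes are analysed: the callers' sex-
chromosome behaviour is not modelled and the control cohorts are heavily
sex-imbalanced, so chrX/chrY calls are rejected up front (configurable via
``allowed_chroms``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .intervals import merge_intervals

#: Default analysis chromosomes: autosomes 1..22.
AUTOSOMES = tuple(str(i) for i in range(1, 23))

#: Copy states accepted in call files. Diploid (2) is disallowed: a call is
#: by definition non-diploid, and silently carrying CN=2 records would make
#: the deletion/duplication dichotomy ill-defined.
VALID_COPY_STATES = (0, 1, 3, 4)

#: Strata used by the stratified exact tests: (country, sex).
STRATA = (("SWE", "M"), ("SWE", "F"), ("NOR", "M"), ("NOR", "F"))


def normalize_chrom(chrom: str) -> str:
    """Strip a 'chr' prefix so 'chr1' and '1' compare equal."""
    c = str(chrom)
    return c[3:] if c.lower().startswith("chr") else c


@dataclass(frozen=True)
class CnvCall:
    """One CNV call in one sample (1-based inclusive interval).

    ``copy_state`` < 2 marks a deletion, > 2 a duplication. ``filter_flags``
    accumulates the names of every filter the call fails; a call with an
    empty flag set is an analysis-ready survivor.
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    copy_state: int
    n_probes: int
    caller: str = "consensus"  # one of {"A", "B", "consensus"}
    filter_flags: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError(
                f"call {self.sample_id} {self.chrom}:{self.start}-{self.end}: end < start"
            )
        if self.copy_state not in VALID_COPY_STATES:
            raise ValueError(f"invalid copy state {self.copy_state} (diploid calls disallowed)")
        if self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    @property
    def cnv_type(self) -> str:
        """'del' for copy state < 2, 'dup' for > 2."""
        return "del" if self.copy_state < 2 else "dup"

    def with_flags(self, *flags: str) -> "CnvCall":
        return replace(self, filter_flags=self.filter_flags | frozenset(flags))


#: Flags that annotate but do not remove a call.
NON_REMOVAL_FLAGS = frozenset({"BAF_UNTESTED"})


def survivors(calls: Iterable[CnvCall]) -> list[CnvCall]:
    """Calls with no removal flags (the analysis-ready set)."""
    return [c for c in calls if not (c.filter_flags - NON_REMOVAL_FLAGS)]


class RegionSet:
    """A named set of genomic intervals with optional per-interval payload.

    Stored as a DataFrame with columns ``chrom, start, end`` (1-based
    inclusive) plus any payload columns (``gene_id``, ``pli``, gene-set
    flags, ``score`` ...), sorted by (chrom, start). Construction merges
    overlapping or abutting intervals that carry identical payload.
    """

    def __init__(self, name: str, df: pd.DataFrame, merge: bool = True):
        required = {"chrom", "start", "end"}
        if not required.issubset(df.columns):
            raise ValueError(f"RegionSet '{name}' missing columns {required - set(df.columns)}")
        df = df.copy()
        df["chrom"] = df["chrom"].map(normalize_chrom)
        if len(df) and (df["end"] < df["start"]).any():
            raise ValueError(f"RegionSet '{name}': interval with end < start")
        if "pli" in df.columns and len(df):
            pli = df["pli"].dropna()
            if len(pli) and ((pli < 0) | (pli > 1)).any():
                raise ValueError("pLI values must lie in [0, 1]")
        if merge and len(df):
            df = self._merge_same_payload(df)
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
        self.name = name
        self.df = df
        # per-chromosome caches: merged intervals for coverage queries and
        # raw start/end/row arrays for overlap queries
        self._merged: dict[str, np.ndarray] = {}
        self._by_chrom: dict[str, tuple] = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            self._merged[chrom] = merge_intervals(sub[["start", "end"]].to_numpy())
            self._by_chrom[chrom] = (sub["start"].to_numpy(),
                                     sub["end"].to_numpy(),
                                     sub.index.to_numpy())

    @staticmethod
    def _merge_same_payload(df: pd.DataFrame) -> pd.DataFrame:
        payload_cols = [c for c in df.columns if c not in ("chrom", "start", "end")]
        out_rows = []
        keys = ["chrom"] + payload_cols
        for _, sub in df.groupby(keys, dropna=False, sort=False):
            sub = sub.sort_values(["start", "end"])
            merged = merge_intervals(sub[["start", "end"]].to_numpy())
            proto = sub.iloc[0]
            for s, e in merged:
                row = proto.to_dict()
                row["start"], row["end"] = int(s), int(e)
                out_rows.append(row)
        return pd.DataFrame(out_rows, columns=df.columns)

    def __len__(self) -> int:
        return len(self.df)

    def merged_intervals(self, chrom: str) -> np.ndarray:
        """Merged (n, 2) start/end array for one chromosome (may be empty)."""
        return self._merged.get(normalize_chrom(chrom), np.empty((0, 2), dtype=np.int64))

    def covered_bp(self, chrom: str, start: int, end: int) -> int:
        """Bases of [start, end] covered by this set's union on ``chrom``."""
        merged = self.merged_intervals(chrom)
        if merged.size == 0:
            return 0
        lo = np.maximum(merged[:, 0], start)
        hi = np.minimum(merged[:, 1], end)
        lens = hi - lo + 1
        return int(lens[lens > 0].sum())

    def overlapping_rows(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Row labels of intervals overlapping [start, end] by >= 1 bp."""
        cached = self._by_chrom.get(normalize_chrom(chrom))
        if cached is None:
            return np.empty(0, dtype=np.int64)
        starts, ends, rows = cached
        return rows[(starts <= end) & (ends >= start)]

    def overlapping(self, chrom: str, start: int, end: int) -> pd.DataFrame:
        """Rows (with payload) whose interval overlaps [start, end] by >=1 bp."""
        return self.df.loc[self.overlapping_rows(chrom, start, end)]


class ProbeMap:
    """Array probe positions and optional per-sample signal at call sites.

    Parameters
    ----------
    probes : DataFrame with columns chrom, pos, probe_id
        Positions must be strictly increasing within each chromosome.
    signal : optional dict sample_id -> DataFrame(chrom, pos, lrr, baf)
        Marker-level signal; only emitted at call sites plus flanks, so
        lookups for probes without signal return nothing.
    """

    def __init__(self, probes: pd.DataFrame, signal: dict | None = None):
        probes = probes.copy()
        probes["chrom"] = probes["chrom"].map(normalize_chrom)
        probes = probes.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        for chrom, sub in probes.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"probe positions not strictly increasing on chrom {chrom}")
        self.probes = probes
        self._pos: dict[str, np.ndarray] = {
            chrom: sub["pos"].to_numpy() for chrom, sub in probes.groupby("chrom", sort=False)
        }
        self.signal = signal or {}
        for sid, df in self.signal.items():
            if len(df) and ((df["baf"] < 0) | (df["baf"] > 1)).any():
                raise ValueError(f"BAF outside [0,1] for sample {sid}")

    def n_probes_in(self, chrom: str, start: int, end: int) -> int:
        """Number of array probes inside the inclusive interval."""
        pos = self._pos.get(normalize_chrom(chrom))
        if pos is None:
            return 0
        return int(np.searchsorted(pos, end, side="right") - np.searchsorted(pos, start, side="left"))

    def sample_signal(self, sample_id: str, chrom: str, start: int, end: int) -> pd.DataFrame:
        """Per-probe (pos, lrr, baf) for one carrier inside an interval."""
        df = self.signal.get(sample_id)
        if df is None or len(df) == 0:
            return pd.DataFrame(columns=["pos", "lrr", "baf"])
        chrom = normalize_chrom(chrom)
        sub = df[(df["chrom"] == chrom) & (df["pos"] >= start) & (df["pos"] <= end)]
        return sub[["pos", "lrr", "baf"]]


SAMPLE_SHEET_CORE = ["sample_id", "is_case", "dataset", "country", "sex",
                     "lrrsd", "abs_wf", "baf_drift"]
PC_COLUMNS = [f"PC{i}" for i in range(1, 21)]


def validate_sample_sheet(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a sample sheet.

    Requires the core identity/metric columns and PC1..PC20; enforces
    non-negative intensity metrics, country in {SWE, NOR}, sex in {M, F}
    and unique sample IDs. Returns a copy with ``is_case`` as bool.
    """
    missing = [c for c in SAMPLE_SHEET_CORE + PC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns: {missing}")
    df = df.copy()
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample IDs: {dupes[:5]}")
    bad_country = set(df["country"]) - {"SWE", "NOR"}
    if bad_country:
        raise ValueError(f"unknown country codes: {bad_country}")
    bad_sex = set(df["sex"]) - {"M", "F"}
    if bad_sex:
        raise ValueError(f"unknown sex codes: {bad_sex}")
    for col in ("lrrsd", "abs_wf", "baf_drift"):
        if (df[col] < 0).any():
            raise ValueError(f"negative values in {col}")
    df["is_case"] = df["is_case"].astype(bool)
    return df


def stratum_labels(samples: pd.DataFrame) -> pd.Series:
    """(country, sex) stratum label per sample, e.g. 'SWE_F'."""
    return samples["country"].astype(str) + "_" + samples["sex"].astype(str)
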