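"""Readers and writers for the pipeline's tabular formats.

Formats supported:

* CNV call TSV (PennCNV-style dialect): columns ``chrom start end copy_state
  n_probes sample_id``, 1-based inclusive, one call per row.
* BED region files (0-based half-open), converted on read to the internal
  1-based inclusive convention, with optional payload columns.
* Gene annotation TSV: ``gene_id chrom start end pli`` plus 0/1 gene-set
  flag columns (``ndd_kendall ndd_fu haplosensitive triplosensitive``).
* Constraint TSV: ``chrom start end score`` (per-base constraint, e.g. a
  phyloP-derived track collapsed into scored intervals).
* External CNV frequency reference TSV: ``chrom start end cnv_type`` plus
  one or more ``freq_*`` columns (global and subpopulation frequencies).
* Sample sheet TSV (see :func:`cnvburden.types.validate_sample_sheet`).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from .types import (
    AUTOSOMES,
    CnvCall,
    RegionSet,
    normalize_chrom,
    validate_sample_sheet,
)

CALL_COLUMNS = ["chrom", "start", "end", "copy_state", "n_probes", "sample_id"]


class ParseError(ValueError):
    """A malformed row in an input file; the message names the row."""


def read_cnv_calls(path, caller_label: str = "consensus",
                   allowed_chroms: tuple = AUTOSOMES) -> list[CnvCall]:
    """Read a PennCNV-style call TSV into validated :class:`CnvCall` records.

    Rows on chromosomes outside ``allowed_chroms`` (default: autosomes) are
    rejected; malformed rows raise :class:`ParseError` naming the row number
    (1-based, excluding the header).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        return []
    missing = [c for c in CALL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    calls = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            chrom = normalize_chrom(row.chrom)
            if chrom not in allowed_chroms:
                raise ValueError(f"chromosome {row.chrom!r} not analysed")
            call = CnvCall(
                sample_id=str(row.sample_id),
                chrom=chrom,
                start=int(row.start),
                end=int(row.end),
                copy_state=int(row.copy_state),
                n_probes=int(row.n_probes),
                caller=caller_label,
            )
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path} row {i}: {exc}") from exc
        calls.append(call)
    return calls


def write_cnv_calls(calls: Iterable[CnvCall], path) -> None:
    """Write calls back out in the same TSV dialect (flags in an extra column)."""
    rows = [
        {
            "chrom": c.chrom, "start": c.start, "end": c.end,
            "copy_state": c.copy_state, "n_probes": c.n_probes,
            "sample_id": c.sample_id, "caller": c.caller,
            "filter_flags": ",".join(sorted(c.filter_flags)),
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=CALL_COLUMNS + ["caller", "filter_flags"]).to_csv(
        path, sep="\t", index=False
    )


def read_bed_regions(path, name: str, allowed_chroms: tuple | None = None) -> RegionSet:
    """Read a BED file (0-based half-open) into a 1-based inclusive RegionSet.

    Columns beyond the first three are kept as payload; overlapping or
    abutting intervals with identical payload are merged. A BED row with
    start >= end describes an empty interval and is rejected.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return RegionSet(name, pd.DataFrame(columns=["chrom", "start", "end"]))
    ncol = df.shape[1]
    cols = ["chrom", "start", "end"] + [f"col{i}" for i in range(3, ncol)]
    df.columns = cols
    if (df["start"] >= df["end"]).any():
        bad = df.index[df["start"] >= df["end"]][0]
        raise ParseError(f"{path} row {bad + 1}: BED start >= end (empty interval)")
    # BED 0-based half-open [start, end) -> 1-based inclusive [start+1, end]
    df["start"] = df["start"].astype(int) + 1
    df["end"] = df["end"].astype(int)
    if allowed_chroms is not None:
        df = df[df["chrom"].map(normalize_chrom).isin(allowed_chroms)]
    return RegionSet(name, df)


def write_bed_regions(regions: RegionSet, path) -> None:
    """Write a RegionSet as BED (converting back to 0-based half-open)."""
    df = regions.df.copy()
    df["start"] = df["start"] - 1
    df.to_csv(path, sep="\t", header=False, index=False)


def read_gene_annotation(path, name: str = "genes") -> RegionSet:
    """Gene annotation TSV -> RegionSet with gene_id/pli/gene-set payload."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "start", "end", "pli"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return RegionSet(name, df, merge=False)


def read_constraint_track(path, name: str = "constraint") -> RegionSet:
    """Constraint score TSV (chrom, start, end, score) -> RegionSet."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "score"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return RegionSet(name, df, merge=False)


def read_frequency_reference(path) -> pd.DataFrame:
    """External CNV frequency table (gnomAD-like): interval, type, freq_* columns."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "cnv_type"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    freq_cols = [c for c in df.columns if c.startswith("freq_")]
    if not freq_cols:
        raise ParseError(f"{path}: no freq_* columns")
    df["chrom"] = df["chrom"].map(normalize_chrom)
    return df


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return validate_sample_sheet(df)


def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index=False)
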