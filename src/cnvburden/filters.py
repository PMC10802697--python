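"""Two-caller consensus and the CNV filter cascade.

The cascade takes the consensus callset and assigns *audit flags*; it never
deletes calls.  Every filter is computed on the full consensus callset (not
on survivors of prior filters), so flag assignment is order-independent and
the analysis-ready set is exactly the calls with zero flags:

* ``SIZE`` — fewer than 15 probes or shorter than 30 kb (inclusive bounds
  kept: 15 probes / 30,000 bp survive);
* one flag per region mask — coverage > 30% for telomere/centromere
  buffers, polyN, segmental duplications and repeat classes; any overlap
  (> 0 bp) for T-cell-receptor/immunoglobulin loci and known
  lymphoblastoid-cell-line artifact loci;
* ``FREQ_INTERNAL`` — the call's locus cluster (single-linkage at >= 50%
  reciprocal overlap, same CNV direction) reaches >= 1% carrier frequency
  in the combined cohort or in any single dataset;
* ``FREQ_EXTERNAL`` — the call matches (same direction, >= 50% reciprocal
  overlap) an external reference record with any listed frequency >= 1%;
* ``BAF_REJECT`` / ``BAF_UNTESTED`` — marker-level B-allele-frequency
  validation: a deletion must not show a heterozygous band, a duplication
  must concentrate its mid-range BAFs near 1/3 and 2/3;
* ``INFLATION_LOCUS`` — membership in a small-deletion locus excluded by
  the iterative batch-effect screen (:func:`detect_inflation_loci`).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import reciprocal_overlap
from .types import CnvCall, ProbeMap, RegionSet

__all__ = [
    "FilterConfig", "BafParams", "LocusCluster",
    "intersect_callsets", "apply_size_filter", "fraction_overlap",
    "apply_region_filters", "cluster_calls", "cluster_and_frequency_filter",
    "baf_validate", "apply_baf_filter", "detect_inflation_loci",
    "run_filter_cascade",
]

#: Masks removed on any overlap rather than the 30% coverage rule.
ANY_OVERLAP_MASKS = ("tcr_ig", "lcl_artifact")


@dataclass(frozen=True)
class BafParams:
    """Thresholds for BAF-based call validation."""
    het_band: tuple = (0.25, 0.75)   # diploid heterozygous band
    del_het_max: float = 0.10        # max in-band fraction tolerated for a deletion
    mid_range: tuple = (0.10, 0.90)  # informative range for duplications
    dup_band_lo: tuple = (0.20, 0.45)
    dup_band_hi: tuple = (0.55, 0.80)
    dup_band_min: float = 0.60       # min fraction of mid-range probes in-band
    min_informative: int = 10


@dataclass(frozen=True)
class FilterConfig:
    min_probes: int = 15
    min_len_bp: int = 30_000
    region_overlap_max: float = 0.30  # strict: > 30% removed
    freq_max: float = 0.01            # >= 1% removed
    reciprocal_overlap: float = 0.50
    baf: BafParams = BafParams()
    lambda_max: float = 1.10          # inflation-screen stopping threshold
    dataset_concentration: float = 0.80
    small_del_range: tuple = (30_000, 100_000)

    def __post_init__(self):
        for name in ("region_overlap_max", "freq_max", "reciprocal_overlap"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")


@dataclass
class LocusCluster:
    """Single-linkage cluster of same-direction calls at >= 50% reciprocal
    overlap; the unit of the internal frequency filter."""
    cluster_id: int
    chrom: str
    start: int               # envelope
    end: int
    cnv_type: str
    member_idx: list = field(default_factory=list)   # indices into the callset
    carriers: set = field(default_factory=set)
    dataset_carriers: dict = field(default_factory=dict)

    @property
    def n_carriers(self) -> int:
        return len(self.carriers)


# ---------------------------------------------------------------------------
# consensus


def intersect_callsets(calls_a: list[CnvCall], calls_b: list[CnvCall],
                       probe_map: ProbeMap,
                       known_samples: set | None = None) -> list[CnvCall]:
    """Consensus of two per-sample callsets by interval intersection.

    For each sample, every pair (a in A, b in B) on the same chromosome
    with the same CNV direction that overlaps contributes its intersection;
    probe counts are recomputed over the intersected interval. Overlapping
    consensus intervals of the same direction are then merged (union
    envelope, probes recounted). Calls present in only one callset vanish.
    """
    if known_samples is not None:
        unknown = {c.sample_id for c in calls_a + calls_b} - set(known_samples)
        if unknown:
            raise ValueError(f"calls from samples absent from the sample sheet: "
                             f"{sorted(unknown)[:5]}")
    by_key_a: dict = defaultdict(list)
    for c in calls_a:
        by_key_a[(c.sample_id, c.chrom, c.cnv_type)].append(c)
    by_key_b: dict = defaultdict(list)
    for c in calls_b:
        by_key_b[(c.sample_id, c.chrom, c.cnv_type)].append(c)

    out: list[CnvCall] = []
    for key, a_list in by_key_a.items():
        b_list = by_key_b.get(key)
        if not b_list:
            continue
        sid, chrom, cnv_type = key
        pieces = []
        for a in a_list:
            for b in b_list:
                s, e = max(a.start, b.start), min(a.end, b.end)
                if s <= e:
                    # same direction but possibly different magnitude: keep
                    # the state nearer diploid (the conservative consensus)
                    state = max(a.copy_state, b.copy_state) if cnv_type == "del" \
                        else min(a.copy_state, b.copy_state)
                    pieces.append((s, e, state))
        if not pieces:
            continue
        pieces.sort()
        merged = [list(pieces[0])]
        for s, e, state in pieces[1:]:
            if s <= merged[-1][1]:  # >= 1 bp overlap merges
                merged[-1][1] = max(merged[-1][1], e)
                merged[-1][2] = max(merged[-1][2], state) if cnv_type == "del" \
                    else min(merged[-1][2], state)
            else:
                merged.append([s, e, state])
        for s, e, state in merged:
            n_probes = probe_map.n_probes_in(chrom, s, e)
            if n_probes < 1:
                continue
            out.append(CnvCall(sample_id=sid, chrom=chrom, start=int(s),
                               end=int(e), copy_state=int(state),
                               n_probes=n_probes, caller="consensus"))
    out.sort(key=lambda c: (c.chrom, c.start, c.end, c.sample_id))
    return out


# ---------------------------------------------------------------------------
# size and region filters


def apply_size_filter(calls: list[CnvCall], cfg: FilterConfig) -> list[CnvCall]:
    """Flag calls with fewer than ``min_probes`` probes or shorter than
    ``min_len_bp`` (bounds inclusive on the keep side)."""
    return [c.with_flags("SIZE")
            if (c.n_probes < cfg.min_probes or c.length_bp < cfg.min_len_bp)
            else c
            for c in calls]


def fraction_overlap(call: CnvCall, mask: RegionSet) -> float:
    """Fraction of the call's bases covered by the union of mask intervals."""
    return mask.covered_bp(call.chrom, call.start, call.end) / call.length_bp


def apply_region_filters(calls: list[CnvCall], masks: dict,
                         cfg: FilterConfig) -> list[CnvCall]:
    """Flag calls against every region mask (full audit: all masks checked).

    ``masks`` maps mask name -> RegionSet.  TCR/Ig and LCL-artifact masks
    remove on any overlap; all others on coverage strictly above
    ``region_overlap_max``.
    """
    out = []
    for c in calls:
        flags = []
        for name, mask in masks.items():
            frac = fraction_overlap(c, mask)
            if name in ANY_OVERLAP_MASKS:
                if frac > 0:
                    flags.append(name)
            elif frac > cfg.region_overlap_max:
                flags.append(name)
        out.append(c.with_flags(*flags) if flags else c)
    return out


# ---------------------------------------------------------------------------
# locus clustering and frequency filters


def cluster_calls(calls: list[CnvCall], samples: pd.DataFrame,
                  min_ro: float = 0.50,
                  restrict_idx: list | None = None) -> list[LocusCluster]:
    """Single-linkage clustering of same-direction calls at >= ``min_ro``
    reciprocal overlap.

    ``restrict_idx`` limits clustering to a subset of call indices while
    keeping cluster ``member_idx`` in the original callset's indexing.
    """
    idx = list(range(len(calls))) if restrict_idx is None else list(restrict_idx)
    ds_of = dict(zip(samples["sample_id"], samples["dataset"]))
    parent = {i: i for i in idx}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    by_group: dict = defaultdict(list)
    for i in idx:
        c = calls[i]
        by_group[(c.chrom, c.cnv_type)].append(i)
    for group in by_group.values():
        group.sort(key=lambda i: (calls[i].start, calls[i].end))
        for a_pos, i in enumerate(group):
            ci = calls[i]
            for j in group[a_pos + 1:]:
                cj = calls[j]
                if cj.start > ci.end:
                    break
                if reciprocal_overlap(ci.start, ci.end, cj.start, cj.end) >= min_ro:
                    union(i, j)

    groups: dict = defaultdict(list)
    for i in idx:
        groups[find(i)].append(i)
    clusters = []
    for cid, members in enumerate(sorted(groups.values(), key=lambda m: min(m))):
        c0 = calls[members[0]]
        carriers = {calls[i].sample_id for i in members}
        ds_counts: dict = defaultdict(set)
        for sid in carriers:
            ds_counts[ds_of.get(sid, "?")].add(sid)
        clusters.append(LocusCluster(
            cluster_id=cid, chrom=c0.chrom,
            start=min(calls[i].start for i in members),
            end=max(calls[i].end for i in members),
            cnv_type=c0.cnv_type, member_idx=sorted(members),
            carriers=carriers,
            dataset_carriers={k: len(v) for k, v in ds_counts.items()},
        ))
    return clusters


def cluster_and_frequency_filter(calls: list[CnvCall], samples: pd.DataFrame,
                                 external_ref: pd.DataFrame | None,
                                 cfg: FilterConfig
                                 ) -> tuple[list[CnvCall], list[LocusCluster]]:
    """Internal and external frequency filters.

    Internal: a call is flagged ``FREQ_INTERNAL`` when its locus cluster's
    distinct-carrier frequency reaches ``freq_max`` in the combined cohort
    or in any single input dataset (that dataset's size as denominator).
    External: ``FREQ_EXTERNAL`` when the call matches a reference record of
    the same direction at >= 50% reciprocal overlap with any ``freq_*``
    column >= ``freq_max``. Denominators come from the QC-pass sample
    sheet; a zero denominator is an error.
    """
    n_total = len(samples)
    if n_total == 0:
        raise ValueError("zero samples: frequency denominators undefined")
    ds_sizes = samples["dataset"].value_counts().to_dict()

    clusters = cluster_calls(calls, samples, min_ro=cfg.reciprocal_overlap)
    flagged_internal = set()
    for cl in clusters:
        freqs = [cl.n_carriers / n_total]
        freqs += [cnt / ds_sizes[ds] for ds, cnt in cl.dataset_carriers.items()
                  if ds in ds_sizes]
        if any(f >= cfg.freq_max for f in freqs):
            flagged_internal.update(cl.member_idx)

    flagged_external = set()
    if external_ref is not None and len(external_ref):
        freq_cols = [c for c in external_ref.columns if c.startswith("freq_")]
        common = external_ref[
            (external_ref[freq_cols] >= cfg.freq_max).any(axis=1)]
        by_chrom_type: dict = defaultdict(list)
        for row in common.itertuples(index=False):
            by_chrom_type[(str(row.chrom), row.cnv_type)].append(
                (int(row.start), int(row.end)))
        for i, c in enumerate(calls):
            for (s, e) in by_chrom_type.get((c.chrom, c.cnv_type), ()):
                if reciprocal_overlap(c.start, c.end, s, e) >= cfg.reciprocal_overlap:
                    flagged_external.add(i)
                    break

    out = []
    for i, c in enumerate(calls):
        flags = []
        if i in flagged_internal:
            flags.append("FREQ_INTERNAL")
        if i in flagged_external:
            flags.append("FREQ_EXTERNAL")
        out.append(c.with_flags(*flags) if flags else c)
    return out, clusters


# ---------------------------------------------------------------------------
# BAF validation


def baf_validate(call: CnvCall, probe_map: ProbeMap,
                 baf: BafParams = BafParams()) -> tuple[str, float]:
    """Validate one call against the carrier's marker-level BAF pattern.

    Returns ``(status, score)`` with status in {"accept", "reject",
    "untested"}.  For deletions the score is the fraction of probes in the
    diploid heterozygous band (low is good); for duplications it is the
    fraction of mid-range probes inside the 1/3 and 2/3 bands (high is
    good).  Raises ``ValueError`` if the carrier has no signal at the call
    site at all.
    """
    sig = probe_map.sample_signal(call.sample_id, call.chrom, call.start, call.end)
    if len(sig) == 0:
        raise ValueError(
            f"no marker signal for carrier {call.sample_id} at "
            f"{call.chrom}:{call.start}-{call.end}")
    vals = sig["baf"].to_numpy(dtype=float)
    if call.cnv_type == "del":
        if len(vals) < baf.min_informative:
            return "untested", np.nan
        lo, hi = baf.het_band
        frac_het = float(np.mean((vals > lo) & (vals < hi)))
        return ("reject" if frac_het > baf.del_het_max else "accept"), frac_het
    # duplication: require the mid-range probes to sit in the 1/3, 2/3 bands
    mlo, mhi = baf.mid_range
    mid = vals[(vals > mlo) & (vals < mhi)]
    if len(mid) < baf.min_informative:
        return "untested", np.nan
    in_band = ((mid > baf.dup_band_lo[0]) & (mid < baf.dup_band_lo[1])) | \
              ((mid > baf.dup_band_hi[0]) & (mid < baf.dup_band_hi[1]))
    frac = float(np.mean(in_band))
    return ("reject" if frac < baf.dup_band_min else "accept"), frac


def apply_baf_filter(calls: list[CnvCall], probe_map: ProbeMap,
                     cfg: FilterConfig) -> list[CnvCall]:
    """Run :func:`baf_validate` over a callset, flagging ``BAF_REJECT`` or
    ``BAF_UNTESTED``; skipped entirely when no signal is loaded."""
    if not probe_map.signal:
        return list(calls)
    out = []
    for c in calls:
        status, _ = baf_validate(c, probe_map, cfg.baf)
        if status == "reject":
            out.append(c.with_flags("BAF_REJECT"))
        elif status == "untested":
            out.append(c.with_flags("BAF_UNTESTED"))
        else:
            out.append(c)
    return out


# ---------------------------------------------------------------------------
# batch-effect inflation screen


def detect_inflation_loci(calls: list[CnvCall], samples: pd.DataFrame,
                          cfg: FilterConfig, n_perm: int = 100,
                          seed: int = 0) -> tuple[list[LocusCluster], dict]:
    """Iteratively exclude small-deletion loci with a batch-effect signature.

    Restricted to deletions in the 30-100 kb band: while the permutation
    genomic-inflation lambda over their locus clusters exceeds
    ``lambda_max``, remove the cluster with the smallest exact-test p-value
    whose carriers are >= ``dataset_concentration`` concentrated in a single
    dataset; stop when lambda is controlled or no cluster qualifies.

    Returns the removed clusters and a diagnostics dict with the lambda
    trajectory (``lambdas[0]`` is the pre-exclusion value).
    """
    from .assoc import cmh_exact_from_carriers, permutation_lambda, units_from_clusters

    lo, hi = cfg.small_del_range
    small_idx = [i for i, c in enumerate(calls)
                 if c.cnv_type == "del" and lo <= c.length_bp <= hi
                 and not (c.filter_flags - {"BAF_UNTESTED"})]
    clusters = cluster_calls(calls, samples, min_ro=cfg.reciprocal_overlap,
                             restrict_idx=small_idx)
    removed: list[LocusCluster] = []
    active = list(clusters)
    lambdas: list[float] = []
    rng_seed = seed
    while True:
        if not active:
            lambdas.append(float("nan"))
            break
        units = units_from_clusters(active, samples)
        res = permutation_lambda(units, samples, n_perm=n_perm, seed=rng_seed)
        lam = res.lambda_
        lambdas.append(lam)
        # stop when controlled, or when too few multi-carrier units remain
        # for the median-ratio estimate to mean anything
        if not (lam > cfg.lambda_max) or res.unreliable:
            break
        # candidates: clusters whose dataset composition is itself
        # improbable: >= 4 carriers in one dataset, >= 80% of all carriers
        # there, and binomial tail p < 0.01 given that dataset's cohort
        # share.  Singletons are trivially 100% concentrated and
        # same-dataset pairs/triples arise routinely by chance; the
        # binomial gate makes candidacy a direct test of the batch
        # signature rather than of case/control association, which for a
        # case-only batch follows automatically.
        ds_share = samples["dataset"].value_counts(normalize=True).to_dict()
        candidates = []
        for cl in active:
            top_ds, top = max(cl.dataset_carriers.items(),
                              key=lambda kv: kv[1], default=(None, 0))
            if top < 4 or top / cl.n_carriers < cfg.dataset_concentration:
                continue
            p_conc = float(stats.binom.sf(top - 1, cl.n_carriers,
                                          ds_share.get(top_ds, 0.0)))
            if p_conc >= 0.01:
                continue
            p, _ = cmh_exact_from_carriers(cl.carriers, samples)
            candidates.append((p, cl))
        if not candidates:
            break
        # all clusters bearing the batch-effect signature are excluded as a
        # set (smallest p first, for the audit trail): gating one-by-one
        # removals on the lambda threshold is unstable against the
        # estimator's granularity at this unit count
        candidates.sort(key=lambda t: (t[0], t[1].cluster_id))
        for _, cl in candidates:
            removed.append(cl)
            active.remove(cl)
    return removed, {"lambdas": lambdas, "n_small_clusters": len(clusters)}


# ---------------------------------------------------------------------------
# cascade orchestration


def run_filter_cascade(calls_a: list[CnvCall], calls_b: list[CnvCall],
                       samples: pd.DataFrame, probe_map: ProbeMap,
                       masks: dict, external_ref: pd.DataFrame | None,
                       cfg: FilterConfig | None = None,
                       inflation_screen: bool = True,
                       n_perm: int = 100, seed: int = 0) -> dict:
    """Consensus plus the full filter cascade.

    Returns a dict with the flagged consensus callset (``calls``), the
    locus ``clusters`` of the qualifying callset, ``survivors``, the
    excluded inflation ``inflation_loci`` and the screen's diagnostics.
    """
    cfg = cfg or FilterConfig()
    consensus = intersect_callsets(calls_a, calls_b, probe_map,
                                   known_samples=set(samples["sample_id"]))
    flagged = apply_size_filter(consensus, cfg)
    flagged = apply_region_filters(flagged, masks, cfg)
    flagged, clusters = cluster_and_frequency_filter(flagged, samples,
                                                     external_ref, cfg)
    flagged = apply_baf_filter(flagged, probe_map, cfg)

    removed, diag = ([], {"lambdas": [], "n_small_clusters": 0})
    if inflation_screen:
        removed, diag = detect_inflation_loci(flagged, samples, cfg,
                                              n_perm=n_perm, seed=seed)
        excluded_idx = {i for cl in removed for i in cl.member_idx}
        flagged = [c.with_flags("INFLATION_LOCUS") if i in excluded_idx else c
                   for i, c in enumerate(flagged)]

    survivors = [c for c in flagged if not (c.filter_flags - {"BAF_UNTESTED"})]
    survivor_clusters = cluster_calls(survivors, samples,
                                      min_ro=cfg.reciprocal_overlap)
    return {"calls": flagged, "clusters": clusters, "survivors": survivors,
            "survivor_clusters": survivor_clusters,
            "inflation_loci": removed, "inflation_diagnostics": diag,
            "config": cfg}
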