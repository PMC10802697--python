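"""Consensus and the CNV filter cascade."""

import numpy as np
import pandas as pd
import pytest

import cnvburden as cb
from cnvburden.filters import (BafParams, FilterConfig, apply_region_filters,
                               apply_size_filter, baf_validate, cluster_calls,
                               cluster_and_frequency_filter, fraction_overlap,
                               intersect_callsets)
from cnvburden.intervals import reciprocal_overlap
from cnvburden.types import CnvCall, ProbeMap, RegionSet
from .conftest import make_samples


def simple_probe_map(spacing=1_000, n=2_000, chroms=("1", "2")):
    rows = []
    for chrom in chroms:
        pos = spacing // 2 + spacing * np.arange(n)
        rows.append(pd.DataFrame({"chrom": chrom, "pos": pos,
                                  "probe_id": [f"{chrom}_{i}" for i in range(n)]}))
    return ProbeMap(pd.concat(rows, ignore_index=True))


def dcall(sid, chrom, start, end, state=1, n_probes=None):
    if n_probes is None:
        n_probes = max(1, (end - start) // 1_000)
    return CnvCall(sid, chrom, start, end, state, n_probes)


class TestConsensus:
    pm = simple_probe_map()

    def test_identical_callsets_round_trip(self):
        calls = [dcall("S1", "1", 10_500, 50_500), dcall("S2", "2", 500, 30_500, 3)]
        out = intersect_callsets(calls, list(calls), self.pm)
        assert [(c.sample_id, c.chrom, c.start, c.end, c.copy_state) for c in out] == \
               [("S1", "1", 10_500, 50_500, 1), ("S2", "2", 500, 30_500, 3)]
        # probe count recomputed from the map
        assert out[0].n_probes == self.pm.n_probes_in("1", 10_500, 50_500)

    def test_single_caller_call_dropped(self):
        out = intersect_callsets([dcall("S1", "1", 10_500, 50_500)], [], self.pm)
        assert out == []

    def test_pairwise_intersection(self):
        a = [dcall("S1", "1", 100_500, 200_500)]
        b = [dcall("S1", "1", 150_500, 260_500)]
        out = intersect_callsets(a, b, self.pm)
        assert (out[0].start, out[0].end) == (150_500, 200_500)

    def test_opposite_direction_never_intersects(self):
        a = [dcall("S1", "1", 100_500, 200_500, 1)]
        b = [dcall("S1", "1", 100_500, 200_500, 3)]
        assert intersect_callsets(a, b, self.pm) == []

    def test_unknown_sample_is_error(self):
        with pytest.raises(ValueError, match="absent"):
            intersect_callsets([dcall("ghost", "1", 500, 10_500)], [],
                               self.pm, known_samples={"S1"})


@pytest.mark.parametrize("n_probes,length,expect_flag", [
    (14, 50_000, True),     # probe floor
    (20, 29_999, True),     # length floor
    (15, 30_000, False),    # inclusive boundary survives
    (15, 29_999, True),
])
def test_size_filter_boundaries(n_probes, length, expect_flag):
    call = CnvCall("S1", "1", 1_000, 1_000 + length - 1, 1, n_probes)
    out = apply_size_filter([call], FilterConfig())
    assert (("SIZE" in out[0].filter_flags) is expect_flag)


class TestFractionOverlap:
    def test_containment_disjoint_and_union(self):
        mask = RegionSet("m", pd.DataFrame(
            {"chrom": ["1", "1"], "start": [1, 151], "end": [200, 400]}))
        call = dcall("S1", "1", 1, 1_000)
        assert fraction_overlap(call, mask) == pytest.approx(0.4)  # 400/1000
        inside = dcall("S1", "1", 160, 260)
        assert fraction_overlap(inside, mask) == 1.0
        away = dcall("S1", "1", 5_000, 6_000)
        assert fraction_overlap(away, mask) == 0.0


def test_region_filters_rules_and_audit():
    masks = {
        "segdup": RegionSet("segdup", pd.DataFrame(
            {"chrom": ["1"], "start": [1], "end": [300]})),
        "tcr_ig": RegionSet("tcr_ig", pd.DataFrame(
            {"chrom": ["1"], "start": [5_000], "end": [6_000]})),
    }
    cfg = FilterConfig()
    at_threshold = dcall("S1", "1", 1, 1_000)          # 300/1000 = 0.30 exactly
    out = apply_region_filters([at_threshold], masks, cfg)
    assert "segdup" not in out[0].filter_flags          # strict > 30%
    over = dcall("S1", "1", 1, 999)                     # 300/999 > 0.30
    assert "segdup" in apply_region_filters([over], masks, cfg)[0].filter_flags
    one_bp = dcall("S1", "1", 4_001, 5_000)             # touches the Ig region
    assert "tcr_ig" in apply_region_filters([one_bp], masks, cfg)[0].filter_flags
    # audit: all masks evaluated even after one failure
    both = dcall("S1", "1", 1, 5_000)
    flags = apply_region_filters([both], masks, cfg)[0].filter_flags
    assert flags == {"segdup", "tcr_ig"} or flags == {"tcr_ig"}


def test_region_flags_match_brute_force():
    rng = np.random.default_rng(5)
    masks = {}
    for name in ("segdup", "repeats", "tcr_ig"):
        n = 12
        s = rng.integers(1, 80_000, n)
        masks[name] = RegionSet(name, pd.DataFrame(
            {"chrom": rng.choice(["1", "2"], n).tolist(),
             "start": s, "end": s + rng.integers(100, 8_000, n)}))
    calls = []
    for i in range(60):
        s = int(rng.integers(1, 90_000))
        calls.append(dcall(f"S{i}", str(rng.integers(1, 3)), s,
                           s + int(rng.integers(100, 10_000))))
    out = apply_region_filters(calls, masks, FilterConfig())
    for c_in, c_out in zip(calls, out):
        base = set(range(c_in.start, c_in.end + 1))
        for name, mask in masks.items():
            cov = set()
            for r in mask.df.itertuples(index=False):
                if r.chrom == c_in.chrom:
                    cov |= base & set(range(r.start, r.end + 1))
            frac = len(cov) / c_in.length_bp
            expected = frac > 0 if name == "tcr_ig" else frac > 0.30
            assert ((name in c_out.filter_flags) is expected), (name, frac)


class TestClusteringAndFrequency:
    def test_clusters_match_brute_force(self):
        rng = np.random.default_rng(8)
        samples = make_samples(40, seed=8)
        calls = []
        for i in range(80):
            sid = samples["sample_id"].iloc[rng.integers(0, len(samples))]
            s = int(rng.integers(1, 200_000))
            calls.append(dcall(sid, str(rng.integers(1, 3)), s,
                               s + int(rng.integers(1_000, 30_000)),
                               state=int(rng.choice([1, 3]))))
        clusters = cluster_calls(calls, samples, min_ro=0.5)
        # brute force: union-find over all pairs
        parent = list(range(len(calls)))
        def find(i):
            while parent[i] != i:
                i = parent[i]
            return i
        for i in range(len(calls)):
            for j in range(i + 1, len(calls)):
                ci, cj = calls[i], calls[j]
                if ci.chrom == cj.chrom and ci.cnv_type == cj.cnv_type and \
                   reciprocal_overlap(ci.start, ci.end, cj.start, cj.end) >= 0.5:
                    parent[find(j)] = find(i)
        expected = {}
        for i in range(len(calls)):
            expected.setdefault(find(i), set()).add(i)
        got = {frozenset(cl.member_idx) for cl in clusters}
        assert got == {frozenset(v) for v in expected.values()}
        for cl in clusters:
            assert cl.carriers == {calls[i].sample_id for i in cl.member_idx}

    def test_internal_frequency_threshold(self):
        samples = make_samples(200, seed=1, n_datasets=1)
        carriers = samples["sample_id"].tolist()
        calls = [dcall(carriers[i], "1", 10_000, 60_000) for i in range(3)]
        out, _ = cluster_and_frequency_filter(calls, samples, None, FilterConfig())
        assert all("FREQ_INTERNAL" in c.filter_flags for c in out)   # 3/200 = 1.5%
        calls = [dcall(carriers[0], "1", 10_000, 60_000)]
        out, _ = cluster_and_frequency_filter(calls, samples, None, FilterConfig())
        assert out[0].filter_flags == frozenset()                    # 0.5% kept

    def test_per_dataset_denominator(self):
        samples = make_samples(200, seed=2, n_datasets=2)
        ds0 = samples[samples["dataset"] == "ds0"]["sample_id"].tolist()
        calls = [dcall(ds0[i], "1", 10_000, 60_000) for i in range(2)]  # 2% of ds0
        out, _ = cluster_and_frequency_filter(calls, samples, None, FilterConfig())
        assert all("FREQ_INTERNAL" in c.filter_flags for c in out)

    def test_external_reference_matching(self):
        samples = make_samples(100)
        ref = pd.DataFrame({"chrom": ["1", "1"], "start": [10_000, 100_000],
                            "end": [60_000, 150_000],
                            "cnv_type": ["del", "del"],
                            "freq_global": [0.05, 0.001]})
        sid = samples["sample_id"].iloc[0]
        hit = dcall(sid, "1", 12_000, 58_000)        # RO ~0.9 with common record
        rare = dcall(sid, "1", 102_000, 148_000)     # matches only the rare record
        flipped = dcall(sid, "1", 12_000, 58_000, state=3)  # wrong direction
        out, _ = cluster_and_frequency_filter([hit, rare, flipped], samples,
                                              ref, FilterConfig())
        assert "FREQ_EXTERNAL" in out[0].filter_flags
        assert "FREQ_EXTERNAL" not in out[1].filter_flags
        assert "FREQ_EXTERNAL" not in out[2].filter_flags

    def test_zero_denominator_is_error(self):
        samples = make_samples(10).iloc[:0]
        with pytest.raises(ValueError, match="zero samples"):
            cluster_and_frequency_filter([], samples, None, FilterConfig())


class TestBafValidation:
    def _pm_with(self, baf, chrom="1", start=1_000, spacing=100, sid="S1"):
        pos = start + spacing * np.arange(len(baf))
        probes = pd.DataFrame({"chrom": chrom, "pos": pos,
                               "probe_id": [f"p{i}" for i in range(len(baf))]})
        sig = {sid: pd.DataFrame({"chrom": chrom, "pos": pos,
                                  "lrr": 0.0, "baf": baf})}
        return ProbeMap(probes, sig), int(pos[0]), int(pos[-1])

    def test_clean_hemizygous_accepted(self):
        baf = np.array([0.0, 1.0] * 10)
        pm, lo, hi = self._pm_with(baf)
        call = CnvCall("S1", "1", lo, hi, 1, len(baf))
        assert baf_validate(call, pm)[0] == "accept"

    def test_het_band_rejected_for_deletion(self):
        baf = np.array([0.0, 1.0, 0.5, 0.5, 0.48] * 4)   # 60% het band
        pm, lo, hi = self._pm_with(baf)
        call = CnvCall("S1", "1", lo, hi, 1, len(baf))
        status, score = baf_validate(call, pm)
        assert status == "reject" and score > 0.5

    def test_duplication_band_rule(self):
        good = np.array([0.0, 1.0, 0.33, 0.66] * 6)
        pm, lo, hi = self._pm_with(good)
        assert baf_validate(CnvCall("S1", "1", lo, hi, 3, 24), pm)[0] == "accept"
        diploid = np.array([0.0, 1.0, 0.5, 0.5] * 6)
        pm, lo, hi = self._pm_with(diploid)
        assert baf_validate(CnvCall("S1", "1", lo, hi, 3, 24), pm)[0] == "reject"

    def test_too_few_informative_probes_untested(self):
        baf = np.array([0.0, 1.0, 0.5])
        pm, lo, hi = self._pm_with(baf)
        assert baf_validate(CnvCall("S1", "1", lo, hi, 1, 3), pm)[0] == "untested"

    def test_missing_signal_is_error(self):
        pm, lo, hi = self._pm_with(np.array([0.0, 1.0] * 10))
        call = CnvCall("other", "1", lo, hi, 1, 20)
        with pytest.raises(ValueError, match="other"):
            baf_validate(call, pm)

    def test_simulated_calls_classified_with_known_truth(self, small_study,
                                                         small_cascade):
        """>=95% of clean duplications accepted; >=90% of diploid 'false'
        calls rejected, using the generator's ground truth."""
        st = small_study
        truth = st.truth.calls
        by_sample = {}
        for r in truth.itertuples(index=False):
            by_sample.setdefault(r.sample_id, []).append(r)

        def truth_kind(c):
            best, ov_best = None, 0
            for r in by_sample.get(c.sample_id, ()):
                if r.chrom != c.chrom:
                    continue
                ov = min(c.end, r.end) - max(c.start, r.start) + 1
                if ov > ov_best:
                    best, ov_best = r, ov
            return best.kind if best else None

        stats = {"clean_acc": [0, 0], "false_rej": [0, 0]}
        for c in small_cascade["calls"]:
            kind = truth_kind(c)
            if kind is None:
                continue
            tested = not ({"BAF_UNTESTED"} & c.filter_flags)
            if not tested:
                continue
            rejected = "BAF_REJECT" in c.filter_flags
            if kind == "false":
                stats["false_rej"][0] += rejected
                stats["false_rej"][1] += 1
            elif not kind.startswith("small"):
                stats["clean_acc"][0] += (not rejected)
                stats["clean_acc"][1] += 1
        acc, n_acc = stats["clean_acc"]
        rej, n_rej = stats["false_rej"]
        assert n_acc > 50
        assert acc / n_acc >= 0.95
        if n_rej >= 5:
            assert rej / n_rej >= 0.9


def test_cascade_flags_are_order_independent(small_cascade):
    """Each filter is computed on the consensus callset, so re-running the
    size filter on the already-flagged calls changes nothing, and the
    survivor set equals the calls without removal flags."""
    calls = small_cascade["calls"]
    again = apply_size_filter(calls, FilterConfig())
    assert [c.filter_flags for c in again] == [c.filter_flags for c in calls]
    from cnvburden.types import NON_REMOVAL_FLAGS
    expected = [c for c in calls if not (c.filter_flags - NON_REMOVAL_FLAGS)]
    assert expected == small_cascade["survivors"]
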