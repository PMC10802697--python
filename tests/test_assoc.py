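"""Clumping, the exact stratified test, BH-FDR and the permutation machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact, hypergeom

import cnvburden as cb
from cnvburden.assoc import (TestUnit, bh_fdr, clump_gene_units,
                             clump_probe_units, cmh_exact, cmh_exact_test,
                             permutation_lambda, recurrence_permutation_test,
                             run_association)
from cnvburden.filters import LocusCluster
from cnvburden.types import CnvCall, ProbeMap, RegionSet
from .conftest import make_samples


def gene_set(rows):
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])
    df["pli"] = 0.5
    for f in ("ndd_kendall", "ndd_fu", "haplosensitive", "triplosensitive"):
        df[f] = False
    return RegionSet("genes", df, merge=False)


def dcall(sid, chrom, start, end, state=1):
    return CnvCall(sid, chrom, start, end, state, max(1, (end - start) // 1000))


class TestGeneClumping:
    genes = gene_set([("G1", "1", 1_000, 2_000), ("G2", "1", 5_000, 6_000),
                      ("G3", "2", 1_000, 2_000)])

    def test_always_cohit_genes_merge(self):
        calls = [dcall(f"S{i}", "1", 500, 6_500) for i in range(4)]
        units = clump_gene_units(calls, self.genes)
        assert len(units) == 1
        assert units[0].members == ("G1", "G2")

    def test_never_cohit_genes_stay_separate(self):
        calls = [dcall("S1", "1", 900, 2_100), dcall("S2", "1", 4_900, 6_100)]
        units = clump_gene_units(calls, self.genes)
        assert {u.members for u in units} == {("G1",), ("G2",)}

    def test_gene_without_calls_dropped(self):
        calls = [dcall("S1", "1", 900, 2_100)]
        units = clump_gene_units(calls, self.genes)
        assert {u.members for u in units} == {("G1",)}

    def test_types_clumped_separately(self):
        calls = [dcall("S1", "1", 500, 6_500, 1), dcall("S2", "1", 900, 2_100, 3)]
        units = clump_gene_units(calls, self.genes)
        kinds = {(u.cnv_type, u.members) for u in units}
        assert ("del", ("G1", "G2")) in kinds
        assert ("dup", ("G1",)) in kinds

    def test_random_instance_matches_pairwise_rule(self):
        rng = np.random.default_rng(21)
        genes = gene_set([(f"G{i}", "1", 1_000 + 3_000 * i, 2_500 + 3_000 * i)
                          for i in range(8)])
        calls = []
        for i in range(40):
            s = int(rng.integers(500, 22_000))
            calls.append(dcall(f"S{i}", "1", s, s + int(rng.integers(500, 9_000))))
        units = clump_gene_units(calls, genes)
        # brute force: evaluate the >50% rule for each adjacent pair, then
        # chain transitively
        gdf = genes.df
        hit = []
        for r in gdf.itertuples(index=False):
            hit.append({i for i, c in enumerate(calls)
                        if c.start <= r.end and c.end >= r.start})
        merged_with_next = []
        for i in range(len(gdf) - 1):
            u = hit[i] | hit[i + 1]
            merged_with_next.append(bool(u) and len(hit[i] & hit[i + 1]) / len(u) > 0.5)
        groups, current = [], [0]
        for i, m in enumerate(merged_with_next):
            if m:
                current.append(i + 1)
            else:
                groups.append(current); current = [i + 1]
        groups.append(current)
        expected = {tuple(gdf["gene_id"].iloc[g]) for g in groups
                    if set().union(*(hit[i] for i in g))}
        assert {u.members for u in units if u.cnv_type == "del"} == expected


class TestProbeClumping:
    def _pm(self):
        probes = pd.DataFrame({"chrom": "1", "pos": 1_000 * np.arange(1, 31),
                               "probe_id": [f"p{i}" for i in range(30)]})
        return ProbeMap(probes)

    def test_identical_breakpoints_single_unit(self):
        pm = self._pm()
        calls = [dcall(f"S{i}", "1", 5_000, 10_000) for i in range(3)]
        units = clump_probe_units(calls, pm)
        assert len(units) == 1
        assert len(units[0].members) == 6   # probes at 5..10 kb

    def test_disjoint_clusters_two_units(self):
        pm = self._pm()
        calls = [dcall("S1", "1", 2_000, 5_000), dcall("S2", "1", 2_000, 5_000),
                 dcall("S3", "1", 20_000, 25_000)]
        units = clump_probe_units(calls, pm)
        assert len(units) == 2


class TestCmhExact:
    def test_balanced_null(self):
        counts = [(1, 2, 10, 20), (1, 2, 10, 20), (1, 2, 10, 20), (1, 2, 10, 20)]
        p, or_mh = cmh_exact(counts)
        assert p == pytest.approx(1.0, abs=0.05)
        assert or_mh == pytest.approx(1.0, abs=0.3)

    def test_degenerate_no_carriers(self):
        p, or_mh = cmh_exact([(0, 0, 10, 20)] * 4)
        assert p == 1.0 and np.isnan(or_mh)

    def test_single_stratum_equals_fisher_minlike(self):
        rng = np.random.default_rng(31)
        for _ in range(150):
            N = int(rng.integers(6, 40))
            n1 = int(rng.integers(1, N))
            m = int(rng.integers(1, N))
            k = int(rng.integers(max(0, m + n1 - N), min(m, n1) + 1))
            table = np.array([[k, n1 - k], [m - k, N - n1 - m + k]])
            p_ours, _ = cmh_exact([(k, m, n1, N)])
            p_fisher = fisher_exact(table, alternative="two-sided")[1]
            assert p_ours == pytest.approx(p_fisher, rel=1e-9, abs=1e-12)

    def test_multi_stratum_equals_enumeration(self):
        rng = np.random.default_rng(32)
        for _ in range(25):
            strata = []
            for _ in range(4):
                N = int(rng.integers(4, 13))
                n1 = int(rng.integers(1, N))
                m = int(rng.integers(0, N + 1))
                k = int(rng.integers(max(0, m + n1 - N), min(m, n1) + 1))
                strata.append((k, m, n1, N))
            p_ours, _ = cmh_exact(strata)
            p_brute = enumerate_cmh(strata)
            assert p_ours == pytest.approx(p_brute, rel=1e-9, abs=1e-12)

    def test_invariances(self):
        strata = [(2, 3, 8, 20), (0, 1, 5, 15), (1, 4, 10, 25), (1, 1, 6, 12)]
        p0, _ = cmh_exact(strata)
        # stratum order
        p1, _ = cmh_exact(strata[::-1])
        assert p1 == pytest.approx(p0, rel=1e-12)
        # jointly swapping case<->control and carrier<->non-carrier
        swapped = []
        for k, m, n1, N in strata:
            n0 = N - n1
            k_sw = (N - m) - (n1 - k)  # non-carriers among controls
            swapped.append((k_sw, N - m, n0, N))
        p2, _ = cmh_exact(swapped)
        assert p2 == pytest.approx(p0, rel=1e-12)


def enumerate_cmh(strata):
    """Independent oracle: enumerate all margin-consistent k-vectors."""
    supports = []
    for k, m, n1, N in strata:
        lo, hi = max(0, m + n1 - N), min(m, n1)
        ks = np.arange(lo, hi + 1)
        supports.append((ks, hypergeom.pmf(ks, N, m, n1)))
    from itertools import product
    s_obs = sum(k for k, _, _, _ in strata)
    outcomes = {}
    for combo in product(*[range(len(ks)) for ks, _ in supports]):
        s = sum(int(supports[i][0][j]) for i, j in enumerate(combo))
        pr = float(np.prod([supports[i][1][j] for i, j in enumerate(combo)]))
        outcomes[s] = outcomes.get(s, 0.0) + pr
    p_obs = outcomes[s_obs]
    return min(1.0, sum(pr for pr in outcomes.values() if pr <= p_obs * (1 + 1e-7)))


class TestBhFdr:
    def test_hand_computed_example(self):
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_trivial_cases(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(33)
        for _ in range(20):
            p = rng.random(rng.integers(1, 40))
            q = bh_fdr(p)
            q_sm = multipletests(p, method="fdr_bh")[1]
            assert q == pytest.approx(q_sm, rel=1e-12)
            assert (q >= p - 1e-12).all()

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, np.nan])


def _units_from_carriers(carrier_sets, samples):
    units = []
    for i, carriers in enumerate(carrier_sets):
        units.append(TestUnit(unit_id=f"u{i}", kind="gene", members=(f"G{i}",),
                              chrom="1", start=i * 1000, end=i * 1000 + 500,
                              cnv_type="del", carriers=frozenset(carriers)))
    return units


class TestPermutationLambda:
    def test_random_labels_give_lambda_near_one(self):
        rng = np.random.default_rng(34)
        samples = make_samples(400, seed=34)
        sids = samples["sample_id"].to_numpy()
        carrier_sets = [set(rng.choice(sids, size=rng.integers(2, 8),
                                       replace=False)) for _ in range(60)]
        res = permutation_lambda(_units_from_carriers(carrier_sets, samples),
                                 samples, n_perm=200, seed=34)
        assert 0.6 < res.lambda_ < 1.4
        assert not res.unreliable

    def test_few_units_flagged_unreliable(self):
        samples = make_samples(50, seed=35)
        sids = samples["sample_id"].tolist()
        units = _units_from_carriers([set(sids[:3])], samples)
        res = permutation_lambda(units, samples, n_perm=50, seed=35)
        assert res.unreliable

    def test_planted_concentration_inflates_lambda(self):
        rng = np.random.default_rng(36)
        samples = make_samples(400, seed=36)
        sids = samples["sample_id"].to_numpy()
        cases = samples.loc[samples["is_case"], "sample_id"].to_numpy()
        carrier_sets = [set(rng.choice(sids, size=4, replace=False))
                        for _ in range(25)]
        carrier_sets += [set(rng.choice(cases, size=7, replace=False))
                         for _ in range(3)]   # case-only loci
        res = permutation_lambda(_units_from_carriers(carrier_sets, samples),
                                 samples, n_perm=200, seed=36)
        assert res.lambda_ > 1.1


class TestRecurrence:
    def _cluster(self, i, carriers, cnv_type="del"):
        return LocusCluster(cluster_id=i, chrom="1", start=i * 10_000,
                            end=i * 10_000 + 5_000, cnv_type=cnv_type,
                            member_idx=[], carriers=set(carriers))

    def test_no_calls_gives_p_one(self):
        samples = make_samples(50)
        res = recurrence_permutation_test([], samples, "del", n_perm=100, seed=0)
        assert res.p_value == 1.0 and res.t_observed == 0

    def test_planted_case_recurrence_detected(self):
        # a single extreme locus cannot move T (a permuted multi-carrier
        # locus still has >= 2 case carriers most of the time); power comes
        # from many case-concentrated loci, so that is what we plant
        rng = np.random.default_rng(37)
        samples = make_samples(300, seed=37)
        cases = samples.loc[samples["is_case"], "sample_id"].to_numpy()
        sids = samples["sample_id"].to_numpy()
        clusters = [self._cluster(i, rng.choice(sids, size=2, replace=False))
                    for i in range(30)]
        clusters += [self._cluster(100 + i, rng.choice(cases, size=3, replace=False))
                     for i in range(12)]
        res = recurrence_permutation_test(clusters, samples, "del",
                                          n_perm=500, seed=37)
        assert res.p_value < 0.05

    def test_wrong_type_ignored(self):
        samples = make_samples(50)
        clusters = [self._cluster(0, samples["sample_id"][:5], cnv_type="dup")]
        res = recurrence_permutation_test(clusters, samples, "del",
                                          n_perm=50, seed=1)
        assert res.t_observed == 0


def test_run_association_table(small_study, small_cascade):
    units = clump_gene_units(small_cascade["survivors"],
                             small_study.annotation.genes,
                             small_cascade["kept_samples"])
    table = run_association(units, small_cascade["kept_samples"])
    assert len(table) == len(units)
    assert (table["q_value"] >= table["p_value"] - 1e-12).all()
    assert table["p_value"].is_monotonic_increasing
    # no double counting: per-unit case+control carriers equal carrier sets
    total = (table["case_carriers"] + table["control_carriers"]).sum()
    assert total == sum(u.n_carriers for u in units)
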