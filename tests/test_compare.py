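"""Landscape comparison: bootstrap, partition, composition, paired tests."""

import numpy as np
import pandas as pd
import pytest

from telscope.caller import InsertionCall, Landscape
from telscope.compare import (
    BootstrapConfig,
    aging_tests,
    bootstrap_landscape,
    classify_common_unique,
    cohort_difference_test,
    family_composition,
)
from telscope.mapping import align_reads
from telscope.simulate import SeqParams, plant_insertions, random_insertion_plan, simulate_wgs


def _call(chrom, pos, family):
    return InsertionCall(chrom, pos, family, "+", 5, 5, 10, "TE")


def _landscape(sample_id, loci, mapped=10**6):
    return Landscape(sample_id, mapped, [_call(*l) for l in loci])


class TestBootstrap:
    def test_fraction_one_has_zero_sd(self, wgs_alns, bundle):
        res = bootstrap_landscape(wgs_alns, bundle, BootstrapConfig(n_perm=5, fraction=1.0))
        assert res.sd == 0.0
        assert np.ptp(res.values) == 0.0

    def test_fixed_seeds_reproduce_bitwise(self, wgs_alns, bundle):
        r1 = bootstrap_landscape(wgs_alns, bundle, BootstrapConfig(20, 0.5))
        r2 = bootstrap_landscape(wgs_alns, bundle, BootstrapConfig(20, 0.5))
        assert np.array_equal(r1.values, r2.values)
        assert (r1.mean, r1.sd, r1.ci95) == (r2.mean, r2.sd, r2.ci95)

    def test_high_support_calls_survive_halving(self, wgs_alns, bundle, landscape):
        res = bootstrap_landscape(wgs_alns, bundle, BootstrapConfig(20, 0.5))
        full = landscape.normalized_per_million
        assert abs(res.mean - full) / full <= 0.05
        assert res.ci95[0] - 1e-9 <= res.mean <= res.ci95[1] + 1e-9

    def test_sd_decreases_with_planted_support(self, bundle):
        """Halving hurts marginal calls most: bootstrap SD shrinks as depth
        (hence per-call support) grows."""
        sds = []
        for depth in (6.0, 12.0, 24.0):
            plan = random_insertion_plan(bundle, 15, 1.0, seed=71, min_spacing=900)
            sample = plant_insertions(bundle, plan, 10, seed=72)
            reads, _ = simulate_wgs(sample, SeqParams(depth=depth, seed=73))
            alns = align_reads(reads, bundle)
            res = bootstrap_landscape(alns, bundle, BootstrapConfig(20, 0.5))
            sds.append(res.sd / max(res.mean, 1e-9))  # relative SD
        assert sds[0] > sds[-1]

    def test_cumulative_mean_converges_to_mean(self, wgs_alns, bundle):
        res = bootstrap_landscape(wgs_alns, bundle, BootstrapConfig(10, 0.5))
        assert res.cumulative_mean[-1] == pytest.approx(res.mean)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            BootstrapConfig(n_perm=0)
        with pytest.raises(ValueError):
            BootstrapConfig(fraction=0.0)


class TestCommonUniquePartition:
    def test_identical_tables_are_all_common(self):
        loci = [("chr1", 1000 * i, "TE1") for i in range(1, 11)]
        cmp = classify_common_unique(_landscape("a", loci), _landscape("b", loci))
        assert cmp.n_common == 10
        assert len(cmp.unique_a) == 0 and len(cmp.unique_b) == 0

    def test_shared_and_specific_counts_partition_exactly(self):
        shared = [("chr1", 1000 * i, "TE1") for i in range(1, 81)]
        only_a = [("chr1", 200_000 + 1000 * i, "TE2") for i in range(10)]
        only_b = [("chr1", 400_000 + 1000 * i, "TE3") for i in range(10)]
        a = _landscape("young", shared + only_a)
        b = _landscape("aged", shared + only_b)
        cmp = classify_common_unique(a, b)
        assert (cmp.n_common, len(cmp.unique_a), len(cmp.unique_b)) == (80, 10, 10)
        cmp.check_conservation(90, 90)

    def test_swapping_inputs_swaps_unique_sets(self):
        a = _landscape("a", [("chr1", 1000, "TE1"), ("chr1", 5000, "TE2")])
        b = _landscape("b", [("chr1", 1020, "TE1"), ("chr1", 9000, "TE3")])
        fwd = classify_common_unique(a, b)
        rev = classify_common_unique(b, a)
        assert fwd.n_common == rev.n_common == 1
        pd.testing.assert_frame_equal(fwd.unique_a, rev.unique_b)
        pd.testing.assert_frame_equal(fwd.unique_b, rev.unique_a)

    def test_same_locus_different_family_not_matched(self):
        a = _landscape("a", [("chr1", 1000, "TE1")])
        b = _landscape("b", [("chr1", 1000, "TE2")])
        cmp = classify_common_unique(a, b)
        assert cmp.n_common == 0

    def test_match_window_bounds_positional_slop(self):
        a = _landscape("a", [("chr1", 1000, "TE1")])
        b = _landscape("b", [("chr1", 1101, "TE1")])
        assert classify_common_unique(a, b, match_window=100).n_common == 0
        assert classify_common_unique(a, b, match_window=101).n_common == 1

    def test_greedy_matching_is_one_to_one(self):
        a = _landscape("a", [("chr1", 1000, "TE1"), ("chr1", 1040, "TE1")])
        b = _landscape("b", [("chr1", 1010, "TE1")])
        cmp = classify_common_unique(a, b)
        assert cmp.n_common == 1
        # nearest pair wins: the 1000 call matches, 1040 stays unique
        assert cmp.common["pos0_a"].tolist() == [1000]


class TestFamilyComposition:
    def test_single_family_is_hundred_percent(self):
        ls = _landscape("a", [("chr1", 1000 * i, "TE1") for i in range(1, 51)])
        comp = family_composition(ls)
        assert comp.loc["TE1", "percent"] == pytest.approx(100.0)

    def test_rare_families_folded_into_others(self):
        loci = [("chr1", 1000 * i, "TE1") for i in range(1, 200)]
        loci += [("chr1", 300_000, "TE2")]  # 0.5% share
        comp = family_composition(_landscape("a", loci), min_fraction=0.01)
        assert "TE2" not in comp.index
        assert comp.loc["Others", "count"] == 1

    def test_percentages_sum_to_hundred(self):
        loci = [("chr1", 1000 * i, f"TE{1 + i % 4}") for i in range(1, 120)]
        comp = family_composition(_landscape("a", loci))
        assert comp["percent"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_empty_landscape_gives_empty_table(self):
        assert family_composition(_landscape("a", [])).empty


class TestAgingTests:
    def _table(self, young, aged):
        return pd.DataFrame({"unique_a": young, "unique_b": aged})

    def test_unit_gain_in_ten_families_hits_exact_tail(self):
        table = self._table([2] * 10, [3] * 10)
        res = aging_tests(table, alternative="greater")["signed_rank_unique"]
        assert res.p_value == pytest.approx(2.0**-10)
        assert res.direction == "greater"

    def test_fewer_than_three_informative_pairs_refused(self):
        table = self._table([1, 1, 1, 4], [1, 1, 2, 5])
        with pytest.raises(ValueError, match="informative"):
            aging_tests(table)

    def test_cohort_rank_sum_direction(self):
        res = cohort_difference_test([5, 6, 7, 8], [1, 2, 1, 2], alternative="greater")
        assert res.p_value < 0.05
        inv = cohort_difference_test([1, 2, 1, 2], [5, 6, 7, 8], alternative="greater")
        assert inv.p_value > 0.95
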