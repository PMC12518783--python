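"""Read-table analytics: efficiency, richness thresholds, accumulation,
paired tests, detection summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from nestblock.reads import (ReadTable, Scope, ThresholdKind,
                             blocking_efficiency, detection_summary,
                             expected_accumulation,
                             paired_mean_difference_test, per_sample_richness,
                             percent_change, read_table_from_files,
                             relative_retention, richness, round_half_away,
                             species_accumulation, threshold_sweep)


class TestBlockingEfficiency:
    def test_published_read_totals(self):
        eff = blocking_efficiency(5108, 1189276)
        assert eff == pytest.approx(99.57, abs=0.005)
        assert round_half_away(eff) == 100

    def test_complete_block(self):
        assert blocking_efficiency(0, 1234) == 100.0

    def test_no_change(self):
        assert blocking_efficiency(777, 777) == 0.0

    def test_increase_is_negative(self):
        assert blocking_efficiency(200, 100) == -100.0

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            blocking_efficiency(5, 0)

    @given(st.integers(0, 10**7), st.integers(1, 10**7))
    def test_matches_direct_arithmetic(self, w, wo):
        assert blocking_efficiency(w, wo) == pytest.approx(
            100.0 * (wo - w) / wo)


class TestPercentChange:
    @pytest.mark.parametrize("before,after,expected", [
        (82, 87, 6), (78, 86, 10), (58, 66, 14), (36, 47, 31), (5, 5, 0),
        (100, 50, -50),
    ])
    def test_reported_richness_boosts(self, before, after, expected):
        assert percent_change(before, after) == expected

    def test_half_rounds_away_from_zero(self):
        assert percent_change(200, 203) == 2       # 1.5 -> 2
        assert percent_change(200, 197) == -2      # -1.5 -> -2

    @given(st.integers(1, 10**6), st.integers(0, 10**6))
    def test_matches_direct_arithmetic(self, before, after):
        raw = 100.0 * (after - before) / before
        got = percent_change(before, after)
        assert abs(got - raw) <= 0.5 + 1e-9


class TestRichness:
    def test_toy_site_wide_min_reads(self):
        rows = [("s1", "blocker", t, c) for t, c in
                [("a", 5), ("b", 2), ("c", 1)]]
        table = ReadTable(pd.DataFrame(
            rows, columns=["sample_id", "condition", "taxon_id", "count"]))
        assert richness(table, "blocker", ThresholdKind.MIN_READS, 2) == 2
        assert richness(table, "blocker", ThresholdKind.MIN_READS, 1) == 3
        assert richness(table, "blocker", ThresholdKind.MIN_READS, 6) == 0

    def test_threshold_zero_equals_one(self, toy_table):
        for cond in ("blocker", "no_blocker"):
            assert richness(toy_table, cond, ThresholdKind.MIN_READS, 0) == \
                richness(toy_table, cond, ThresholdKind.MIN_READS, 1)

    def test_nest_builder_exclusion_is_per_sample(self, toy_table):
        assert richness(toy_table, "no_blocker",
                        exclude_nest_builders=True) == 2  # moth, fly
        assert richness(toy_table, "no_blocker",
                        exclude_nest_builders=False) == 3

    def test_site_wide_sums_across_samples(self, toy_table):
        # moth has 60 + 80 = 140 blocker reads site-wide
        assert richness(toy_table, "blocker", ThresholdKind.MIN_READS, 100) == 1

    def test_rra_per_sample(self, toy_table):
        # n1 blocker library total = 89; moth 60/89 = 0.674, fly 0.28,
        # weasel 0.034, builder 0.011
        r = per_sample_richness(toy_table, "blocker",
                                ThresholdKind.MIN_RRA, 0.05)
        assert r["n1"] == 2
        # n2 blocker total = 81: moth 80/81 passes, snake 1/81 fails
        assert r["n2"] == 1

    def test_pooled_condition(self, toy_table):
        # pooling sums conditions: builder 901 in n1
        assert richness(toy_table, "pooled", ThresholdKind.MIN_READS, 901) == 1

    @given(st.integers(0, 10_000))
    def test_matches_brute_force_recount(self, seed):
        rng = np.random.default_rng(seed)
        n_samples, n_taxa = int(rng.integers(1, 5)), int(rng.integers(1, 6))
        rows = []
        for s in range(n_samples):
            for cond in ("blocker", "no_blocker"):
                for t in range(n_taxa):
                    if rng.random() < 0.7:
                        rows.append((f"s{s}", cond, f"t{t}",
                                     int(rng.integers(0, 30))))
        if not rows:
            rows = [("s0", "blocker", "t0", 1)]
        table = ReadTable(pd.DataFrame(
            rows, columns=["sample_id", "condition", "taxon_id", "count"]))
        thr = int(rng.integers(1, 10))
        for cond in ("blocker", "no_blocker"):
            # brute force: sum per taxon, count those >= thr
            totals = {}
            for r in rows:
                if r[1] == cond:
                    totals[r[2]] = totals.get(r[2], 0) + r[3]
            expect = sum(v >= thr for v in totals.values())
            assert richness(table, cond, ThresholdKind.MIN_READS, thr) == expect
            # per-sample brute force
            got = per_sample_richness(table, cond, ThresholdKind.MIN_READS, thr)
            for s in {r[0] for r in rows}:
                expect_s = sum(1 for r in rows
                               if r[0] == s and r[1] == cond and r[3] >= thr)
                assert got[s] == expect_s


class TestThresholdSweep:
    def test_hand_counted_pairs(self, toy_table):
        res = threshold_sweep(toy_table, [1, 2, 5, 10, 100])
        by_thr = {r.threshold: r for r in res}
        # site-wide sums -- no_blocker: builder 1700, moth 15, fly 2;
        # blocker: builder 1, moth 140, fly 25, weasel 3, snake 1
        assert (by_thr[1].richness_without, by_thr[1].richness_with) == (3, 5)
        assert (by_thr[2].richness_without, by_thr[2].richness_with) == (3, 3)
        assert (by_thr[5].richness_without, by_thr[5].richness_with) == (2, 2)
        assert by_thr[100].richness_with == 1
        assert by_thr[1].percent_change == percent_change(3, 5)

    def test_monotone_non_increasing_in_threshold(self, toy_table):
        res = threshold_sweep(toy_table, [1, 2, 3, 5, 8, 13, 100])
        for a, b in zip(res, res[1:]):
            assert b.richness_with <= a.richness_with
            assert b.richness_without <= a.richness_without

    @given(st.integers(0, 5_000))
    def test_monotonicity_property_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        rows = [(f"s{rng.integers(3)}", rng.choice(["blocker", "no_blocker"]),
                 f"t{rng.integers(6)}", int(rng.integers(0, 40)))
                for _ in range(20)]
        df = pd.DataFrame(rows, columns=["sample_id", "condition",
                                         "taxon_id", "count"])
        df = df.drop_duplicates(["sample_id", "condition", "taxon_id"])
        table = ReadTable(df)
        for kind, thrs in [(ThresholdKind.MIN_READS, [1, 2, 4, 8]),
                           (ThresholdKind.MIN_RRA, [0.0, 0.05, 0.2, 0.5])]:
            for scope in (Scope.SITE_WIDE, Scope.PER_SAMPLE):
                res = threshold_sweep(table, thrs, scope, kind)
                for a, b in zip(res, res[1:]):
                    assert b.richness_with <= a.richness_with
                    assert b.richness_without <= a.richness_without

    def test_pooling_never_loses_species(self, toy_table):
        pooled = richness(toy_table, "pooled", ThresholdKind.MIN_READS, 1)
        assert pooled >= richness(toy_table, "blocker")
        assert pooled >= richness(toy_table, "no_blocker")


class TestSpeciesAccumulation:
    def test_single_sample_curve(self):
        rows = [("s1", "blocker", "a", 3), ("s1", "blocker", "b", 1)]
        table = ReadTable(pd.DataFrame(
            rows, columns=["sample_id", "condition", "taxon_id", "count"]))
        curve = species_accumulation(table, "blocker", 10, seed=0)
        assert list(curve["k"]) == [1]
        assert curve["mean"].iloc[0] == 2 and curve["sd"].iloc[0] == 0

    def test_identical_samples_flat_after_first(self):
        rows = [(f"s{i}", "blocker", t, 2) for i in range(4)
                for t in ("a", "b", "c")]
        table = ReadTable(pd.DataFrame(
            rows, columns=["sample_id", "condition", "taxon_id", "count"]))
        curve = species_accumulation(table, "blocker", 25, seed=0)
        assert np.allclose(curve["mean"], 3.0) and np.allclose(curve["sd"], 0)

    def test_mean_curve_non_decreasing(self, toy_table):
        curve = species_accumulation(toy_table, "blocker", 50, seed=1)
        assert (np.diff(curve["mean"]) >= -1e-12).all()

    @pytest.mark.parametrize("seed", [11, 23, 37])
    def test_matches_closed_form_expectation(self, seed):
        """Permutation means on random 10-sample tables fall within 3
        Monte-Carlo standard errors of E[S_k] = sum_t 1 - C(N-n_t,k)/C(N,k)."""
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(10):
            for t in range(12):
                if rng.random() < 0.4:
                    rows.append((f"s{s:02d}", "blocker", f"t{t:02d}",
                                 int(rng.integers(1, 50))))
        for s in range(10):   # every sample present in the condition
            rows.append((f"s{s:02d}", "blocker", "common", 5))
        table = ReadTable(pd.DataFrame(
            rows, columns=["sample_id", "condition", "taxon_id", "count"]))
        n_perm = 100
        curve = species_accumulation(table, "blocker", n_perm, seed=seed)
        expect = expected_accumulation(table, "blocker")
        se = curve["sd"].to_numpy() / math.sqrt(n_perm)
        diff = np.abs(curve["mean"].to_numpy() - expect)
        assert (diff <= 3 * se + 1e-9).all()

    def test_deterministic_under_seed(self, toy_table):
        a = species_accumulation(toy_table, "no_blocker", 20, seed=5)
        b = species_accumulation(toy_table, "no_blocker", 20, seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestPairedTest:
    def test_identical_vectors(self):
        t, df, p = paired_mean_difference_test([3, 4, 5], [3, 4, 5])
        assert (t, df, p) == (0.0, 2, 1.0)

    def test_zero_mean_differences(self):
        t, _, _ = paired_mean_difference_test([1, -1, 2, -2], [0, 0, 0, 0])
        assert t == pytest.approx(0.0)

    def test_hand_computed_t(self):
        # d = {1,2,3}: mean 2, sd 1, n 3 -> t = 2*sqrt(3) = 3.4641
        t, df, p = paired_mean_difference_test([2, 4, 6], [1, 2, 3])
        assert t == pytest.approx(2 * math.sqrt(3), abs=1e-4)
        assert df == 2

    def test_constant_nonzero_difference_flagged_infinite(self):
        t, df, p = paired_mean_difference_test([2, 3, 4], [1, 2, 3])
        assert math.isinf(t) and p == 0.0

    @given(st.integers(0, 10_000))
    def test_agrees_with_scipy(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 15))
        w = rng.normal(10, 3, n)
        wo = w + rng.normal(0, 2, n)
        t, df, p = paired_mean_difference_test(w, wo)
        ref = sps.ttest_rel(w, wo)
        assert t == pytest.approx(ref.statistic, rel=1e-9)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)
        assert df == n - 1


class TestDetectionSummary:
    def test_predator_detected_in_both_nests(self, toy_table):
        n, total, pct = detection_summary(toy_table, "predator")
        assert (n, total, pct) == (2, 2, 100)

    def test_ectoparasite_in_one_of_two(self, toy_table):
        n, total, pct = detection_summary(toy_table, "ectoparasite")
        assert (n, total, pct) == (1, 2, 50)

    def test_published_percentages(self):
        """8-of-22 and 18-of-22 detection fractions print as 36% and 82%."""
        rows = []
        for i in range(22):
            rows.append((f"n{i:02d}", "no_blocker", "host", 100))
            if i < 8:
                rows.append((f"n{i:02d}", "blocker", "pred", 3))
            if i < 18:
                rows.append((f"n{i:02d}", "no_blocker", "blowfly", 7))
        taxa = {"host": {"group": "sparrow", "is_nest_builder_of": None},
                "pred": {"group": "predator", "is_nest_builder_of": None},
                "blowfly": {"group": "ectoparasite", "is_nest_builder_of": None}}
        table = ReadTable(pd.DataFrame(
            rows, columns=["sample_id", "condition", "taxon_id", "count"]),
            taxa, {})
        assert detection_summary(table, "predator") == (8, 22, 36)
        assert detection_summary(table, "ectoparasite") == (18, 22, 82)

    def test_unknown_label_raises(self, toy_table):
        with pytest.raises(ValueError):
            detection_summary(toy_table, "no-such-group")

    def test_min_reads_pools_conditions(self, toy_table):
        # weasel has 3 blocker reads in n1 only; at min_reads 4 undetected
        assert detection_summary(toy_table, "predator", min_reads=4)[0] == 0


class TestRelativeRetention:
    def test_reference_normalisation(self):
        # target drops 1000 -> 10 while reference doubles (depth freed):
        # naive retention 0.01, true retention 0.01/2 = 0.005
        rows = [("s", "no_blocker", "tgt", 1000), ("s", "no_blocker", "ref", 500),
                ("s", "blocker", "tgt", 10), ("s", "blocker", "ref", 1000)]
        table = ReadTable(pd.DataFrame(
            rows, columns=["sample_id", "condition", "taxon_id", "count"]))
        r = relative_retention(table, {"tgt"}, {"ref"}, 1.0)
        assert r == pytest.approx(0.005)

    def test_disjointness_enforced(self, toy_table):
        with pytest.raises(ValueError):
            relative_retention(toy_table, {"moth"}, {"moth"})


class TestValidationAndIO:
    def test_duplicate_rows_rejected(self):
        rows = [("s", "blocker", "a", 1), ("s", "blocker", "a", 2)]
        with pytest.raises(ValueError):
            ReadTable(pd.DataFrame(
                rows, columns=["sample_id", "condition", "taxon_id", "count"]))

    def test_unknown_condition_rejected(self):
        rows = [("s", "maybe", "a", 1)]
        with pytest.raises(ValueError):
            ReadTable(pd.DataFrame(
                rows, columns=["sample_id", "condition", "taxon_id", "count"]))

    def test_round_trip_tsv(self, toy_table, tmp_path):
        reads = tmp_path / "reads.tsv"
        ann = tmp_path / "ann.tsv"
        smp = tmp_path / "samples.tsv"
        toy_table.counts.to_csv(reads, sep="\t", index=False)
        ann.write_text("taxon_id\tgroup\tis_nest_builder_of\n"
                       "builder\tsparrow\tbrsp\nmoth\tinsect\n"
                       "fly\tectoparasite\nweasel\tpredator\nsnake\tpredator\n")
        smp.write_text("sample_id\tnest_builder\nn1\tbrsp\nn2\tbrsp\n")
        loaded = read_table_from_files(reads, ann, smp)
        assert loaded.taxa["builder"]["is_nest_builder_of"] == "brsp"
        assert loaded.taxa["moth"]["is_nest_builder_of"] is None
        assert richness(loaded, "blocker", exclude_nest_builders=True) == \
            richness(toy_table, "blocker", exclude_nest_builders=True)
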