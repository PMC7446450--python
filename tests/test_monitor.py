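"""Decrease testing, responder statistics, burden models and concordance.

The Fisher decrease test is checked against an independent brute-force
oracle that enumerates all 2x2 tables with the observed margins and sums
hypergeometric point probabilities from :func:`math.comb`.
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctdna_monitor import (
    MonitorConfig,
    build_trajectories,
    classify_responder,
    compare_responder_groups,
    correlate_series,
    decrease_tests,
    estimate_tumor_fraction,
    fisher_decrease_test,
    jeffreys_lower,
    monitor_cohort,
    plasma_tissue_concordance,
    run_filter_chain,
    select_truncal_tp53,
)
from ctdna_monitor.monitor import decrease_proportion
from ctdna_monitor.records import Cohort


def enumerate_decrease_p(a1, d1, a2, d2):
    """Oracle: P(X >= a1) for X = pretreatment alt count given fixed margins."""
    K, n, N = a1 + a2, d1, d1 + d2
    denom = math.comb(N, K)
    lo, hi = max(0, K - (N - n)), min(K, n)
    return sum(math.comb(n, x) * math.comb(N - n, K - x) for x in range(max(a1, lo), hi + 1)) / denom


def table_prob(a1, d1, a2, d2):
    K, n, N = a1 + a2, d1, d1 + d2
    return math.comb(n, a1) * math.comb(N - n, K - a1) / math.comb(N, K)


class TestFisherDecrease:
    def test_no_decrease_is_not_significant(self):
        assert fisher_decrease_test((5, 100), (5, 100)) >= 0.5

    def test_matches_enumeration_example(self):
        p = fisher_decrease_test((8, 20), (1, 20))
        assert p == pytest.approx(enumerate_decrease_p(8, 20, 1, 20))
        assert p == pytest.approx(0.009828009828, rel=1e-9)

    def test_steep_decline_from_pretreatment(self):
        # TP53: 34.6% pretreatment down to 0.4% after the last cycle
        p = fisher_decrease_test((346, 1000), (4, 1000))
        assert p < 0.01

    def test_exhaustive_sweep_small_margins(self):
        for d1 in range(1, 13):
            for d2 in range(1, 13):
                for a1 in range(d1 + 1):
                    for a2 in range(d2 + 1):
                        assert fisher_decrease_test((a1, d1), (a2, d2)) == pytest.approx(
                            enumerate_decrease_p(a1, d1, a2, d2), abs=1e-12)

    def test_zero_depth_is_undefined(self):
        assert np.isnan(fisher_decrease_test((0, 0), (5, 100)))

    @given(st.integers(1, 30), st.integers(1, 30), st.data())
    @settings(max_examples=60, deadline=None)
    def test_swap_identity(self, d1, d2, data):
        """p_dec(pre, post) + p_dec(post, pre) = 1 + P(observed table)."""
        a1 = data.draw(st.integers(0, d1))
        a2 = data.draw(st.integers(0, d2))
        total = fisher_decrease_test((a1, d1), (a2, d2)) + fisher_decrease_test((a2, d2), (a1, d1))
        assert total == pytest.approx(1.0 + table_prob(a1, d1, a2, d2), abs=1e-10)


class TestJeffreys:
    def test_closed_form_value(self):
        # 2.5% quantile of Beta(4.5, 4.5)
        assert jeffreys_lower(4, 8) == pytest.approx(0.1989656, abs=1e-6)

    def test_zero_successes_bound_is_zero(self):
        assert jeffreys_lower(0, 10) == 0.0

    @pytest.mark.parametrize("k, n", [(1, 3), (4, 8), (7, 7), (10, 40)])
    def test_corrected_never_exceeds_raw(self, k, n):
        assert jeffreys_lower(k, n) <= k / n


def _tests_frame(rows):
    return pd.DataFrame(rows, columns=[
        "patient_id", "key", "sample_id", "timepoint_days", "phase", "decrease_p"])


class TestDecreaseProportion:
    def test_saturation(self):
        rows = [("P", f"k{i}", "S1", 30, "on_treatment", 1e-6) for i in range(8)]
        d = decrease_proportion(_tests_frame(rows), "P")
        assert d.raw == 1.0 and d.best_sample == "S1"

    def test_half_decreased_jeffreys_correction(self):
        rows = [("P", f"k{i}", "S1", 30, "on_treatment", 1e-6 if i < 4 else 0.5)
                for i in range(8)]
        d = decrease_proportion(_tests_frame(rows), "P")
        assert d.raw == 0.5
        assert d.corrected == pytest.approx(jeffreys_lower(4, 8))
        assert d.corrected <= d.raw

    def test_no_on_treatment_samples_undefined(self):
        with pytest.warns(UserWarning, match="undefined"):
            d = decrease_proportion(_tests_frame([]), "P")
        assert d.raw is None and d.corrected is None

    def test_invariant_to_order_and_duplicate_sample_rows(self):
        rows = [("P", f"k{i}", "S1", 30, "on_treatment", 0.001 * (i + 1)) for i in range(6)]
        base = decrease_proportion(_tests_frame(rows), "P")
        shuffled = decrease_proportion(_tests_frame(rows[::-1] + rows[:2]), "P")
        assert (base.raw, base.corrected) == (shuffled.raw, shuffled.corrected)


class TestClassifier:
    @pytest.mark.parametrize("n, corrected, expect", [
        (8, 0.1, "good"),     # few mutations
        (40, 0.9, "good"),    # large decrease
        (40, 0.2, "poor"),
        (40, None, None),     # undefined proportion, many mutations
        (8, None, "good"),    # few mutations dominates even when undefined
    ])
    def test_rule(self, n, corrected, expect):
        assert classify_responder(n, corrected) == expect


class TestGroupComparison:
    def test_fully_separated_three_vs_three(self):
        assert compare_responder_groups([0.9, 0.8, 0.7], [0.1, 0.2, 0.3]) == pytest.approx(1 / 20)

    def test_fully_separated_six_vs_six(self):
        p = compare_responder_groups(np.linspace(0.7, 0.95, 6), np.linspace(0.05, 0.3, 6))
        assert p == pytest.approx(1 / math.comb(12, 6), rel=1e-9)

    def test_identical_values_give_half(self):
        assert compare_responder_groups([0.5, 0.5], [0.5, 0.5]) == 0.5

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError):
            compare_responder_groups([], [0.5])


class TestTumorFraction:
    @pytest.mark.parametrize("model", ["direct", "het", "loh"])
    def test_zero_maps_to_zero(self, model):
        assert estimate_tumor_fraction(0.0, model) == 0.0

    def test_loh_algebra(self):
        assert estimate_tumor_fraction(0.5, "loh") == pytest.approx(2 / 3)

    def test_direct_identity(self):
        assert estimate_tumor_fraction(0.581, "direct") == 0.581

    def test_het_saturates_at_one(self):
        assert estimate_tumor_fraction(0.7, "het") == 1.0

    def test_monotone_transforms(self):
        grid = np.linspace(0, 1, 21)
        for model in ("direct", "het", "loh"):
            vals = [estimate_tumor_fraction(v, model) for v in grid]
            assert all(0 <= f <= 1 for f in vals)
            assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_invalid_vaf_rejected(self):
        with pytest.raises(ValueError):
            estimate_tumor_fraction(1.5, "direct")


def _mini_cohort(plasma_sets, tissue_sets):
    """Cohort whose per-material variant detections are the given key sets."""
    samples, variants = [], []
    for p, (plasma, tissue) in enumerate(zip(plasma_sets, tissue_sets)):
        pid = f"P{p}"
        samples += [
            (pid, f"{pid}-BC", "germline", -14, "pretreatment", np.nan),
            (pid, f"{pid}-T1", "tissue", -10, "pretreatment", np.nan),
            (pid, f"{pid}-PL1", "plasma", -7, "pretreatment", np.nan),
        ]
        for sid, keys in ((f"{pid}-PL1", plasma), (f"{pid}-T1", tissue)):
            for k in keys:
                variants.append((pid, sid, "1", hash(k) % 10_000 + ord(k[0]) * 10_000,
                                 "A", "T", 100, 1000, k, np.nan, ""))
    cohort = Cohort(
        variants=pd.DataFrame(variants, columns=[
            "patient_id", "sample_id", "chrom", "pos", "ref", "alt",
            "alt_count", "depth", "gene", "cadd", "consequence"]),
        samples=pd.DataFrame(samples, columns=[
            "patient_id", "sample_id", "material", "timepoint_days", "phase", "ca125"]),
    )
    return cohort, cohort.variants


class TestConcordance:
    def test_identical_sets_are_fully_concordant(self):
        cohort, tracked = _mini_cohort([{"a", "b"}], [{"a", "b"}])
        for direction in ("tissue_recall", "plasma_recall", "jaccard"):
            per, med = plasma_tissue_concordance(tracked, cohort, direction)
            assert med == 1.0

    def test_set_arithmetic(self):
        cohort, tracked = _mini_cohort([{"a", "b", "c"}], [{"a", "b", "d", "e"}])
        assert plasma_tissue_concordance(tracked, cohort, "tissue_recall")[1] == 0.5
        assert plasma_tissue_concordance(tracked, cohort, "jaccard")[1] == pytest.approx(2 / 5)

    def test_plasma_superset_gives_full_tissue_recall(self):
        cohort, tracked = _mini_cohort([{"a", "b", "c"}], [{"a", "b"}])
        assert plasma_tissue_concordance(tracked, cohort, "tissue_recall")[1] == 1.0


class TestCorrelation:
    def test_exact_linearity(self):
        x = np.arange(10.0)
        assert correlate_series(x, 2 * x + 1) == pytest.approx(1.0)

    def test_monotone_nonlinearity(self):
        x = np.linspace(0, 5, 12)
        assert correlate_series(x, np.exp(x), "spearman") == pytest.approx(1.0)
        assert correlate_series(x, np.exp(x), "pearson") < 1.0

    def test_anti_ordered(self):
        x = np.arange(8.0)
        assert correlate_series(x, -x, "spearman") == pytest.approx(-1.0)

    def test_too_few_pairs_undefined(self):
        with pytest.warns(UserWarning):
            assert np.isnan(correlate_series([1, 2], [3, 4]))


class TestTrajectories:
    def test_eoc429_nf1_points(self, eoc429):
        res = run_filter_chain(eoc429.cohort)
        points = build_trajectories(res.tracked, eoc429.cohort)
        nf1 = points[(points["gene"] == "NF1")].sort_values("timepoint_days")
        assert list(nf1["vaf"].round(3)) == [0.34, 0.054, 0.0]
        # absent from the last plasma sample: completed with an imputed zero
        assert bool(nf1["imputed"].iloc[-1])

    def test_every_tracked_variant_covers_every_plasma_sample(self, eoc429):
        res = run_filter_chain(eoc429.cohort)
        points = build_trajectories(res.tracked, eoc429.cohort)
        counts = points[points["patient_id"] == "EOC429"].groupby("key").size()
        assert (counts == 3).all()

    def test_points_sorted_by_day(self, eoc429):
        res = run_filter_chain(eoc429.cohort)
        points = build_trajectories(res.tracked, eoc429.cohort)
        for _, grp in points.groupby(["patient_id", "key"]):
            assert grp["timepoint_days"].is_monotonic_increasing


class TestTruncalSelection:
    def test_two_tp53_variants_argmax_tissue(self, eoc736):
        cohort = eoc736.cohort
        extra = cohort.variants.iloc[[0]].copy()
        extra.loc[:, ["pos", "alt_count"]] = [7578999, 10]  # second TP53 at 5% tissue VAF
        tracked = pd.concat([cohort.variants, extra], ignore_index=True)
        key = select_truncal_tp53(tracked, cohort, "EOC736")
        assert key == "17:7577100:G:A"

    def test_single_variant_selected(self, eoc429):
        res = run_filter_chain(eoc429.cohort)
        assert select_truncal_tp53(res.tracked, eoc429.cohort, "EOC429") == "17:7577538:C:T"

    def test_no_tp53_warns_and_returns_none(self, eoc429):
        res = run_filter_chain(eoc429.cohort)
        no_tp53 = res.tracked[res.tracked["gene"] != "TP53"]
        with pytest.warns(UserWarning, match="TP53"):
            assert select_truncal_tp53(no_tp53, eoc429.cohort, "EOC429") is None


class TestMonitorEndToEnd:
    def test_eoc429_good_responder(self, eoc429):
        res = run_filter_chain(eoc429.cohort)
        mon = monitor_cohort(res.tracked, eoc429.cohort)
        call = mon.responder_calls.set_index("patient_id").loc["EOC429"]
        assert call["predicted"] == "good" and call["truth"] == "good"
        assert call["n_mutations"] == 8

    def test_eoc736_poor_responder_with_persistent_tp53(self, eoc736):
        res = run_filter_chain(eoc736.cohort)
        mon = monitor_cohort(res.tracked, eoc736.cohort)
        call = mon.responder_calls.set_index("patient_id").loc["EOC736"]
        assert call["predicted"] == "poor" and call["truth"] == "poor"
        burden = mon.burden[mon.burden["patient_id"] == "EOC736"]
        assert (burden["tp53_vaf"] > 0.05).all()  # detectable throughout treatment

    def test_summary_mentions_concordance(self, eoc429):
        res = run_filter_chain(eoc429.cohort)
        mon = monitor_cohort(res.tracked, eoc429.cohort)
        assert "concordance" in mon.summary()
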