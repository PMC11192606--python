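"""Normality-gated summaries, t-tests, Pearson correlation, reclassification."""

import numpy as np
import pandas as pd
import pytest

import lvtrab as lt
from lvtrab.stats import compare, correlate, reclassify, summarize


class TestSummarize:
    def test_constant_sample_flagged_degenerate(self):
        rep = summarize([1.0] * 10)
        assert rep.sd == 0.0
        assert rep.normal is None
        assert any("degenerate" in f for f in rep.flags)

    def test_large_normal_sample(self):
        rng = np.random.default_rng(0)
        rep = summarize(rng.standard_normal(10_000))
        assert abs(rep.mean) < 0.05
        assert rep.sd == pytest.approx(1.0, abs=0.05)
        assert rep.summary_kind == "mean_sd"

    def test_skewed_sample_reported_as_median_iqr(self):
        rng = np.random.default_rng(1)
        rep = summarize(rng.exponential(size=200))
        assert rep.summary_kind == "median_iqr"
        assert "(" in rep.estimate

    def test_tiny_sample_skips_normality_gate(self):
        rep = summarize([1.0, 2.0])
        assert rep.normal is None
        assert any("too few" in f for f in rep.flags)


class TestCompare:
    def test_identical_paired_columns(self):
        rep = compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], mode="paired")
        assert rep.statistic == 0.0
        assert rep.p_value == 1.0

    def test_paired_t_against_hand_computed_three_points(self):
        # diffs 1,2,3: mean 2, sd 1, t = 2/(1/sqrt(3)) = 2*sqrt(3);
        # for df=2, F(t) = 1/2*(1 + t/sqrt(t^2+2)) -> two-sided p = 0.0742
        rep = compare([1.0, 2.0, 3.0], [0.0, 0.0, 0.0], mode="paired")
        t = 2 * np.sqrt(3)
        assert rep.statistic == pytest.approx(t, abs=1e-9)
        p_hand = 2 * (1 - 0.5 * (1 + t / np.sqrt(t**2 + 2)))
        assert rep.p_value == pytest.approx(p_hand, abs=1e-9)

    def test_one_sample_vs_unity_near_one(self):
        rep = compare([1.0, 1.0 + 1e-12, 1.0 - 1e-12], mode="one_sample_vs_unity")
        assert rep.p_value > 0.9

    def test_one_sample_vs_unity_hand_computed(self):
        rep = compare([2.0, 3.0, 4.0], mode="one_sample_vs_unity")
        assert rep.statistic == pytest.approx(2 * np.sqrt(3), abs=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            compare([1.0, 2.0], [1.0, 2.0, 3.0], mode="paired")

    def test_recess_vs_cavity_sfvc_power_on_synthetic_cohorts(self):
        """The recess-vs-cavity SFVC difference reaches p < 0.001 in at least
        90% of default n=15 cohorts."""
        hits = 0
        for seed in range(100):
            table = lt.generate_cohort_table(lt.CohortSpec(n_subjects=15, seed=seed))
            mt = lt.cohort_metric_table(table)
            rep = compare(mt["sfvc_ir"], mt["sfvc_cc"], mode="paired")
            hits += rep.p_value < 0.001
        assert hits >= 90


class TestCorrelate:
    def test_perfect_correlation(self):
        rep = correlate([0.0, 1.0, 2.0], [0.0, 2.0, 4.0])
        assert rep.statistic == pytest.approx(1.0)
        assert rep.sd == pytest.approx(1.0)  # R²

    def test_hand_computed_three_points(self):
        # x=[0,1,2], y=[0,1,4]: r = 4 / (sqrt(2)*sqrt(26/3))
        rep = correlate([0.0, 1.0, 2.0], [0.0, 1.0, 4.0])
        r_hand = 4 / (np.sqrt(2.0) * np.sqrt(26 / 3))
        assert rep.statistic == pytest.approx(r_hand, abs=1e-12)

    def test_negative_relation_has_negative_r(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=100)
        rep = correlate(x, -x + 0.1 * rng.normal(size=100))
        assert rep.statistic < 0

    def test_null_simulation(self):
        rng = np.random.default_rng(3)
        rep = correlate(rng.normal(size=10_000), rng.normal(size=10_000))
        assert abs(rep.statistic) < 0.05

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            correlate([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])


class TestReclassify:
    def test_identical_conventions_give_diagonal_table(self):
        table = pd.DataFrame({
            "ef_guidelines": [0.35, 0.45, 0.55],
            "ef_contour": [0.35, 0.45, 0.55],
        })
        out = reclassify(table)
        assert out["fraction_reclassified"] == 0.0
        assert np.trace(out["table"].to_numpy()) == 3

    def test_excessive_baseline_moves_one_subject_upward(self):
        m = lt.baseline("excessive")
        table = pd.DataFrame({
            "ef_guidelines": [lt.convention_ef(m, "guidelines").ef],  # 0.476
            "ef_contour": [lt.convention_ef(m, "contour").ef],        # 0.60
        })
        out = reclassify(table)
        assert out["table"].loc["40_to_50", "above_50"] == 1
        assert out["fraction_reclassified"] == 1.0

    def test_marginals_sum_to_n_and_movement_is_upward_only(self):
        table = lt.generate_cohort_table(lt.CohortSpec(n_subjects=40, seed=6))
        mt = lt.cohort_metric_table(table)
        out = reclassify(mt)
        assert sum(out["guidelines_marginals"].values()) == out["n"] == 40
        # contouring only raises EF: the lower triangle must be empty
        counts = out["table"].to_numpy()
        assert np.tril(counts, k=-1).sum() == 0
        below_g = out["guidelines_marginals"]["below_40"]
        below_c = out["contour_marginals"]["below_40"]
        assert below_c <= below_g

    def test_missing_convention_excluded_and_logged(self):
        table = pd.DataFrame({
            "ef_guidelines": [0.35, np.nan],
            "ef_contour": [0.45, 0.5],
        })
        out = reclassify(table)
        assert out["n"] == 1
        assert out["excluded"] == [1]
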