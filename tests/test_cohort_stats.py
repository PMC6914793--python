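"""Statistics layer: diagnostic accuracy, kappa, correlation, t test, Cox RFS."""

import numpy as np
import pandas as pd
import pytest

from bpequant import (
    cohen_kappa,
    diagnostic_accuracy,
    fit_recurrence_model,
    fleiss_kappa,
    pearson_r,
    simulate_cohort,
    two_sample_t,
)


class TestDiagnosticAccuracy:
    def test_contingency_counts(self):
        """25/27 true responders detected, 12 false alarms among 75 -> 92.6 / 84.0."""
        acc = diagnostic_accuracy(tp=25, fn=2, fp=12, tn=63)
        assert round(acc.sensitivity, 1) == 92.6
        assert round(acc.specificity, 1) == 84.0
        assert round(acc.sensitivity) == 93
        assert round(acc.specificity) == 84

    def test_wald_intervals_clip_to_printed_bounds(self):
        acc = diagnostic_accuracy(tp=25, fn=2, fp=12, tn=63)
        lo_s, hi_s = acc.ci_sensitivity
        lo_p, hi_p = acc.ci_specificity
        # oracle: direct formula evaluation p +/- 1.96 sqrt(p(1-p)/n), clipped
        p = 25 / 27
        half = 1.959963984540054 * np.sqrt(p * (1 - p) / 27)
        np.testing.assert_allclose(lo_s, 100 * (p - half))
        assert hi_s == 100.0  # clipped
        assert (round(lo_s), round(hi_s)) == (83, 100)
        assert (round(lo_p), round(hi_p)) == (76, 92)

    def test_clopper_pearson_available(self):
        acc = diagnostic_accuracy(25, 2, 12, 63, ci_method="clopper-pearson")
        lo, hi = acc.ci_sensitivity
        assert 0 <= lo < acc.sensitivity < hi <= 100

    def test_symmetric_counts_give_50(self):
        assert diagnostic_accuracy(tp=7, fn=7, fp=3, tn=5).sensitivity == 50.0

    def test_transposed_table_swaps_sensitivity_and_specificity(self):
        a = diagnostic_accuracy(25, 2, 12, 63)
        b = diagnostic_accuracy(tp=63, fn=12, fp=2, tn=25)
        assert a.sensitivity == b.specificity
        assert a.specificity == b.sensitivity

    @pytest.mark.parametrize("counts", [(0, 0, 5, 5), (5, 5, 0, 0), (-1, 2, 3, 4)])
    def test_degenerate_margins_rejected(self, counts):
        with pytest.raises(ValueError):
            diagnostic_accuracy(*counts)


class TestKappa:
    def test_perfect_agreement_is_one(self):
        r = cohen_kappa(["a", "b", "c", "a", "b"], ["a", "b", "c", "a", "b"])
        assert r.kappa == 1.0

    def test_hand_calculation_on_2x2_counts(self):
        """40 both-yes, 40 both-no, 20 split disagreements: kappa = 0.6 by hand."""
        a = ["y"] * 40 + ["n"] * 40 + ["y"] * 10 + ["n"] * 10
        b = ["y"] * 40 + ["n"] * 40 + ["n"] * 10 + ["y"] * 10
        # p_o = 0.8; marginals 0.5/0.5 -> p_e = 0.5; kappa = (0.8-0.5)/0.5 = 0.6
        r = cohen_kappa(a, b)
        np.testing.assert_allclose(r.kappa, 0.6)
        assert r.p_value < 0.001

    def test_independent_ratings_give_near_zero_kappa(self):
        rng = np.random.default_rng(0)
        n = 20_000
        a = rng.choice(["a", "b", "c"], n, p=[0.5, 0.3, 0.2])
        b = rng.choice(["a", "b", "c"], n, p=[0.5, 0.3, 0.2])
        assert abs(cohen_kappa(a, b).kappa) < 0.02

    def test_invariant_to_relabelling(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 4, 200)
        b = np.where(rng.random(200) < 0.7, a, rng.integers(0, 4, 200))
        relabel = {0: "D", 1: "C", 2: "B", 3: "A"}
        r1 = cohen_kappa(a, b)
        r2 = cohen_kappa([relabel[v] for v in a], [relabel[v] for v in b])
        np.testing.assert_allclose(r1.kappa, r2.kappa)

    def test_constant_raters_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            cohen_kappa([1, 1, 1], [1, 1, 1])

    def test_fleiss_multi_rater_form(self):
        rng = np.random.default_rng(2)
        base = rng.integers(1, 5, 60)
        ratings = np.column_stack(
            [np.where(rng.random(60) < 0.8, base, rng.integers(1, 5, 60)) for _ in range(3)]
        )
        r = fleiss_kappa(ratings)
        assert 0.3 < r.kappa <= 1.0
        assert r.method == "fleiss"


class TestCorrelationAndT:
    def test_exact_linear_relations(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1).statistic == pytest.approx(1.0)
        assert pearson_r(x, -x).statistic == pytest.approx(-1.0)

    def test_bivariate_normal_sampling_check(self):
        rng = np.random.default_rng(3)
        n = 10_000
        x = rng.normal(size=n)
        y = 0.5 * x + np.sqrt(1 - 0.25) * rng.normal(size=n)
        assert abs(pearson_r(x, y).statistic - 0.5) < 0.03

    def test_identical_groups_t_zero(self):
        g = np.arange(10.0)
        r = two_sample_t(g, g)
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(1.0)

    def test_swapping_groups_flips_sign(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(0, 1, 30), rng.normal(1, 1, 30)
        assert two_sample_t(x, y).statistic == pytest.approx(-two_sample_t(y, x).statistic)

    def test_shifted_normals_power(self):
        """delta = 1 sigma at n=50/50: p < 0.01 in >= 95% of simulations."""
        rng = np.random.default_rng(5)
        hits = sum(
            two_sample_t(rng.normal(0, 1, 50), rng.normal(1, 1, 50)).p_value < 0.01
            for _ in range(200)
        )
        assert hits >= 0.95 * 200

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            pearson_r([1.0, 2.0], [1.0, 2.0])


class TestCoxModel:
    def test_recovers_known_log_hazard_ratio(self):
        """Exponential times, binary covariate with true log-HR = 1, n = 500."""
        rng = np.random.default_rng(6)
        n = 500
        x = (rng.random(n) < 0.5).astype(float)
        t = rng.exponential(1.0 / (0.05 * np.exp(1.0 * x)))
        c = np.minimum(t, 30.0)
        df = pd.DataFrame(
            {"rfs_months": c, "recurrence": t <= 30.0, "x": x, "lost_to_followup": False}
        )
        res = fit_recurrence_model(df, ["x"])
        assert abs(res.summary.loc["x", "coef"] - 1.0) < 0.2
        assert res.summary.loc["x", "hazard_ratio"] == pytest.approx(
            np.exp(res.summary.loc["x", "coef"])
        )

    def test_null_covariate_ci_covers_one(self):
        """Independent covariate: 95% CI covers HR = 1 in most replicates."""
        cover = 0
        reps = 40
        for s in range(reps):
            rng = np.random.default_rng(100 + s)
            n = 120
            x = rng.normal(size=n)
            t = rng.exponential(10.0, n)
            df = pd.DataFrame({"rfs_months": np.minimum(t, 25.0), "recurrence": t <= 25.0, "x": x})
            res = fit_recurrence_model(df, ["x"])
            lo, hi = res.summary.loc["x", ["hr_ci_lower", "hr_ci_upper"]]
            cover += lo <= 1.0 <= hi
        assert cover >= 0.85 * reps

    def test_all_censored_is_explicit_error(self):
        df = pd.DataFrame({"rfs_months": [5.0, 6.0, 7.0], "recurrence": [False] * 3, "x": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="no recurrence events"):
            fit_recurrence_model(df, ["x"])

    def test_lost_to_followup_rows_are_excluded(self):
        rng = np.random.default_rng(7)
        n = 80
        t = rng.exponential(10, n)
        df = pd.DataFrame(
            {
                "rfs_months": np.minimum(t, 20),
                "recurrence": t <= 20,
                "x": rng.normal(size=n),
                "lost_to_followup": [True] * 10 + [False] * (n - 10),
            }
        )
        res = fit_recurrence_model(df, ["x"])
        assert res.n == n - 10

    def test_bpe_hazard_association_detected(self):
        """Structural analogue: hazard increasing with post-treatment BPE20%
        is flagged (HR > 1, p < 0.05) in >= 90% of simulated cohorts at n=100."""
        hits = 0
        reps = 30
        for s in range(reps):
            cohort = simulate_cohort(n=100, seed=s, log_hr_bpe_post=1.0)
            res = fit_recurrence_model(cohort, ["bpe20_post"])
            hits += (
                res.summary.loc["bpe20_post", "hazard_ratio"] > 1.0
                and res.summary.loc["bpe20_post", "p_value"] < 0.05
            )
        assert hits >= 0.90 * reps


class TestSimulateCohort:
    def test_deterministic_and_schema(self):
        a = simulate_cohort(n=50, seed=3)
        b = simulate_cohort(n=50, seed=3)
        pd.testing.assert_frame_equal(a, b)
        assert {"bpe20_pre", "bpe20_post", "pcr", "recurrence", "rfs_months"} <= set(a.columns)

    def test_event_rate_near_design(self):
        cohort = simulate_cohort(n=100, seed=1)
        events = int(cohort["recurrence"].sum())
        assert 5 <= events <= 30  # designed for roughly 15 events per 100
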