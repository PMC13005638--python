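import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
import statsmodels.formula.api as smf

from adhera import (
    build_person_periods,
    compute_smd,
    dispersion_switch,
    fit_cost_lmm,
    fit_count_glmm,
    fit_count_model,
    group_compare,
)
from adhera.stats import ADHERENT_PERIOD, NONADHERENT_PERIOD, StatsConfig


def simulate_person_periods(rng, n, rate_ratio, sigma=0.5, base=1.0,
                            gamma_disp=None, with_cost=False, cost_effect=0.0,
                            cost_sigma=0.0):
    """Direct person-period simulator with known ground truth."""
    rows = []
    for i in range(n):
        u = rng.normal(0, sigma)
        cu = rng.normal(0, cost_sigma) if cost_sigma else 0.0
        d1 = int(rng.integers(100, 300))
        for state, days in ((ADHERENT_PERIOD, d1), (NONADHERENT_PERIOD, 365 - d1)):
            mu = base / 365 * days * np.exp(u)
            if state == NONADHERENT_PERIOD:
                mu *= rate_ratio
            if gamma_disp:
                mu *= rng.gamma(1 / gamma_disp, gamma_disp)
            row = {
                "patient_id": f"P{i:04d}",
                "state": state,
                "person_days": days,
                "count_ev": int(rng.poisson(mu)),
            }
            if with_cost:
                row["cost"] = (
                    1000.0
                    + cu
                    + (cost_effect if state == NONADHERENT_PERIOD else 0.0)
                    + rng.normal(0, 100)
                )
            rows.append(row)
    return pd.DataFrame(rows)


class FakeSummary:
    def __init__(self, patient_id, covered):
        self.patient_id = patient_id
        self.covered = covered


class TestPersonPeriods:
    def test_fully_covered_patient_is_one_adherent_period(self):
        periods = build_person_periods([FakeSummary("P1", [(0, 365)])])
        assert len(periods) == 1
        row = periods.iloc[0]
        assert row["state"] == ADHERENT_PERIOD and row["person_days"] == 365

    def test_event_lands_in_uncovered_period(self):
        events = pd.DataFrame(
            {"patient_id": ["P1"], "event_type": ["exac"], "day": [150]}
        )
        periods = build_person_periods(
            [FakeSummary("P1", [(0, 100)])], events=events
        )
        by_state = periods.set_index("state")["count_exac"]
        assert by_state[NONADHERENT_PERIOD] == 1 and by_state[ADHERENT_PERIOD] == 0

    def test_event_outside_followup_is_fatal(self):
        events = pd.DataFrame(
            {"patient_id": ["P1"], "event_type": ["exac"], "day": [400]}
        )
        with pytest.raises(ValueError, match="outside follow-up"):
            build_person_periods([FakeSummary("P1", [(0, 100)])], events=events)

    def test_person_days_conserved_across_cohort(self, small_cohort):
        periods = build_person_periods(small_cohort["summaries"])
        totals = periods.groupby("patient_id")["person_days"].sum()
        assert (totals == 365).all()
        assert len(totals) == len(small_cohort["summaries"])


class TestCountGlmm:
    def test_rate_ratio_recovery(self):
        rng = np.random.default_rng(10)
        periods = simulate_person_periods(rng, 2000, rate_ratio=2.0)
        res = fit_count_glmm(periods, "ev")
        assert res.effect == pytest.approx(2.0, rel=0.15)
        assert res.p_value < 0.001

    def test_null_confidence_coverage(self):
        """Under no effect the 95% CI covers a rate ratio of 1 in >=90/100."""
        rng = np.random.default_rng(11)
        covered = 0
        for _ in range(100):
            periods = simulate_person_periods(rng, 120, rate_ratio=1.0)
            res = fit_count_glmm(periods, "ev")
            if res.p_value >= 0.05:
                covered += 1
        assert covered >= 90

    def test_zero_random_effect_matches_plain_poisson(self):
        rng = np.random.default_rng(12)
        periods = simulate_person_periods(rng, 800, rate_ratio=2.0, sigma=0.0)
        res = fit_count_glmm(periods, "ev")
        x = sm.add_constant(
            (periods["state"] == NONADHERENT_PERIOD).to_numpy(float)
        )
        glm = sm.GLM(
            periods["count_ev"],
            x,
            family=sm.families.Poisson(),
            offset=np.log(periods["person_days"]),
        ).fit()
        assert res.extra["theta"][1] == pytest.approx(glm.params.iloc[1], abs=1e-3)
        # the intercept can shift slightly while the variance sits at its
        # lower bound; the state effect is the estimate of interest
        assert res.extra["theta"][0] == pytest.approx(glm.params.iloc[0], abs=0.05)

    def test_all_zero_outcome_flagged(self):
        periods = simulate_person_periods(
            np.random.default_rng(0), 20, rate_ratio=1.0
        )
        periods["count_ev"] = 0
        res = fit_count_glmm(periods, "ev")
        assert not res.converged and np.isnan(res.effect)


class TestDispersionSwitch:
    def test_poisson_data_statistic_near_one(self):
        rng = np.random.default_rng(13)
        stats = []
        for _ in range(20):
            periods = simulate_person_periods(rng, 400, rate_ratio=2.0, base=4.0)
            res = fit_count_glmm(periods, "ev")
            stat, switch = dispersion_switch(res, periods)
            stats.append(stat)
        assert 0.8 <= np.mean(stats) <= 1.2

    def test_gamma_heterogeneity_triggers_switch(self):
        """Period-level variance twice the mean flips the family."""
        rng = np.random.default_rng(14)
        triggered = 0
        for _ in range(5):
            periods = simulate_person_periods(
                rng, 400, rate_ratio=2.0, base=4.0, gamma_disp=0.5
            )
            res = fit_count_glmm(periods, "ev")
            _, switch = dispersion_switch(res, periods)
            triggered += switch
        assert triggered >= 4

    def test_infinite_threshold_never_switches(self):
        rng = np.random.default_rng(15)
        periods = simulate_person_periods(
            rng, 200, rate_ratio=2.0, base=4.0, gamma_disp=1.0
        )
        res = fit_count_glmm(periods, "ev")
        _, switch = dispersion_switch(
            res, periods, StatsConfig(dispersion_threshold=np.inf)
        )
        assert not switch

    def test_switched_model_reports_negbin_family(self):
        rng = np.random.default_rng(16)
        periods = simulate_person_periods(
            rng, 400, rate_ratio=2.0, base=4.0, gamma_disp=1.0
        )
        res = fit_count_model(periods, "ev")
        assert res.family == "negbin_glmm"
        assert res.dispersion > 1.5
        assert res.effect == pytest.approx(2.0, rel=0.3)


class TestCostLmm:
    def test_cost_effect_recovery_within_two_se(self):
        rng = np.random.default_rng(17)
        periods = simulate_person_periods(
            rng, 2000, rate_ratio=1.0, with_cost=True, cost_effect=500.0,
            cost_sigma=200.0
        )
        res = fit_cost_lmm(periods)
        assert res.family == "lmm"
        assert abs(res.effect - 500.0) <= 2 * res.log_effect_se

    def test_identical_costs_flagged_zero_effect(self):
        rng = np.random.default_rng(18)
        periods = simulate_person_periods(rng, 50, rate_ratio=1.0, with_cost=True)
        periods["cost"] = 1234.0
        res = fit_cost_lmm(periods)
        assert res.effect == 0.0 and res.extra.get("flagged")

    def test_zero_variance_random_intercept_matches_ols(self):
        rng = np.random.default_rng(19)
        periods = simulate_person_periods(
            rng, 400, rate_ratio=1.0, with_cost=True, cost_effect=300.0,
            cost_sigma=0.0
        )
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            res = fit_cost_lmm(periods)
        periods["nonadherent"] = (periods["state"] == NONADHERENT_PERIOD).astype(float)
        ols = smf.ols("cost ~ nonadherent", periods).fit()
        assert res.effect == pytest.approx(ols.params["nonadherent"], rel=1e-3)


class TestGroupCompare:
    def test_identical_groups_give_null_statistic(self):
        rng = np.random.default_rng(20)
        v = rng.normal(size=40)
        values = np.concatenate([v, v])
        labels = np.array(["a"] * 40 + ["b"] * 40)
        res = group_compare(values, labels, "continuous")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value > 0.99

    def test_shifted_normal_groups_detected_by_anova(self):
        rng = np.random.default_rng(21)
        values = np.concatenate([rng.normal(0, 1, 50), rng.normal(2, 1, 50)])
        labels = np.array(["a"] * 50 + ["b"] * 50)
        res = group_compare(values, labels, "continuous")
        assert res.method == "anova"
        assert res.p_value < 0.001

    def test_heavy_tails_take_kruskal_branch(self):
        rng = np.random.default_rng(22)
        values = np.concatenate(
            [rng.standard_cauchy(80), rng.standard_cauchy(80) + 1]
        )
        labels = np.array(["a"] * 80 + ["b"] * 80)
        res = group_compare(values, labels, "continuous")
        assert res.method == "kruskal_wallis"

    def test_count_outcome_uses_poisson_regression(self):
        rng = np.random.default_rng(23)
        values = np.concatenate([rng.poisson(1.0, 80), rng.poisson(2.0, 80)])
        labels = np.array(["a"] * 80 + ["b"] * 80)
        res = group_compare(values, labels, "count")
        assert res.method == "poisson_regression"
        assert res.p_value < 0.01

    def test_binary_outcome_uses_logistic(self):
        rng = np.random.default_rng(24)
        values = np.concatenate(
            [rng.random(100) < 0.2, rng.random(100) < 0.5]
        ).astype(float)
        labels = np.array(["a"] * 100 + ["b"] * 100)
        res = group_compare(values, labels, "binary")
        assert res.method == "logistic_regression"
        assert res.p_value < 0.01

    def test_tiny_group_excluded_with_warning(self):
        values = np.array([1.0, 2.0, 3.0, 4.0, 9.0])
        labels = np.array(["a", "a", "b", "b", "c"])
        with pytest.warns(UserWarning, match="n<2"):
            res = group_compare(values, labels, "continuous")
        assert res.excluded_groups == ["c"]


class TestSmd:
    def test_identical_groups_zero(self):
        values = np.concatenate([np.arange(10.0), np.arange(10.0)])
        labels = np.array(["a"] * 10 + ["b"] * 10)
        assert compute_smd(values, labels) == 0.0

    def test_unit_shift_closed_form(self):
        rng = np.random.default_rng(25)
        a = rng.normal(0, 1, 50000)
        values = np.concatenate([a, a + 1.0])
        labels = np.array(["a"] * 50000 + ["b"] * 50000)
        assert compute_smd(values, labels) == pytest.approx(1.0, abs=0.02)

    def test_equal_proportions_zero(self):
        values = pd.Series(["y", "n"] * 20)
        labels = np.array(["a", "a", "b", "b"] * 10)
        assert compute_smd(values, labels) == pytest.approx(0.0, abs=1e-12)

    def test_binary_proportion_closed_form(self):
        # groups with event proportions 0.3 and 0.5
        values = pd.Series(["y"] * 30 + ["n"] * 70 + ["y"] * 50 + ["n"] * 50)
        labels = np.array(["a"] * 100 + ["b"] * 100)
        expected = 0.2 / np.sqrt((0.3 * 0.7 + 0.5 * 0.5) / 2)
        assert compute_smd(values, labels) == pytest.approx(expected)

    def test_multigroup_is_max_pairwise(self):
        values = np.concatenate(
            [np.zeros(50), np.ones(50), np.full(50, 3.0)]
        ) + np.tile(np.linspace(-0.5, 0.5, 50), 3)
        labels = np.repeat(["a", "b", "c"], 50)
        pair = compute_smd(values[:100][np.r_[0:50, 50:100]],
                           labels[:100])
        full = compute_smd(values, labels)
        assert full >= pair

    def test_zero_pooled_sd_with_unequal_means_is_infinite(self):
        values = np.array([1.0, 1.0, 2.0, 2.0])
        labels = np.array(["a", "a", "b", "b"])
        with pytest.warns(UserWarning, match="infinite"):
            assert compute_smd(values, labels) == np.inf
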