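"""Survival estimators: hand-computed oracles, consistency, calibration."""

import numpy as np
import pandas as pd
import pytest

from hingepoint import datagen
from hingepoint.survival import (
    cox_fit,
    interaction_model,
    nelson_aalen,
    rfs_at,
    stratified_comparison,
    stratum_table,
)


def make_two_arm_exponential(n_per_arm, hr, lam0=0.1, censor=5.5, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for arm_ind, lam in ((0, lam0), (1, lam0 * hr)):
        t = rng.exponential(1 / lam, n_per_arm)
        c = censor - rng.uniform(0, 1, n_per_arm)
        rows.append(
            pd.DataFrame(
                {
                    "time_years": np.minimum(t, c),
                    "event": (t <= c).astype(int),
                    "arm_indicator": arm_ind,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


class TestNelsonAalen:
    def test_three_subject_hand_computation(self):
        curve = nelson_aalen([1.0, 2.0, 3.0], [1, 1, 1])
        np.testing.assert_allclose(curve.event_times, [1, 2, 3])
        np.testing.assert_allclose(
            curve.cumulative_hazard, [1 / 3, 1 / 3 + 1 / 2, 1 / 3 + 1 / 2 + 1]
        )
        np.testing.assert_array_equal(curve.at_risk, [3, 2, 1])

    def test_all_censored_yields_flat_zero(self):
        with pytest.warns(UserWarning, match="no events"):
            curve = nelson_aalen([1.0, 2.0], [0, 0])
        assert len(curve.event_times) == 0

    def test_large_exponential_sample_approaches_closed_form(self):
        lam = 0.3
        rng = np.random.default_rng(2)
        t = rng.exponential(1 / lam, 20_000)
        curve = nelson_aalen(t, np.ones_like(t, dtype=int))
        # H(t) = lam * t in the uncensored exponential limit
        at_2 = np.interp(2.0, curve.event_times, curve.cumulative_hazard)
        assert at_2 == pytest.approx(lam * 2.0, rel=0.05)

    def test_agrees_with_kaplan_meier_via_exponential_identity(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(5.0, 5000)
        c = np.full_like(t, 8.0)
        time = np.minimum(t, c)
        event = (t <= c).astype(int)
        curve = nelson_aalen(time, event)
        km_5 = rfs_at(time, event, horizon=5.0)
        h_5 = np.interp(5.0, curve.event_times, curve.cumulative_hazard)
        assert np.exp(-h_5) == pytest.approx(km_5, rel=0.02)


class TestRfsAt:
    def test_no_events_is_one(self):
        assert rfs_at([1.0, 2.0, 3.0], [0, 0, 0], horizon=2.5) == 1.0

    def test_single_subject_event_before_horizon(self):
        assert rfs_at([2.0], [1], horizon=5.0) == 0.0

    def test_exponential_closed_form(self):
        # S(5) = 0.71 <=> lam = -ln(0.71)/5
        lam = -np.log(0.71) / 5
        rng = np.random.default_rng(4)
        t = rng.exponential(1 / lam, 10_000)
        est = rfs_at(t, np.ones_like(t, dtype=int), horizon=5.0)
        assert est == pytest.approx(0.71, abs=0.02)

    def test_horizon_beyond_followup_warns(self):
        with pytest.warns(UserWarning, match="beyond last observed"):
            rfs_at([1.0, 2.0], [1, 0], horizon=10.0)


def exhaustive_partial_likelihood_beta(df):
    """Grid/golden-section oracle: maximize the (Breslow/no-ties) partial
    likelihood for one binary covariate on a tiny no-ties dataset."""
    order = df.sort_values("time_years")
    times = order["time_years"].to_numpy()
    events = order["event"].to_numpy()
    z = order["arm_indicator"].to_numpy().astype(float)

    def neg_loglik(beta):
        ll = 0.0
        for i in range(len(times)):
            if events[i] != 1:
                continue
            risk = times >= times[i]
            ll += beta * z[i] - np.log(np.sum(np.exp(beta * z[risk])))
        return -ll

    from scipy.optimize import minimize_scalar

    res = minimize_scalar(neg_loglik, bounds=(-5, 5), method="bounded")
    return float(res.x)


class TestCoxFit:
    def test_identical_event_patterns_give_unit_hazard_ratio(self):
        df = pd.DataFrame(
            {
                "time_years": [1, 2, 3, 4, 1, 2, 3, 4],
                "event": [1, 1, 0, 1, 1, 1, 0, 1],
                "arm_indicator": [0, 0, 0, 0, 1, 1, 1, 1],
            }
        ).astype(float)
        fit = cox_fit(df, ["arm_indicator"])
        assert fit.hr["arm_indicator"] == pytest.approx(1.0, abs=1e-6)

    def test_matches_exhaustive_partial_likelihood_on_tiny_data(self):
        df = pd.DataFrame(
            {
                "time_years": [1.1, 2.3, 3.7, 4.1, 5.2, 6.9, 7.4, 8.8],
                "event": [1, 1, 1, 0, 1, 1, 0, 1],
                "arm_indicator": [0, 1, 0, 1, 0, 1, 0, 1],
            }
        )
        fit = cox_fit(df, ["arm_indicator"])
        oracle = exhaustive_partial_likelihood_beta(df)
        assert fit.coefficients["arm_indicator"] == pytest.approx(oracle, abs=1e-3)

    def test_consistency_on_simulated_two_arm_data(self):
        df = make_two_arm_exponential(2000, hr=0.5, seed=5)
        fit = cox_fit(df, ["arm_indicator"])
        assert fit.hr["arm_indicator"] == pytest.approx(0.5, abs=0.07)
        lo, hi = fit.ci95["arm_indicator"]
        assert lo < fit.hr["arm_indicator"] < hi

    def test_log_scale_ci_symmetry(self):
        df = make_two_arm_exponential(300, hr=0.6, seed=6)
        fit = cox_fit(df, ["arm_indicator"])
        lo, hi = fit.ci95["arm_indicator"]
        hr = fit.hr["arm_indicator"]
        assert np.log(hi) - np.log(hr) == pytest.approx(np.log(hr) - np.log(lo), abs=1e-6)

    def test_separated_data_flagged_not_raised(self):
        # all events in one arm, none in the other: monotone likelihood
        df = pd.DataFrame(
            {
                "time_years": np.r_[np.linspace(0.2, 2.0, 10), np.full(10, 9.9)],
                "event": np.r_[np.ones(10), np.zeros(10)].astype(int),
                "arm_indicator": np.r_[np.ones(10), np.zeros(10)].astype(int),
            }
        )
        fit = cox_fit(df, ["arm_indicator"])
        assert not fit.converged

    def test_no_events_raises(self):
        df = pd.DataFrame(
            {"time_years": [1.0, 2.0], "event": [0, 0], "arm_indicator": [0, 1]}
        )
        with pytest.raises(ValueError, match="no events"):
            cox_fit(df, ["arm_indicator"])

    def test_wald_null_calibration(self):
        # with identical hazards the Wald test must reject at ~5%
        rejections = 0
        n_sims = 500
        for seed in range(n_sims):
            df = make_two_arm_exponential(40, hr=1.0, lam0=0.25, seed=seed)
            fit = cox_fit(df, ["arm_indicator"])
            if fit.converged and fit.p["arm_indicator"] < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_sims <= 0.07


class TestInteractionModel:
    @staticmethod
    def _make(hr_low, hr_high, n=250, seed=0):
        rng = np.random.default_rng(seed)
        frames = []
        for high in (0, 1):
            hr = hr_high if high else hr_low
            df = make_two_arm_exponential(n, hr=hr, lam0=0.15, seed=rng.integers(2**31))
            df["high_group"] = high
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def test_interaction_column_is_elementwise_product(self):
        df = self._make(1.0, 0.5)
        df["interaction"] = df["arm_indicator"] * df["high_group"]
        assert (df["interaction"] == df["arm_indicator"] * df["high_group"]).all()
        assert set(df["interaction"].unique()) == {0, 1}

    def test_differential_effect_detected(self):
        df = self._make(1.0, 0.45, n=400, seed=1)
        fit, p = interaction_model(df)
        assert p < 0.05
        assert fit.hr["interaction"] < 1.0

    def test_null_interaction_p_roughly_uniform(self):
        ps = []
        for seed in range(60):
            df = self._make(0.8, 0.8, n=120, seed=seed)
            try:
                _, p = interaction_model(df)
            except ValueError:
                continue
            ps.append(p)
        ps = np.asarray(ps)
        # uniform(0,1) checks: mean near 0.5 and ~5% below 0.05
        assert abs(ps.mean() - 0.5) < 0.12
        assert (ps < 0.05).mean() < 0.15

    def test_empty_cell_error_names_cell(self):
        df = self._make(1.0, 1.0, n=50)
        df = df[~((df["arm_indicator"] == 1) & (df["high_group"] == 1))]
        with pytest.raises(ValueError, match="arm=1, high_group=1"):
            interaction_model(df)


class TestStratifiedComparison:
    def test_three_strata_partition_cohort(self, cohort):
        results = stratified_comparison(cohort, [17.0, 29.0])
        assert len(results) == 3
        assert sum(r.n for r in results) == len(cohort)
        labels = [r.label for r in results]
        assert labels[0].startswith("low") and labels[-1].startswith("high")

    def test_single_threshold_two_strata(self, cohort):
        results = stratified_comparison(cohort, [17.0])
        assert len(results) == 2
        assert sum(r.n for r in results) == len(cohort)

    def test_boundary_patients_follow_published_convention(self, cohort):
        modified = cohort.copy()
        modified.loc[modified.index[0], "x25ohd_baseline"] = 17.0  # -> low
        modified.loc[modified.index[1], "x25ohd_baseline"] = 29.0  # -> high
        modified.loc[modified.index[2], "x25ohd_baseline"] = 28.9  # -> intermediate
        results = stratified_comparison(modified, [17.0, 29.0])
        strata = {r.label: r for r in results}
        low = strata[[k for k in strata if k.startswith("low")][0]]
        assert low.n == (modified["x25ohd_baseline"] <= 17.0).sum()

    def test_intermediate_stratum_recovers_generator_effect(self, default_spec):
        from dataclasses import replace

        big = replace(
            default_spec,
            arms={
                "placebo": datagen.ArmDistribution(1500, 23.0, 3.0, 23.0, 3.0),
                "vitamin_d": datagen.ArmDistribution(1500, 23.0, 3.0, 44.0, 17.3),
            },
        )
        df = datagen.simulate_cohort(big, seed=30)
        results = stratified_comparison(df, [17.0, 29.0])
        mid = [r for r in results if r.label.startswith("intermediate")][0]
        assert mid.cox is not None
        assert mid.cox.hr["arm_indicator"] == pytest.approx(0.49, abs=0.12)

    def test_table_shape(self, cohort):
        table = stratum_table(stratified_comparison(cohort, [17.0, 29.0]))
        assert list(table["stratum"].str.split(" ").str[0]) == [
            "low", "intermediate", "high",
        ]
        assert {"rfs_placebo", "rfs_vitamin_d", "hr_treatment"} <= set(table.columns)
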