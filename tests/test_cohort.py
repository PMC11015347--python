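import numpy as np
import pytest

from obesity_cea.cohort import (
    annual_to_monthly_prob,
    bmi_slope,
    initial_state,
    run_strategy,
    step,
)
from obesity_cea.synth import make_scenarios


def test_annual_to_monthly_endpoints_and_example():
    assert annual_to_monthly_prob(0.0) == 0.0
    assert annual_to_monthly_prob(1.0) == 1.0
    assert annual_to_monthly_prob(0.10) == pytest.approx(1 - 0.9 ** (1 / 12))
    assert annual_to_monthly_prob(0.10) == pytest.approx(0.008742, abs=5e-7)
    with pytest.raises(ValueError):
        annual_to_monthly_prob(1.4)


@pytest.mark.parametrize(
    "strategy, compartment, cycle, kwargs, expected",
    [
        ("esg", "on_treatment", 6, {}, -0.40),
        ("esg", "on_treatment", 13, {}, 0.0065),
        ("semaglutide", "on_treatment", 12, {}, -0.34),
        ("semaglutide", "on_treatment", 30, {}, 0.0012),
        ("semaglutide", "dropped_out", 10, {"months_since_dropout": 2}, 0.0),
        ("semaglutide", "dropped_out", 10, {"months_since_dropout": 4}, 0.138),
        ("no_treatment", "on_treatment", 7, {}, 0.0127),
        ("esg", "post_repeat_esg", 30, {"months_since_repeat": 6}, -0.40),
        ("esg", "post_repeat_esg", 40, {"months_since_repeat": 16}, 0.0065),
    ],
)
def test_bmi_slope_schedule(ps, strategy, compartment, cycle, kwargs, expected):
    assert bmi_slope(strategy, compartment, cycle, ps, **kwargs) == pytest.approx(expected)


def test_bmi_slope_unknown_compartment_raises(ps):
    with pytest.raises(ValueError):
        bmi_slope("esg", "limbo", 5, ps)


def test_no_treatment_without_mortality_is_a_pure_bmi_line(ps, lt_zero, hm_flat):
    tr = run_strategy("no_treatment", ps, 60, lt_zero, hm_flat)
    df = tr.df
    assert np.allclose(df["alive"], 1.0, atol=1e-15)
    assert np.allclose(df["mean_bmi"], 37 + 0.0127 * df["cycle"], atol=1e-12)
    assert np.all(df["cost"] == 0.0)


def test_hazard_free_treatment_arms_follow_closed_form_lines(
    no_hazard_ps, lt_zero, hm_flat
):
    for strategy, y1, y25 in (
        ("esg", -0.40, 0.0065),
        ("semaglutide", -0.34, 0.0012),
    ):
        tr = run_strategy(strategy, no_hazard_ps, 60, lt_zero, hm_flat)
        t = tr.df["cycle"].to_numpy()
        expected = 37 + y1 * np.minimum(t, 12) + y25 * np.maximum(0, t - 12)
        assert np.allclose(tr.df["mean_bmi"], expected, atol=1e-12)


def test_occupancy_conserved_for_base_and_perturbed_inputs(ps):
    scenarios = [ps] + make_scenarios(ps, 3, seed=2024)
    for scenario in scenarios:
        for strategy in ("no_treatment", "semaglutide", "esg"):
            tr = run_strategy(strategy, scenario, 60)
            occ = (
                tr.df["occ_on_treatment"]
                + tr.df["occ_dropped_out"]
                + tr.df["occ_post_repeat_esg"]
                + tr.df["occ_dead"]
            )
            assert np.allclose(occ, 1.0, atol=1e-12)
            assert np.all(np.diff(tr.df["alive"]) <= 1e-15)


def test_year_one_semaglutide_dropout_matches_annual_rate(ps, lt_zero, hm_flat):
    tr = run_strategy("semaglutide", ps, 12, lt_zero, hm_flat)
    assert tr.cumulative_dropout_at(12) == pytest.approx(0.10, abs=1e-12)


def test_five_year_cumulative_dropout_closed_form(ps, lt_zero, hm_flat):
    tr = run_strategy("semaglutide", ps, 60, lt_zero, hm_flat)
    expected = 1 - 0.90 * 0.9675**4
    assert tr.cumulative_dropout_at(60) == pytest.approx(expected, abs=1e-12)
    # occupancy view agrees: everyone who ever dropped is still in the
    # dropped compartment when mortality is off
    assert tr.df["occ_dropped_out"].iloc[-1] == pytest.approx(expected, abs=1e-12)


def test_esg_procedural_mortality_extremes(ps, lt_zero, hm_flat):
    dead_all = ps.with_values(esg_mortality_30d=1.0)
    tr = run_strategy("esg", dead_all, 3, lt_zero, hm_flat)
    assert tr.df["alive"].iloc[0] == pytest.approx(0.0, abs=1e-12)
    none = ps.with_values(esg_mortality_30d=0.0)
    tr0 = run_strategy("esg", none, 12, lt_zero, hm_flat)
    assert np.allclose(tr0.df["alive"], 1.0, atol=1e-14)


def test_repeat_esg_moves_sixteen_percent_and_reapplies_year_one_slope(
    ps, lt_zero, hm_flat
):
    clean = ps.with_values(esg_mortality_30d=0.0)
    tr = run_strategy("esg", clean, 60, lt_zero, hm_flat)
    df = tr.df
    # before the repeat month nobody is in the post-repeat compartment
    assert np.all(df["occ_post_repeat_esg"][: 23] == 0.0)
    assert df["occ_post_repeat_esg"].iloc[23] == pytest.approx(0.16, abs=1e-12)
    # twelve months later the repeat subcohort has lost 0.40/month
    bmi_24 = 37 - 0.40 * 12 + 0.0065 * 12
    mix_36 = 0.84 * (bmi_24 + 0.0065 * 12) + 0.16 * (bmi_24 - 0.40 * 12)
    assert df["mean_bmi"].iloc[35] == pytest.approx(mix_36, abs=1e-9)


def test_esg_cumulative_cost_flat_outside_procedure_windows(base_results):
    inc = base_results.traces["esg"].df["cost"].to_numpy()
    assert np.all(inc[13:23] == 0.0)   # after index-year accrual, before repeat
    assert np.all(inc[36:] == 0.0)     # after the repeat complication window


def test_discounted_increments_never_exceed_undiscounted(base_results):
    for tr in base_results.traces.values():
        df = tr.df
        assert np.all(df["disc_cost"] <= df["cost"] + 1e-12)
        assert np.all(df["disc_qaly"] <= df["qaly"] + 1e-12)


def test_twelve_month_bmi_matches_trial_slopes(base_results):
    assert base_results.traces["esg"].bmi_at(12) == pytest.approx(32.2, abs=1e-9)
    assert base_results.traces["semaglutide"].bmi_at(12) == pytest.approx(
        37 - 0.34 * 12, abs=1e-9
    )


def test_step_rejects_unknown_strategy(ps, lt_zero, hm_flat):
    state = initial_state(ps, 60)
    with pytest.raises(ValueError):
        step(state, "surgery", ps, lt_zero, hm_flat)


def test_step_no_treatment_advances_age_and_bmi(ps, lt_zero, hm_flat):
    state = initial_state(ps, 60)
    new = step(state, "no_treatment", ps, lt_zero, hm_flat)
    assert new.cycle == 1
    assert new.age_months == state.age_months + 1
    assert new.on_mass == pytest.approx(1.0)
    assert new.on_bmi == pytest.approx(37.0127)
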