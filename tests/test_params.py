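import numpy as np
import pytest

from obesity_cea.params import (
    ConfigError,
    Parameter,
    ParameterError,
    ParameterSet,
    default_parameters,
    fit_distribution,
    load_parameters,
    sample_parameters,
    write_parameters,
)


@pytest.mark.parametrize(
    "name, base",
    [
        ("esg_bmi_slope_y1", -0.40),
        ("sema_bmi_slope_y1", -0.34),
        ("natural_bmi_slope", 0.0127),
        ("dropout_y1", 0.10),
        ("dropout_y2_5", 0.0325),
        ("sema_annual_cost", 13618.0),
        ("esg_cost", 16360.0),
        ("utility_class2_obesity", 0.79),
        ("utility_per_bmi_unit", 0.0056),
        ("repeat_esg_prop", 0.16),
        ("discount_rate", 0.03),
        ("wtp", 100000.0),
        ("baseline_bmi", 37.0),
        ("horizon_months", 60.0),
    ],
)
def test_default_registry_base_values(ps, name, base):
    assert ps.get(name).base == pytest.approx(base)


def test_registry_names_unique_with_units(ps):
    assert len(ps.names) == len(set(ps.names))
    assert all(p.units for p in ps)


def test_parameter_range_validation():
    with pytest.raises(ParameterError):
        Parameter("x", 0.5, 0.6, 0.7, "beta", "p")  # base below low
    with pytest.raises(ParameterError):
        Parameter("x", 1.2, 0.9, 1.4, "beta", "p")  # beta outside [0, 1]
    with pytest.raises(ParameterError):
        Parameter("x", 10.0, -1.0, 20.0, "gamma", "$")  # gamma low < 0


def test_yaml_roundtrip_is_exact(ps, tmp_path):
    path = tmp_path / "params.yaml"
    write_parameters(ps, path)
    assert load_parameters(path) == ps


def test_csv_roundtrip_is_exact(ps, tmp_path):
    path = tmp_path / "params.csv"
    ps.to_csv(path)
    assert ParameterSet.from_csv(path) == ps


def test_empty_config_gives_defaults(tmp_path):
    path = tmp_path / "empty.yaml"
    path.write_text("")
    assert load_parameters(path) == default_parameters()


def test_scalar_override_keeps_everything_else(tmp_path):
    path = tmp_path / "override.yaml"
    path.write_text("sema_annual_cost: 3591\n")
    got = load_parameters(path)
    assert got.value("sema_annual_cost") == 3591
    base = default_parameters()
    for p in got:
        if p.name != "sema_annual_cost":
            assert p == base.get(p.name)


def test_unknown_key_rejected(tmp_path):
    path = tmp_path / "bad.yaml"
    path.write_text("no_such_parameter: 1\n")
    with pytest.raises(ConfigError, match="no_such_parameter"):
        load_parameters(path)


def test_probability_above_one_rejected(tmp_path):
    path = tmp_path / "bad.yaml"
    path.write_text("dropout_y1: 1.4\n")
    with pytest.raises(ConfigError):
        load_parameters(path)


def test_low_above_high_rejected(tmp_path):
    path = tmp_path / "bad.yaml"
    path.write_text("esg_cost: {low: 20000, high: 12000}\n")
    with pytest.raises(ConfigError):
        load_parameters(path)


def test_normal_fit_uses_95pct_interval_width():
    p = Parameter("slope", -0.40, -0.44, -0.36, "normal", "BMI/month")
    spec = fit_distribution(p)
    assert spec.family == "normal"
    assert spec.a == pytest.approx(-0.40)
    assert spec.b == pytest.approx(0.08 / 3.92)  # ~0.0204


def test_fitted_means_equal_base_for_all_ranged(ps):
    for p in ps:
        if p.has_range:
            assert fit_distribution(p).mean() == pytest.approx(p.base, rel=1e-9)


def test_degenerate_range_becomes_point_mass():
    p = Parameter("u", 0.79, 0.79, 0.79, "beta", "utility")
    spec = fit_distribution(p)
    assert spec.family == "fixed"
    rng = np.random.default_rng(0)
    assert spec.sample(rng) == 0.79


def test_beta_moment_infeasibility_raises():
    p = Parameter("p", 0.001, 0.0, 1.0, "beta", "probability")
    with pytest.raises(ParameterError, match="infeasible"):
        fit_distribution(p)


def test_sampling_is_deterministic_under_seed(ps):
    a = sample_parameters(ps, np.random.default_rng(42))
    b = sample_parameters(ps, np.random.default_rng(42))
    assert a == b
    assert a != sample_parameters(ps, np.random.default_rng(43))


def test_fixed_entries_returned_unchanged(ps):
    drawn = sample_parameters(ps, np.random.default_rng(5))
    for p in ps:
        if p.is_fixed:
            assert drawn.get(p.name) == p


def test_sampled_values_stay_in_physical_domain(ps):
    rng = np.random.default_rng(7)
    for _ in range(200):
        drawn = sample_parameters(ps, rng)
        for key in ("dropout_y1", "dropout_y2_5", "esg_mortality_30d",
                    "esg_minor_rate", "esg_major_rate", "repeat_esg_prop"):
            assert 0.0 <= drawn.value(key) <= 1.0
        for key in ("esg_cost", "sema_annual_cost", "major_comp_cost",
                    "minor_comp_cost"):
            assert drawn.value(key) >= 0.0
        for key in ("utility_dec_initial", "utility_dec_minor",
                    "utility_dec_major"):
            assert -1.0 <= drawn.value(key) <= 0.0


def test_gamma_sample_mean_matches_base(ps):
    spec = fit_distribution(ps.get("esg_cost"))
    draws = spec.sample(np.random.default_rng(3), 10_000)
    assert np.mean(draws) == pytest.approx(16360, rel=0.02)
    # and within 3 standard errors at larger n
    big = spec.sample(np.random.default_rng(4), 100_000)
    se = np.std(big) / np.sqrt(big.size)
    assert abs(np.mean(big) - 16360) < 3 * se
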