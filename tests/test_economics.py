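import numpy as np
import pytest

from obesity_cea import economics
from obesity_cea.cohort import CohortTrace, run_strategy
from obesity_cea.economics import (
    EconResult,
    compare,
    cycle_utility,
    discount_factor,
    icer,
    nmb,
)


def test_discount_factor_first_cycle_and_one_year():
    assert discount_factor(1, 0.03) == 1.0
    assert discount_factor(13, 0.03) == pytest.approx(1 / 1.03, rel=1e-12)
    assert all(discount_factor(c, 0.0) == 1.0 for c in (1, 7, 60))
    with pytest.raises(ValueError):
        discount_factor(1, -0.1)


def test_cycle_utility_linear_in_bmi():
    assert cycle_utility(37, 37, 0.79, 0.0056) == pytest.approx(0.79)
    assert cycle_utility(32, 37, 0.79, 0.0056) == pytest.approx(0.818)
    # symmetric decrement above baseline
    assert cycle_utility(42, 37, 0.79, 0.0056) == pytest.approx(0.762)


def test_cycle_utility_procedure_week_decrement():
    base = cycle_utility(37, 37, 0.79, 0.0056)
    with_event = cycle_utility(
        37, 37, 0.79, 0.0056, decrement_events=[(-0.22, 1.0, 1.0)]
    )
    assert base - with_event == pytest.approx(0.22 * 7 / (365.25 / 12), rel=1e-12)
    assert base - with_event == pytest.approx(0.0506, abs=2e-4)


def test_cycle_utility_clamped_to_unit_interval():
    assert cycle_utility(-60.0, 37, 0.79, 0.0056) == 1.0
    assert cycle_utility(200.0, 37, 0.79, 0.0056) == 0.0


def test_nmb_identity_holds_exactly(base_results):
    for wtp in (0.0, 50_000.0, 100_000.0, 250_000.0):
        econ = base_results.econ(wtp=wtp)
        for s in econ.totals.index:
            c = econ.totals.loc[s, "cost"]
            q = econ.totals.loc[s, "qaly"]
            assert econ.totals.loc[s, "nmb"] == q * wtp - c


def test_zero_discount_zero_mortality_closed_form_qaly(ps, lt_zero, hm_flat):
    """No-treatment limit: QALYs equal the exact arithmetic sum.

    State rewards start at cycle 2 on end-of-cycle BMI, so the total is
    sum_{t=2..60} (0.79 - 0.0056 * 0.0127 * t) / 12.
    """
    ps0 = ps.with_values(discount_rate=0.0)
    tr = run_strategy("no_treatment", ps0, 60, lt_zero, hm_flat)
    t = np.arange(2, 61)
    expected = np.sum(0.79 - 0.0056 * 0.0127 * t) / 12
    assert tr.total_disc_qaly == pytest.approx(expected, abs=1e-12)
    assert tr.qaly_at(60) == pytest.approx(expected, abs=1e-12)


def test_dominance_labels_and_icer(base_results):
    econ = base_results.econ(horizon=60)
    row = econ.pairwise.set_index(["strategy", "comparator"]).loc[
        ("semaglutide", "esg")
    ]
    # at 5 years semaglutide costs more and yields fewer QALYs
    assert row["label"] == "dominated"
    assert row["icer"] < 0
    # the mirror comparison is then cost saving ("dominant")
    assert economics._dominance_label(-row["inc_cost"], -row["inc_qaly"]) == "dominant"


def test_equal_traces_yield_undefined_icer_and_equal_nmb(base_results):
    tr = base_results.traces["esg"]
    econ = compare({"a": tr, "b": tr}, wtp=100_000.0)
    row = econ.pairwise.iloc[0]
    assert row["label"] == "undefined"
    assert np.isinf(row["icer"])
    assert row["inc_nmb"] == 0.0


def test_raising_wtp_never_demotes_the_higher_qaly_strategy(base_results):
    econ0 = base_results.econ(wtp=0.0)
    q = econ0.totals["qaly"]
    richer = q.idxmax()
    ranks = []
    for wtp in (0, 25_000, 50_000, 100_000, 200_000, 500_000):
        econ = base_results.econ(wtp=wtp)
        order = econ.totals["nmb"].rank(ascending=False)
        ranks.append(order[richer])
    assert all(b <= a for a, b in zip(ranks, ranks[1:]))


def _toy_trace(name, cost, qaly):
    n = len(cost)
    arrays = {
        "cycle": np.arange(1, n + 1, dtype=float),
        "cost": np.asarray(cost, dtype=float),
        "qaly": np.asarray(qaly, dtype=float),
        "disc_cost": np.asarray(cost, dtype=float),
        "disc_qaly": np.asarray(qaly, dtype=float),
    }
    return CohortTrace(name, arrays)


def test_icer_invariant_to_shared_constant_cost():
    a = _toy_trace("a", [100, 50, 50], [0.1, 0.1, 0.1])
    b = _toy_trace("b", [10, 10, 10], [0.08, 0.09, 0.1])
    base = compare({"a": a, "b": b}, wtp=1e5).pairwise.iloc[0]["icer"]
    shift = 77.0
    a2 = _toy_trace("a", [100 + shift, 50 + shift, 50 + shift], [0.1, 0.1, 0.1])
    b2 = _toy_trace("b", [10 + shift, 10 + shift, 10 + shift], [0.08, 0.09, 0.1])
    shifted = compare({"a": a2, "b": b2}, wtp=1e5).pairwise.iloc[0]["icer"]
    assert shifted == pytest.approx(base, rel=1e-12)


def test_icer_undefined_when_qalys_tie():
    assert icer(100.0, 0.0) == np.inf
    assert nmb(3.66, 19685.0, 100_000.0) == pytest.approx(346_315.0)


def test_compare_requires_common_horizon(base_results):
    short = run_strategy("no_treatment", base_results.model.params, 12)
    with pytest.raises(ValueError):
        compare(
            {"a": base_results.traces["esg"], "b": short},
            wtp=1e5,
            horizon_months=60,
        )
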