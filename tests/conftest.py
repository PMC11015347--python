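import pytest

from obesity_cea import MarkovCohortCEA, run_strategy, synth
from obesity_cea.mortality import BmiHazardModel, LifeTable
from obesity_cea.params import default_parameters


@pytest.fixture(scope="session")
def ps():
    return default_parameters()


@pytest.fixture(scope="session")
def lt_zero():
    return LifeTable.zero()


@pytest.fixture(scope="session")
def hm_flat():
    return BmiHazardModel.flat()


@pytest.fixture(scope="session")
def base_results():
    """Base-case fit of all three strategies over 60 months."""
    return MarkovCohortCEA().fit(60)


@pytest.fixture(scope="session")
def no_hazard_ps(ps):
    """All stochastic exits (dropout, complications, mortality) switched off."""
    return ps.with_values(
        dropout_y1=0.0,
        dropout_y2_5=0.0,
        esg_mortality_30d=0.0,
        esg_minor_rate=0.0,
        esg_major_rate=0.0,
        repeat_esg_prop=0.0,
    )


@pytest.fixture(scope="session")
def oracle_comparison(ps):
    """Cohort trace vs microsimulation (n = 20 000) for every strategy."""
    out = {}
    for s in ("no_treatment", "semaglutide", "esg"):
        tr = run_strategy(s, ps, 60)
        ms = synth.microsim_oracle(s, ps, 60, n_individuals=20_000, seed=11)
        out[s] = (tr, ms)
    return out
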