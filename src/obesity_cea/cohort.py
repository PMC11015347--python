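"""Monthly Markov cohort engine for the three obesity strategies.

The cohort starts at age 45 with BMI 37, entirely in the on-treatment
compartment of its strategy (the no-treatment cohort sits in a single
natural-history compartment).  Each monthly cycle applies, in order:

1. background mortality (age/sex/BMI-adjusted), plus the one-time 30-day
   procedural mortality in ESG procedure cycles;
2. semaglutide dropout at the monthly hazard implied by the year-specific
   annual rate (10% in year 1, 3.25% in years 2-5); dropouts stop accruing
   drug cost, hold their BMI for 3 months, then regain at +0.138/month;
3. the repeat-ESG flow (16% of the surviving ESG cohort at the repeat
   month, default cycle 24), which re-applies the year-1 ESG slope for the
   following 12 cycles at full procedure cost;
4. the BMI update for every compartment.

State rewards (utility, drug cost, complication expected flows) accrue at
end-of-cycle membership and BMI from cycle 2 onward — the initial-state
reward is zero, as in common Markov cycle-tree implementations — while
one-time procedure costs and the procedure disutility attach to their
transition cycle (cycle 1, and the repeat cycle).  The dead accrue nothing
in their death cycle.  ESG complication rates (annual 10% minor / 2% major)
act as expected-value flows during the 12 cycles after each procedure,
generating costs and 2-week disutility increments without a dedicated
compartment.  There is no half-cycle correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import economics
from .mortality import BmiHazardModel, LifeTable, load_default_life_table
from .params import ParameterSet, default_parameters

__all__ = [
    "STRATEGIES",
    "COMPARTMENTS",
    "annual_to_monthly_prob",
    "bmi_slope",
    "CohortState",
    "CohortTrace",
    "initial_state",
    "step",
    "run_strategy",
    "run_all",
]

STRATEGIES = ("no_treatment", "semaglutide", "esg")
COMPARTMENTS = ("on_treatment", "dropped_out", "post_repeat_esg", "dead")


def annual_to_monthly_prob(p_annual: float) -> float:
    """Constant-hazard conversion of an annual probability to monthly."""
    if not 0.0 <= p_annual <= 1.0:
        raise ValueError(f"annual probability must lie in [0, 1], got {p_annual}")
    return 1.0 - (1.0 - p_annual) ** (1.0 / 12.0)


def bmi_slope(
    strategy: str,
    compartment: str,
    cycle: int,
    ps: ParameterSet,
    *,
    months_since_dropout: int | None = None,
    months_since_repeat: int | None = None,
) -> float:
    """BMI change (units/month) for one compartment at one cycle.

    Treatment compartments lose weight on the year-1 trial slope for 12
    months after their procedure/initiation and then follow the years-2-5
    maintenance slope.  Dropouts hold their weight for the plateau period
    (3 months) and then regain; the untreated cohort drifts upward on the
    natural-history slope.
    """
    if cycle < 1:
        raise ValueError("cycle index starts at 1")
    if strategy == "no_treatment":
        return ps.value("natural_bmi_slope")
    if compartment == "on_treatment":
        if strategy == "esg":
            return (
                ps.value("esg_bmi_slope_y1")
                if cycle <= 12
                else ps.value("esg_bmi_slope_y2_5")
            )
        if strategy == "semaglutide":
            return (
                ps.value("sema_bmi_slope_y1")
                if cycle <= 12
                else ps.value("sema_bmi_slope_y2_5")
            )
        raise ValueError(f"unknown strategy {strategy!r}")
    if compartment == "post_repeat_esg":
        if strategy != "esg":
            raise ValueError("post_repeat_esg exists only for the ESG strategy")
        if months_since_repeat is None:
            raise ValueError("post_repeat_esg slope needs months_since_repeat")
        if months_since_repeat < 1:
            # the repeat cycle itself: still on the pre-repeat trajectory
            return ps.value("esg_bmi_slope_y2_5")
        return (
            ps.value("esg_bmi_slope_y1")
            if months_since_repeat <= 12
            else ps.value("esg_bmi_slope_y2_5")
        )
    if compartment == "dropped_out":
        if months_since_dropout is None:
            raise ValueError("dropped_out slope needs months_since_dropout")
        if months_since_dropout <= ps.value("regain_plateau_months"):
            return 0.0
        return ps.value("dropout_bmi_slope")
    raise ValueError(f"unknown compartment {compartment!r}")


@dataclass
class CohortState:
    """Cohort occupancy and per-compartment mean BMI after ``cycle`` cycles."""

    cycle: int
    age_months: int
    on_mass: float
    on_bmi: float
    pr_mass: float              # post-repeat-ESG compartment
    pr_bmi: float
    dead: float
    drop_mass: np.ndarray       # indexed by dropout cycle
    drop_bmi: np.ndarray
    natural_bmi: float          # contemporaneous natural-history trajectory
    flows: dict = field(default_factory=dict, compare=False)

    @property
    def alive(self) -> float:
        return self.on_mass + self.pr_mass + float(self.drop_mass.sum())

    @property
    def occupancy(self) -> dict[str, float]:
        return {
            "on_treatment": self.on_mass,
            "dropped_out": float(self.drop_mass.sum()),
            "post_repeat_esg": self.pr_mass,
            "dead": self.dead,
        }

    def mean_bmi(self) -> float:
        """Occupancy-weighted mean BMI over the alive cohort."""
        alive = self.alive
        if alive <= 0:
            return float("nan")
        total = (
            self.on_mass * self.on_bmi
            + self.pr_mass * self.pr_bmi
            + float(np.dot(self.drop_mass, self.drop_bmi))
        )
        return total / alive

    def treated_bmi(self) -> float:
        """Mean BMI among patients remaining on the assigned strategy."""
        mass = self.on_mass + self.pr_mass
        if mass <= 0:
            return float("nan")
        return (self.on_mass * self.on_bmi + self.pr_mass * self.pr_bmi) / mass


def initial_state(ps: ParameterSet, horizon_months: int) -> CohortState:
    bmi0 = ps.value("baseline_bmi")
    return CohortState(
        cycle=0,
        age_months=int(round(ps.value("baseline_age") * 12)),
        on_mass=1.0,
        on_bmi=bmi0,
        pr_mass=0.0,
        pr_bmi=bmi0,
        dead=0.0,
        drop_mass=np.zeros(horizon_months + 2),
        drop_bmi=np.full(horizon_months + 2, bmi0),
        natural_bmi=bmi0,
    )


def step(
    state: CohortState,
    strategy: str,
    ps: ParameterSet,
    lt: LifeTable,
    hm: BmiHazardModel,
) -> CohortState:
    """Advance the cohort by one monthly cycle.

    Returns a new state; ``state.flows`` on the result records the cycle's
    dropout flow, repeat-ESG flow, and deaths (used for reward accrual).
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    t = state.cycle + 1
    ff = ps.value("female_fraction")
    age = state.age_months // 12
    q_annual = lt.qx_mixed(age, ff)

    on_mass, on_bmi = state.on_mass, state.on_bmi
    pr_mass, pr_bmi = state.pr_mass, state.pr_bmi
    drop_mass = state.drop_mass.copy()
    drop_bmi = state.drop_bmi.copy()
    dead = state.dead
    flows: dict[str, float] = {}

    # (1) mortality --------------------------------------------------------
    def p_month(bmi: float) -> float:
        return 1.0 - (1.0 - min(1.0, q_annual * hm.hr(bmi))) ** (1.0 / 12.0)

    d_on = on_mass * p_month(on_bmi)
    d_pr = pr_mass * p_month(pr_bmi)
    q_adj = np.minimum(1.0, q_annual * hm.hr_array(drop_bmi))
    p_drop_mort = 1.0 - (1.0 - q_adj) ** (1.0 / 12.0)
    d_drop = drop_mass * p_drop_mort
    on_mass -= d_on
    pr_mass -= d_pr
    drop_mass = drop_mass - d_drop
    deaths = d_on + d_pr + float(d_drop.sum())

    procedural_deaths = 0.0
    if strategy == "esg" and t == 1:
        p30 = ps.value("esg_mortality_30d")
        procedural_deaths = on_mass * p30
        on_mass -= procedural_deaths
    dead += deaths + procedural_deaths

    # (2) semaglutide dropout ---------------------------------------------
    new_dropout = 0.0
    if strategy == "semaglutide":
        annual = ps.value("dropout_y1") if t <= 12 else ps.value("dropout_y2_5")
        h = annual_to_monthly_prob(annual)
        new_dropout = on_mass * h
        on_mass -= new_dropout
        drop_mass[t] += new_dropout
        drop_bmi[t] = on_bmi

    # (3) repeat ESG -------------------------------------------------------
    repeat_flow = 0.0
    repeat_month = int(ps.value("repeat_esg_month"))
    if strategy == "esg" and t == repeat_month:
        flow = on_mass * ps.value("repeat_esg_prop")
        extra = flow * ps.value("esg_mortality_30d")
        repeat_flow = flow - extra
        on_mass -= flow
        dead += extra
        procedural_deaths += extra
        pr_mass, pr_bmi = repeat_flow, on_bmi

    # (4) BMI update -------------------------------------------------------
    natural_bmi = state.natural_bmi + ps.value("natural_bmi_slope")
    if strategy == "no_treatment":
        on_bmi = on_bmi + ps.value("natural_bmi_slope")
    else:
        on_bmi = on_bmi + bmi_slope(strategy, "on_treatment", t, ps)
    if strategy == "esg" and pr_mass > 0:
        pr_bmi = pr_bmi + bmi_slope(
            strategy, "post_repeat_esg", t, ps,
            months_since_repeat=t - repeat_month,
        )
    if strategy == "semaglutide":
        cycles = np.arange(drop_mass.size)
        ms = t - cycles
        plateau = ps.value("regain_plateau_months")
        regain = (ms > plateau) & (drop_mass > 0)
        drop_bmi = drop_bmi + np.where(regain, ps.value("dropout_bmi_slope"), 0.0)
        if ps.value("dropout_regain_cap"):
            drop_bmi = np.minimum(drop_bmi, natural_bmi)

    flows.update(
        deaths=deaths,
        procedural_deaths=procedural_deaths,
        new_dropout=new_dropout,
        repeat_flow=repeat_flow,
    )
    return CohortState(
        cycle=t,
        age_months=state.age_months + 1,
        on_mass=on_mass,
        on_bmi=on_bmi,
        pr_mass=pr_mass,
        pr_bmi=pr_bmi,
        dead=dead,
        drop_mass=drop_mass,
        drop_bmi=drop_bmi,
        natural_bmi=natural_bmi,
        flows=flows,
    )


class CohortTrace:
    """Per-cycle ledger of occupancy, BMI, and reward increments."""

    def __init__(self, strategy: str, arrays: dict[str, np.ndarray]):
        self.strategy = strategy
        self._arrays = arrays
        self.horizon_months = int(arrays["cycle"][-1])
        self._df: pd.DataFrame | None = None

    @property
    def df(self) -> pd.DataFrame:
        if self._df is None:
            self._df = pd.DataFrame(self._arrays)
        return self._df

    def _cum_at(self, key: str, horizon: int) -> float:
        if not 1 <= horizon <= self.horizon_months:
            raise ValueError(f"horizon {horizon} outside trace (1..{self.horizon_months})")
        return float(self._arrays[key][:horizon].sum())

    def disc_cost_at(self, horizon: int) -> float:
        return self._cum_at("disc_cost", horizon)

    def disc_qaly_at(self, horizon: int) -> float:
        return self._cum_at("disc_qaly", horizon)

    def cost_at(self, horizon: int) -> float:
        return self._cum_at("cost", horizon)

    def qaly_at(self, horizon: int) -> float:
        return self._cum_at("qaly", horizon)

    def cumulative_dropout_at(self, horizon: int | None = None) -> float:
        """Fraction of the initial cohort that ever dropped out of treatment."""
        return self._cum_at("new_dropout", horizon or self.horizon_months)

    def bmi_at(self, horizon: int, among: str = "treated") -> float:
        """Mean BMI at a cycle: 'treated' (on assigned strategy) or 'alive'."""
        key = "treated_bmi" if among == "treated" else "mean_bmi"
        return float(self._arrays[key][horizon - 1])

    @property
    def total_disc_cost(self) -> float:
        return self.disc_cost_at(self.horizon_months)

    @property
    def total_disc_qaly(self) -> float:
        return self.disc_qaly_at(self.horizon_months)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def run_strategy(
    strategy: str,
    ps: ParameterSet | None = None,
    horizon_months: int | None = None,
    lt: LifeTable | None = None,
    hm: BmiHazardModel | None = None,
) -> CohortTrace:
    """Run one strategy for ``horizon_months`` cycles and return its trace."""
    ps = ps if ps is not None else default_parameters()
    lt = lt if lt is not None else load_default_life_table()
    hm = hm if hm is not None else BmiHazardModel()
    horizon = int(horizon_months or ps.value("horizon_months"))
    if horizon < 1:
        raise ValueError("horizon must be >= 1 month")

    rate = ps.value("discount_rate")
    baseline_bmi = ps.value("baseline_bmi")
    u_base = ps.value("utility_class2_obesity")
    u_slope = ps.value("utility_per_bmi_unit")
    dec_initial = abs(ps.value("utility_dec_initial"))
    dec_minor = abs(ps.value("utility_dec_minor"))
    dec_major = abs(ps.value("utility_dec_major"))
    p_minor = annual_to_monthly_prob(ps.value("esg_minor_rate"))
    p_major = annual_to_monthly_prob(ps.value("esg_major_rate"))
    minor_cost = ps.value("minor_comp_cost")
    major_cost = ps.value("major_comp_cost")
    esg_cost = ps.value("esg_cost")
    sema_monthly = ps.value("sema_annual_cost") / 12.0
    repeat_month = int(ps.value("repeat_esg_month"))
    wf = economics.WEEK_FRACTION

    def u_of(bmi) -> float:
        return min(1.0, max(0.0, u_base + u_slope * (baseline_bmi - bmi)))

    cols = (
        "cycle", "age_years", "alive", "mean_bmi", "treated_bmi",
        "occ_on_treatment", "occ_dropped_out", "occ_post_repeat_esg", "occ_dead",
        "new_dropout", "cost", "qaly", "disc_cost", "disc_qaly",
    )
    out = {c: np.zeros(horizon) for c in cols}

    state = initial_state(ps, horizon)
    for t in range(1, horizon + 1):
        state = step(state, strategy, ps, lt, hm)
        disc = economics.discount_factor(t, rate)

        # -- rewards at end-of-cycle membership and BMI; state rewards
        #    start at cycle 2 (initial-state reward zero), transition
        #    rewards (procedure cost + disutility) in their own cycle ------
        cost = 0.0
        qaly = 0.0
        if t >= 2:
            qaly += (
                state.on_mass * u_of(state.on_bmi)
                + state.pr_mass * u_of(state.pr_bmi)
            )
        if strategy == "semaglutide":
            if t >= 2:
                live = state.drop_mass > 0
                if live.any():
                    u_drop = np.clip(
                        u_base + u_slope * (baseline_bmi - state.drop_bmi[live]),
                        0.0, 1.0,
                    )
                    qaly += float(np.dot(state.drop_mass[live], u_drop))
                cost += state.on_mass * sema_monthly
        elif strategy == "esg":
            if t == 1:
                cost += state.on_mass * esg_cost
                qaly -= state.on_mass * dec_initial * wf
            if t == repeat_month:
                cost += state.pr_mass * esg_cost
                qaly -= state.pr_mass * dec_initial * wf
            exposure = 0.0
            if 2 <= t <= 13:
                exposure += state.on_mass
            if repeat_month < t <= repeat_month + 12:
                exposure += state.pr_mass
            if exposure > 0:
                cost += exposure * (p_minor * minor_cost + p_major * major_cost)
                qaly -= exposure * 2.0 * wf * (
                    p_minor * dec_minor + p_major * dec_major
                )
        qaly /= 12.0

        i = t - 1
        out["cycle"][i] = t
        out["age_years"][i] = state.age_months / 12.0
        out["alive"][i] = state.alive
        out["mean_bmi"][i] = state.mean_bmi()
        out["treated_bmi"][i] = (
            state.treated_bmi() if strategy != "no_treatment" else state.mean_bmi()
        )
        occ = state.occupancy
        out["occ_on_treatment"][i] = occ["on_treatment"]
        out["occ_dropped_out"][i] = occ["dropped_out"]
        out["occ_post_repeat_esg"][i] = occ["post_repeat_esg"]
        out["occ_dead"][i] = occ["dead"]
        out["new_dropout"][i] = state.flows["new_dropout"]
        out["cost"][i] = cost
        out["qaly"][i] = qaly
        out["disc_cost"][i] = cost * disc
        out["disc_qaly"][i] = qaly * disc

    return CohortTrace(strategy, out)


def run_all(
    ps: ParameterSet | None = None,
    horizon_months: int | None = None,
    lt: LifeTable | None = None,
    hm: BmiHazardModel | None = None,
    strategies: tuple[str, ...] = STRATEGIES,
) -> dict[str, CohortTrace]:
    """Run several strategies on shared inputs."""
    ps = ps if ps is not None else default_parameters()
    lt = lt if lt is not None else load_default_life_table()
    hm = hm if hm is not None else BmiHazardModel()
    return {s: run_strategy(s, ps, horizon_months, lt, hm) for s in strategies}
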