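"""Synthetic inputs and the individual-level validation oracle.

The decision model needs three inputs that have to be constructed rather
than loaded: a background life table (the bundled one is synthetic,
generated from a Gompertz-Makeham law calibrated to round US-2020
magnitudes — it is a stand-in, not the actual national table), the
BMI-mortality hazard ratios (see :class:`~obesity_cea.mortality.BmiHazardModel`),
and perturbed parameter scenarios for tests.

The microsimulation oracle replays the cohort model at the individual
level with Bernoulli transitions drawn from the same monthly probabilities
and BMI slopes, providing an independent expectation check on the
deterministic engine.  Common random numbers are reused across strategies
to reduce comparison variance.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import economics
from .cohort import annual_to_monthly_prob
from .mortality import BmiHazardModel, LifeTable, load_default_life_table
from .params import ParameterSet, default_parameters, sample_parameters

__all__ = [
    "GompertzMakeham",
    "DEFAULT_GM_FEMALE",
    "DEFAULT_GM_MALE",
    "make_life_table",
    "life_table_checksum",
    "microsim_oracle",
    "MicrosimResult",
    "make_scenarios",
]


@dataclass(frozen=True)
class GompertzMakeham:
    """Hazard mu(x) = makeham + baseline * exp(slope * x), x in years."""

    baseline: float
    slope: float
    makeham: float = 0.0

    def __post_init__(self) -> None:
        if self.baseline <= 0 or self.makeham < 0 or self.slope < 0:
            raise ValueError("hazard parameters must be positive")

    def annual_q(self, age: np.ndarray | int) -> np.ndarray | float:
        """Annual death probability from the integrated hazard over [x, x+1)."""
        x = np.asarray(age, dtype=float)
        if self.slope == 0.0:
            integral = self.makeham + self.baseline
        else:
            integral = self.makeham + (self.baseline / self.slope) * (
                np.exp(self.slope * (x + 1.0)) - np.exp(self.slope * x)
            )
        return 1.0 - np.exp(-integral)


# calibrated to give q45 ~ 0.003 (female) / 0.005 (male), doubling every
# ~8 years -- round US-2020 magnitudes, not the actual national table
DEFAULT_GM_FEMALE = GompertzMakeham(baseline=5.673e-5, slope=0.085, makeham=4e-4)
DEFAULT_GM_MALE = GompertzMakeham(baseline=1.004e-4, slope=0.085, makeham=6e-4)


def make_life_table(
    female: GompertzMakeham = DEFAULT_GM_FEMALE,
    male: GompertzMakeham = DEFAULT_GM_MALE,
    ages: range = range(20, 111),
) -> LifeTable:
    """Deterministic synthetic life table for ages 20-110.

    The ``combined`` rows average the female and male hazards 50/50; the
    cohort engine blends female/male qx itself at its configured sex mix.
    """
    age = np.array(list(ages))
    qf = np.minimum(1.0, female.annual_q(age))
    qm = np.minimum(1.0, male.annual_q(age))
    combined_hazard = 0.5 * (
        -np.log1p(-np.minimum(qf, 1 - 1e-15))
        - np.log1p(-np.minimum(qm, 1 - 1e-15))
    )
    qc = 1.0 - np.exp(-combined_hazard)
    rows = []
    for sex, q in (("female", qf), ("male", qm), ("combined", qc)):
        rows.append(
            pd.DataFrame({"age": age, "sex": sex, "qx": np.round(q, 8)})
        )
    return LifeTable(pd.concat(rows, ignore_index=True))


def life_table_checksum(lt: LifeTable) -> str:
    """SHA-256 of the canonical CSV serialisation (versioning fixture)."""
    csv = lt.df.to_csv(index=False).encode()
    return hashlib.sha256(csv).hexdigest()


@dataclass
class MicrosimResult:
    """Aggregated microsimulation trace with Monte-Carlo standard errors."""

    strategy: str
    n: int
    seed: int | None
    df: pd.DataFrame                  # per-cycle means
    total_disc_cost: float
    total_disc_qaly: float
    se_disc_cost: float
    se_disc_qaly: float

    def bmi_at(self, horizon: int) -> float:
        return float(self.df["mean_bmi"].iloc[horizon - 1])

    def se_bmi_at(self, horizon: int) -> float:
        return float(self.df["se_bmi"].iloc[horizon - 1])

    def disc_cost_at(self, horizon: int) -> float:
        return float(self.df["disc_cost"].iloc[:horizon].sum())

    def disc_qaly_at(self, horizon: int) -> float:
        return float(self.df["disc_qaly"].iloc[:horizon].sum())


def draw_uniform_streams(
    n: int, horizon: int, seed: int
) -> dict[str, np.ndarray]:
    """Pre-drawn uniforms shared across strategies (common random numbers)."""
    rng = np.random.default_rng(seed)
    return {
        "death": rng.random((n, horizon)),
        "dropout": rng.random((n, horizon)),
        "repeat": rng.random(n),
        "proc": rng.random((n, 2)),
        "minor": rng.random((n, horizon)),
        "major": rng.random((n, horizon)),
    }


def microsim_oracle(
    strategy: str,
    ps: ParameterSet | None = None,
    horizon_months: int | None = None,
    n_individuals: int = 20_000,
    seed: int | None = 1,
    lt: LifeTable | None = None,
    hm: BmiHazardModel | None = None,
    uniforms: dict[str, np.ndarray] | None = None,
) -> MicrosimResult:
    """Simulate ``n_individuals`` independent patients on one strategy.

    Transitions use Bernoulli draws at the same monthly probabilities and
    BMI slopes as the cohort engine; the aggregated mean trace therefore
    estimates the cohort expectation with standard error O(n^-1/2).
    """
    ps = ps if ps is not None else default_parameters()
    lt = lt if lt is not None else load_default_life_table()
    hm = hm if hm is not None else BmiHazardModel()
    horizon = int(horizon_months or ps.value("horizon_months"))
    n = int(n_individuals)
    if n < 1:
        raise ValueError("need n_individuals >= 1")
    if uniforms is None:
        if seed is None:
            raise ValueError("need a seed when uniforms are not supplied")
        uniforms = draw_uniform_streams(n, horizon, seed)

    ff = ps.value("female_fraction")
    baseline_bmi = ps.value("baseline_bmi")
    u_base = ps.value("utility_class2_obesity")
    u_slope = ps.value("utility_per_bmi_unit")
    dec_initial = abs(ps.value("utility_dec_initial"))
    dec_minor = abs(ps.value("utility_dec_minor"))
    dec_major = abs(ps.value("utility_dec_major"))
    p_minor = annual_to_monthly_prob(ps.value("esg_minor_rate"))
    p_major = annual_to_monthly_prob(ps.value("esg_major_rate"))
    p30 = ps.value("esg_mortality_30d")
    plateau = ps.value("regain_plateau_months")
    repeat_month = int(ps.value("repeat_esg_month"))
    cap = bool(ps.value("dropout_regain_cap"))
    rate = ps.value("discount_rate")
    wf = economics.WEEK_FRACTION
    sema_monthly = ps.value("sema_annual_cost") / 12.0
    esg_cost = ps.value("esg_cost")
    minor_cost = ps.value("minor_comp_cost")
    major_cost = ps.value("major_comp_cost")
    age0 = int(round(ps.value("baseline_age") * 12))

    alive = np.ones(n, dtype=bool)
    # compartment codes: 0 on-treatment/natural, 1 dropped out, 2 post-repeat
    comp = np.zeros(n, dtype=np.int8)
    bmi = np.full(n, baseline_bmi)
    t_drop = np.full(n, -1, dtype=np.int32)
    t_repeat = np.full(n, -1, dtype=np.int32)
    disc_cost = np.zeros(n)
    disc_qaly = np.zeros(n)

    per_cycle = {
        "cycle": np.zeros(horizon),
        "alive": np.zeros(horizon),
        "mean_bmi": np.zeros(horizon),
        "se_bmi": np.zeros(horizon),
        "cost": np.zeros(horizon),
        "qaly": np.zeros(horizon),
        "disc_cost": np.zeros(horizon),
        "disc_qaly": np.zeros(horizon),
    }

    natural_slope = ps.value("natural_bmi_slope")
    natural_bmi = baseline_bmi

    for t in range(1, horizon + 1):
        age = (age0 + t - 1) // 12
        q_annual = lt.qx_mixed(age, ff)
        disc = economics.discount_factor(t, rate)
        cost_t = np.zeros(n)
        qaly_t = np.zeros(n)

        # (1) mortality
        q_adj = np.minimum(1.0, q_annual * hm.hr_array(bmi))
        p_death = 1.0 - (1.0 - q_adj) ** (1.0 / 12.0)
        dying = alive & (uniforms["death"][:, t - 1] < p_death)
        alive &= ~dying
        if strategy == "esg" and t == 1:
            proc_dying = alive & (uniforms["proc"][:, 0] < p30)
            alive &= ~proc_dying

        # (2) dropout
        if strategy == "semaglutide":
            annual = ps.value("dropout_y1") if t <= 12 else ps.value("dropout_y2_5")
            h = annual_to_monthly_prob(annual)
            dropping = alive & (comp == 0) & (uniforms["dropout"][:, t - 1] < h)
            comp[dropping] = 1
            t_drop[dropping] = t

        # (3) repeat ESG
        if strategy == "esg" and t == repeat_month:
            selected = alive & (comp == 0) & (
                uniforms["repeat"] < ps.value("repeat_esg_prop")
            )
            proc_dying = selected & (uniforms["proc"][:, 1] < p30)
            alive &= ~proc_dying
            moved = selected & alive
            comp[moved] = 2
            t_repeat[moved] = t
            cost_t[moved] += esg_cost
            qaly_t[moved] -= dec_initial * wf

        # (4) BMI update
        natural_bmi += natural_slope
        if strategy == "no_treatment":
            bmi[alive] += natural_slope
        else:
            on = alive & (comp == 0)
            if strategy == "esg":
                slope_on = ps.value("esg_bmi_slope_y1") if t <= 12 else ps.value("esg_bmi_slope_y2_5")
            else:
                slope_on = ps.value("sema_bmi_slope_y1") if t <= 12 else ps.value("sema_bmi_slope_y2_5")
            bmi[on] += slope_on
            pr = alive & (comp == 2)
            if pr.any():
                ms = t - t_repeat[pr]
                slope_pr = np.where(
                    (ms >= 1) & (ms <= 12),
                    ps.value("esg_bmi_slope_y1"),
                    ps.value("esg_bmi_slope_y2_5"),
                )
                bmi[pr] += slope_pr
            dropped = alive & (comp == 1)
            if dropped.any():
                ms = t - t_drop[dropped]
                add = np.where(ms > plateau, ps.value("dropout_bmi_slope"), 0.0)
                newb = bmi[dropped] + add
                bmi[dropped] = np.minimum(newb, natural_bmi) if cap else newb

        # rewards: state rewards from cycle 2 (initial-state reward zero),
        # procedure cost + disutility in their transition cycle
        if t >= 2:
            u = np.clip(u_base + u_slope * (baseline_bmi - bmi), 0.0, 1.0)
            qaly_t[alive] += u[alive]
        if strategy == "semaglutide":
            if t >= 2:
                cost_t[alive & (comp == 0)] += sema_monthly
        elif strategy == "esg":
            if t == 1:
                idx = alive & (comp == 0)
                cost_t[idx] += esg_cost
                qaly_t[idx] -= dec_initial * wf
            exposed = np.zeros(n, dtype=bool)
            if 2 <= t <= 13:
                exposed |= alive & (comp == 0)
            if repeat_month < t <= repeat_month + 12:
                exposed |= alive & (comp == 2)
            if exposed.any():
                minor = exposed & (uniforms["minor"][:, t - 1] < p_minor)
                major = exposed & (uniforms["major"][:, t - 1] < p_major)
                cost_t[minor] += minor_cost
                cost_t[major] += major_cost
                qaly_t[minor] -= dec_minor * 2.0 * wf
                qaly_t[major] -= dec_major * 2.0 * wf
        qaly_t /= 12.0

        disc_cost += cost_t * disc
        disc_qaly += qaly_t * disc

        i = t - 1
        per_cycle["cycle"][i] = t
        n_alive = int(alive.sum())
        per_cycle["alive"][i] = n_alive / n
        if n_alive:
            b = bmi[alive]
            per_cycle["mean_bmi"][i] = b.mean()
            per_cycle["se_bmi"][i] = b.std(ddof=1) / np.sqrt(n_alive) if n_alive > 1 else 0.0
        else:
            per_cycle["mean_bmi"][i] = np.nan
            per_cycle["se_bmi"][i] = np.nan
        per_cycle["cost"][i] = cost_t.mean()
        per_cycle["qaly"][i] = qaly_t.mean()
        per_cycle["disc_cost"][i] = (cost_t * disc).mean()
        per_cycle["disc_qaly"][i] = (qaly_t * disc).mean()

    return MicrosimResult(
        strategy=strategy,
        n=n,
        seed=seed,
        df=pd.DataFrame(per_cycle),
        total_disc_cost=float(disc_cost.mean()),
        total_disc_qaly=float(disc_qaly.mean()),
        se_disc_cost=float(disc_cost.std(ddof=1) / np.sqrt(n)),
        se_disc_qaly=float(disc_qaly.std(ddof=1) / np.sqrt(n)),
    )


def make_scenarios(
    ps: ParameterSet, n: int, seed: int
) -> list[ParameterSet]:
    """``n`` perturbed parameter sets drawn from the PSA distributions."""
    if n < 1:
        raise ValueError("need n >= 1")
    rng = np.random.default_rng(seed)
    return [sample_parameters(ps, rng) for _ in range(n)]
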