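"""Discounting, per-cycle rewards, and cost-effectiveness comparisons.

Utility in a cycle is the class II obesity utility (0.79) plus 0.0056 per
BMI unit below the baseline BMI of 37 (symmetric: BMI above baseline is
decremented), clamped to [0, 1].  Transient procedure and complication
disutilities are duration-weighted within the month (1 month = 365.25/12
days).  Costs and QALYs accrue to the alive fraction only and are
discounted at 3%/year compounded monthly, first cycle undiscounted.

The comparison between strategies reports incremental cost, incremental
QALYs, the ICER, net monetary benefit NMB = QALY * WTP - cost, and a
dominance label ("dominant" = cheaper and more effective).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DAYS_PER_MONTH",
    "WEEK_FRACTION",
    "discount_factor",
    "cycle_utility",
    "cycle_cost",
    "nmb",
    "icer",
    "compare",
    "EconResult",
]

DAYS_PER_MONTH = 365.25 / 12.0
WEEK_FRACTION = 7.0 / DAYS_PER_MONTH  # fraction of a month covered by one week


def discount_factor(cycle: int, annual_rate: float) -> float:
    """Monthly-compounded discount factor; the first cycle is undiscounted."""
    if annual_rate < 0:
        raise ValueError("discount rate must be >= 0")
    return (1.0 + annual_rate) ** (-(cycle - 1) / 12.0)


def cycle_utility(
    mean_bmi: float,
    baseline_bmi: float,
    utility_base: float,
    utility_per_bmi: float,
    decrement_events: list[tuple[float, float, float]] | None = None,
) -> float:
    """Effective monthly utility rate for one compartment.

    ``decrement_events`` is a list of (decrement magnitude, duration in
    weeks, event probability); each subtracts
    ``magnitude * probability * weeks * WEEK_FRACTION`` from the monthly
    utility rate.  The BMI-dependent part is clamped to [0, 1] before the
    event decrements are applied.
    """
    u = utility_base + utility_per_bmi * (baseline_bmi - mean_bmi)
    u = min(1.0, max(0.0, u))
    if decrement_events:
        for magnitude, weeks, prob in decrement_events:
            u -= abs(magnitude) * prob * weeks * WEEK_FRACTION
    return u


def cycle_cost(
    strategy: str,
    cycle: int,
    on_treatment_mass: float,
    procedure_mass: float,
    complication_exposure: float,
    ps,
) -> float:
    """Expected cost accrued in one cycle (USD).

    ``procedure_mass`` is the cohort fraction undergoing ESG (index or
    repeat) this cycle; ``complication_exposure`` the fraction inside a
    post-procedure complication window.  Semaglutide accrues 1/12 of the
    annual drug cost per on-treatment member; no treatment costs nothing.
    """
    from .cohort import annual_to_monthly_prob  # local import, no cycle at import time

    if strategy == "no_treatment":
        return 0.0
    if strategy == "semaglutide":
        return on_treatment_mass * ps.value("sema_annual_cost") / 12.0
    if strategy == "esg":
        cost = procedure_mass * ps.value("esg_cost")
        if complication_exposure > 0:
            p_minor = annual_to_monthly_prob(ps.value("esg_minor_rate"))
            p_major = annual_to_monthly_prob(ps.value("esg_major_rate"))
            cost += complication_exposure * (
                p_minor * ps.value("minor_comp_cost")
                + p_major * ps.value("major_comp_cost")
            )
        return cost
    raise ValueError(f"unknown strategy {strategy!r}")


def nmb(total_qaly: float, total_cost: float, wtp: float) -> float:
    """Net monetary benefit at willingness-to-pay ``wtp``."""
    return total_qaly * wtp - total_cost


def icer(delta_cost: float, delta_qaly: float) -> float:
    """Incremental cost-effectiveness ratio; inf when QALYs are tied."""
    if delta_qaly == 0.0:
        return math.inf
    return delta_cost / delta_qaly


def _dominance_label(delta_cost: float, delta_qaly: float) -> str:
    if delta_cost < 0 and delta_qaly > 0:
        return "dominant"
    if delta_cost > 0 and delta_qaly < 0:
        return "dominated"
    if delta_qaly == 0.0:
        return "undefined"
    return ""


@dataclass
class EconResult:
    """Totals, pairwise incrementals, and NMB for a set of strategies."""

    totals: pd.DataFrame      # index strategy: cost, qaly, nmb
    pairwise: pd.DataFrame    # one row per (strategy, comparator)
    wtp: float
    horizon_months: int

    def nmb_of(self, strategy: str) -> float:
        return float(self.totals.loc[strategy, "nmb"])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<EconResult horizon={self.horizon_months} mo, wtp=${self.wtp:,.0f}\n"
            f"{self.totals.round(4)}\n{self.pairwise.round(4)}>"
        )


def compare(traces: dict, wtp: float, horizon_months: int | None = None) -> EconResult:
    """Pairwise cost-effectiveness comparison of strategy traces.

    ``traces`` maps strategy name to a :class:`~obesity_cea.cohort.CohortTrace`.
    Every trace must cover the requested horizon.  Negative-ICER pairs carry
    the dominance label alongside the raw ratio.
    """
    if not traces:
        raise ValueError("need at least one trace")
    horizons = {t.horizon_months for t in traces.values()}
    h = horizon_months or min(horizons)
    if any(h > t.horizon_months for t in traces.values()):
        raise ValueError("traces do not cover the requested horizon")

    rows = {}
    for name, tr in traces.items():
        c, q = tr.disc_cost_at(h), tr.disc_qaly_at(h)
        rows[name] = {"cost": c, "qaly": q, "nmb": nmb(q, c, wtp)}
    totals = pd.DataFrame(rows).T[["cost", "qaly", "nmb"]]

    pairs = []
    names = list(traces)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            dc = totals.loc[a, "cost"] - totals.loc[b, "cost"]
            dq = totals.loc[a, "qaly"] - totals.loc[b, "qaly"]
            pairs.append(
                {
                    "strategy": a,
                    "comparator": b,
                    "inc_cost": dc,
                    "inc_qaly": dq,
                    "icer": icer(dc, dq),
                    "label": _dominance_label(dc, dq),
                    "inc_nmb": totals.loc[a, "nmb"] - totals.loc[b, "nmb"],
                }
            )
    return EconResult(totals, pd.DataFrame(pairs), wtp, h)
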