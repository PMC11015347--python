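"""Model/Results facade over the cohort engine and economics.

:class:`MarkovCohortCEA` bundles a parameter set, life table, and BMI
hazard model; :meth:`MarkovCohortCEA.fit` runs the strategy traces and
returns a :class:`CEAResults` carrying totals, incrementals, and a
Table-style summary.  Sensitivity analyses and the PSA hang off the model.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import economics, sensitivity
from .cohort import STRATEGIES, CohortTrace, run_strategy
from .mortality import BmiHazardModel, LifeTable, load_default_life_table
from .params import ParameterSet, default_parameters, load_parameters

__all__ = ["MarkovCohortCEA", "CEAResults"]


class MarkovCohortCEA:
    """Markov cohort cost-effectiveness model of class II obesity care.

    Parameters
    ----------
    params
        Parameter registry (defaults to the base case).
    life_table
        Background mortality table (defaults to the bundled synthetic one).
    bmi_hazard
        Piecewise BMI-mortality hazard ratios.
    strategies
        Strategies to evaluate; default all three.
    """

    def __init__(
        self,
        params: ParameterSet | None = None,
        life_table: LifeTable | None = None,
        bmi_hazard: BmiHazardModel | None = None,
        strategies: tuple[str, ...] = STRATEGIES,
    ):
        self.params = params if params is not None else default_parameters()
        self.life_table = (
            life_table if life_table is not None else load_default_life_table()
        )
        self.bmi_hazard = bmi_hazard if bmi_hazard is not None else BmiHazardModel()
        unknown = set(strategies) - set(STRATEGIES)
        if unknown:
            raise ValueError(f"unknown strategies {sorted(unknown)}")
        self.strategies = tuple(strategies)

    @classmethod
    def from_config(cls, path, **kwargs) -> "MarkovCohortCEA":
        """Build a model from a YAML/JSON/CSV parameter configuration."""
        return cls(params=load_parameters(path), **kwargs)

    def fit(self, horizon_months: int | None = None) -> "CEAResults":
        """Run every strategy and return the results object."""
        horizon = int(horizon_months or self.params.value("horizon_months"))
        traces = {
            s: run_strategy(s, self.params, horizon, self.life_table, self.bmi_hazard)
            for s in self.strategies
        }
        return CEAResults(self, traces, horizon)

    # -- sensitivity interface -----------------------------------------
    def tornado(self, **kwargs) -> sensitivity.TornadoResult:
        kwargs.setdefault("lt", self.life_table)
        kwargs.setdefault("hm", self.bmi_hazard)
        return sensitivity.tornado(self.params, **kwargs)

    def two_way(self, param_a: str, param_b: str, **kwargs) -> pd.DataFrame:
        kwargs.setdefault("lt", self.life_table)
        kwargs.setdefault("hm", self.bmi_hazard)
        return sensitivity.two_way(param_a, param_b, self.params, **kwargs)

    def threshold(self, target_param: str, **kwargs) -> sensitivity.ThresholdResult:
        kwargs.setdefault("lt", self.life_table)
        kwargs.setdefault("hm", self.bmi_hazard)
        return sensitivity.threshold_search(target_param, self.params, **kwargs)

    def psa(self, **kwargs) -> sensitivity.PSAResult:
        kwargs.setdefault("lt", self.life_table)
        kwargs.setdefault("hm", self.bmi_hazard)
        return sensitivity.run_psa(self.params, **kwargs)


@dataclass
class CEAResults:
    """Fitted traces plus the economic comparison at the model's WTP."""

    model: MarkovCohortCEA
    traces: dict[str, CohortTrace]
    horizon_months: int

    def econ(self, horizon: int | None = None, wtp: float | None = None) -> economics.EconResult:
        w = wtp if wtp is not None else self.model.params.value("wtp")
        return economics.compare(self.traces, w, horizon or self.horizon_months)

    def total_cost(self, strategy: str, horizon: int | None = None) -> float:
        return self.traces[strategy].disc_cost_at(horizon or self.horizon_months)

    def total_qaly(self, strategy: str, horizon: int | None = None) -> float:
        return self.traces[strategy].disc_qaly_at(horizon or self.horizon_months)

    def bmi(self, strategy: str, horizon: int | None = None) -> float:
        """Headline BMI: mean among patients remaining on the strategy."""
        return self.traces[strategy].bmi_at(horizon or self.horizon_months)

    def table(self, horizons: tuple[int, ...] = (12, 24, 36, 48, 60)) -> pd.DataFrame:
        from .reporting import basecase_table

        return basecase_table(self, horizons)

    def summary(self, horizons: tuple[int, ...] = (12, 24, 36, 48, 60)) -> str:
        """Formatted base-case table (currency without decimals)."""
        horizons = tuple(h for h in horizons if h <= self.horizon_months)
        df = self.table(horizons)
        show = df.copy()
        for c in ("cost", "inc_cost", "nmb"):
            show[c] = show[c].map(lambda v: "" if pd.isna(v) else f"{v:,.0f}")
        show["icer"] = df.apply(
            lambda r: r["icer_label"]
            if r["icer_label"] not in ("", None)
            else ("" if pd.isna(r["icer"]) else f"{r['icer']:,.0f}"),
            axis=1,
        )
        show["qaly"] = df["qaly"].map(lambda v: f"{v:.3f}")
        show["inc_qaly"] = df["inc_qaly"].map(
            lambda v: "" if pd.isna(v) else f"{v:.4f}"
        )
        show["bmi"] = df["bmi"].map(lambda v: f"{v:.1f}")
        cols = [
            "horizon_months", "strategy", "cost", "inc_cost",
            "qaly", "inc_qaly", "icer", "nmb", "bmi",
        ]
        wtp = self.model.params.value("wtp")
        header = (
            f"Markov cohort cost-effectiveness results "
            f"(WTP ${wtp:,.0f}/QALY, discounted)\n"
        )
        return header + show[cols].to_string(index=False)
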