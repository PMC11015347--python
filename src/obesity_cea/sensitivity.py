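"""One-way, two-way, threshold, and probabilistic sensitivity analyses.

All analyses re-run the full cohort model.  Decision rules use net monetary
benefit (NMB = QALY * WTP - cost), which stays well-defined where the ICER
changes sign; comparisons follow the head-to-head framing of the two active
strategies (ESG vs semaglutide) unless told otherwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import economics
from .cohort import run_strategy
from .mortality import BmiHazardModel, LifeTable, load_default_life_table
from .params import ParameterSet, default_parameters, fit_distribution, sample_parameters

__all__ = [
    "one_way",
    "tornado",
    "TornadoResult",
    "two_way",
    "threshold_search",
    "ThresholdResult",
    "run_psa",
    "PSAResult",
]

logger = logging.getLogger(__name__)

ACTIVE_PAIR = ("esg", "semaglutide")


def _totals(strategy, ps, horizon, lt, hm):
    tr = run_strategy(strategy, ps, horizon, lt, hm)
    return tr.disc_cost_at(horizon), tr.disc_qaly_at(horizon)


def _pair_metrics(ps, horizon, wtp, lt, hm, pair=ACTIVE_PAIR):
    ca, qa = _totals(pair[0], ps, horizon, lt, hm)
    cb, qb = _totals(pair[1], ps, horizon, lt, hm)
    return {
        "icer": economics.icer(ca - cb, qa - qb),
        "inc_nmb": economics.nmb(qa, ca, wtp) - economics.nmb(qb, cb, wtp),
        "inc_cost": ca - cb,
        "inc_qaly": qa - qb,
    }


def one_way(
    param_name: str,
    ps: ParameterSet | None = None,
    horizon: int = 60,
    wtp: float = 100_000.0,
    lt: LifeTable | None = None,
    hm: BmiHazardModel | None = None,
    pair: tuple[str, str] = ACTIVE_PAIR,
) -> dict:
    """Evaluate the model at a parameter's low and high, all else at base."""
    ps = ps if ps is not None else default_parameters()
    lt = lt if lt is not None else load_default_life_table()
    hm = hm if hm is not None else BmiHazardModel()
    p = ps.get(param_name)
    lo = _pair_metrics(ps.with_values(**{param_name: p.low}), horizon, wtp, lt, hm, pair)
    hi = _pair_metrics(ps.with_values(**{param_name: p.high}), horizon, wtp, lt, hm, pair)
    return {
        "parameter": param_name,
        "low_value": p.low,
        "high_value": p.high,
        "icer_low": lo["icer"],
        "icer_high": hi["icer"],
        "inc_nmb_low": lo["inc_nmb"],
        "inc_nmb_high": hi["inc_nmb"],
        "spread": abs(hi["inc_nmb"] - lo["inc_nmb"]),
    }


@dataclass
class TornadoResult:
    """Per-parameter one-way results sorted by NMB spread (widest first)."""

    df: pd.DataFrame
    base_icer: float
    base_inc_nmb: float
    horizon: int
    wtp: float


def tornado(
    ps: ParameterSet | None = None,
    parameters: list[str] | None = None,
    horizon: int = 60,
    wtp: float = 100_000.0,
    lt: LifeTable | None = None,
    hm: BmiHazardModel | None = None,
    pair: tuple[str, str] = ACTIVE_PAIR,
) -> TornadoResult:
    """One-way sensitivity analysis over every ranged parameter."""
    ps = ps if ps is not None else default_parameters()
    lt = lt if lt is not None else load_default_life_table()
    hm = hm if hm is not None else BmiHazardModel()
    names = parameters or [p.name for p in ps if p.has_range]
    base = _pair_metrics(ps, horizon, wtp, lt, hm, pair)
    rows = [one_way(n, ps, horizon, wtp, lt, hm, pair) for n in names]
    df = pd.DataFrame(rows).sort_values("spread", ascending=False).reset_index(drop=True)
    return TornadoResult(df, base["icer"], base["inc_nmb"], horizon, wtp)


def two_way(
    param_a: str,
    param_b: str,
    ps: ParameterSet | None = None,
    grid_a: int = 10,
    grid_b: int = 10,
    horizon: int = 60,
    wtp: float = 100_000.0,
    lt: LifeTable | None = None,
    hm: BmiHazardModel | None = None,
    pair: tuple[str, str] = ACTIVE_PAIR,
) -> pd.DataFrame:
    """NMB-preferred strategy over a grid of two parameters' ranges.

    Returns a DataFrame indexed by ``param_a`` values with ``param_b``
    values as columns; each cell holds the preferred strategy name.
    """
    ps = ps if ps is not None else default_parameters()
    lt = lt if lt is not None else load_default_life_table()
    hm = hm if hm is not None else BmiHazardModel()
    pa, pb = ps.get(param_a), ps.get(param_b)
    a_vals = np.linspace(pa.low, pa.high, grid_a)
    b_vals = np.linspace(pb.low, pb.high, grid_b)
    cells = []
    for av in a_vals:
        row = []
        for bv in b_vals:
            m = _pair_metrics(
                ps.with_values(**{param_a: float(av), param_b: float(bv)}),
                horizon, wtp, lt, hm, pair,
            )
            row.append(pair[0] if m["inc_nmb"] > 0 else pair[1])
        cells.append(row)
    return pd.DataFrame(cells, index=a_vals, columns=b_vals)


@dataclass
class ThresholdResult:
    """Solution of a threshold (price-search) analysis."""

    parameter: str
    bracket: tuple[float, float]
    value: float
    achieved_icer: float
    boundary: str          # "icer" or "cost_parity"
    tolerance: float
    horizon: int
    wtp: float


def threshold_search(
    target_param: str,
    ps: ParameterSet | None = None,
    horizon: int = 60,
    wtp: float = 100_000.0,
    tol: float = 1.0,
    bracket: tuple[float, float] | None = None,
    lt: LifeTable | None = None,
    hm: BmiHazardModel | None = None,
    pair: tuple[str, str] = ACTIVE_PAIR,
) -> ThresholdResult:
    """Bisection on a parameter until the pair reaches the WTP boundary.

    Solves ``inc_NMB(pair[0] vs pair[1]) = 0`` at the given WTP, i.e. the
    point where the richer strategy's ICER equals WTP (or, when the QALY
    difference is adverse throughout, the cost-parity/dominance boundary).
    Raises if the incremental NMB does not change sign over the bracket.
    """
    ps = ps if ps is not None else default_parameters()
    lt = lt if lt is not None else load_default_life_table()
    hm = hm if hm is not None else BmiHazardModel()
    p = ps.get(target_param)
    if bracket is None:
        bracket = (p.low, p.high)
    lo, hi = float(bracket[0]), float(bracket[1])

    def f(v: float) -> float:
        return _pair_metrics(
            ps.with_values(**{target_param: float(v)}), horizon, wtp, lt, hm, pair
        )["inc_nmb"]

    f_lo, f_hi = f(lo), f(hi)
    if f_lo == 0.0:
        sol = lo
    elif f_hi == 0.0:
        sol = hi
    elif np.sign(f_lo) == np.sign(f_hi):
        raise ValueError(
            f"incremental NMB does not change sign over bracket ({lo}, {hi}): "
            f"f(lo)={f_lo:.1f}, f(hi)={f_hi:.1f}"
        )
    else:
        sol = float(brentq(f, lo, hi, xtol=tol))

    m = _pair_metrics(
        ps.with_values(**{target_param: sol}), horizon, wtp, lt, hm, pair
    )
    boundary = "icer" if m["inc_qaly"] > 0 else "cost_parity"
    if boundary == "cost_parity":
        logger.info(
            "threshold on %s found on the cost-parity/dominance boundary "
            "(QALY difference <= 0 at the solution)", target_param,
        )
    return ThresholdResult(
        parameter=target_param,
        bracket=(lo, hi),
        value=sol,
        achieved_icer=m["icer"],
        boundary=boundary,
        tolerance=tol,
        horizon=horizon,
        wtp=wtp,
    )


@dataclass
class PSAResult:
    """Second-order Monte Carlo results.

    ``cost``/``qaly`` are (n_iter, n_strategies) arrays per horizon;
    ``prob_ce`` holds, per horizon, the fraction of draws in which each
    strategy has the maximum NMB (ties broken toward the cheaper strategy).
    """

    strategies: tuple[str, ...]
    horizons: tuple[int, ...]
    n_iter: int
    seed: int
    wtp: float
    cost: dict[int, np.ndarray]
    qaly: dict[int, np.ndarray]

    def nmb(self, horizon: int, wtp: float | None = None) -> np.ndarray:
        w = self.wtp if wtp is None else wtp
        return self.qaly[horizon] * w - self.cost[horizon]

    def prob_cost_effective(
        self, horizon: int, wtp: float | None = None
    ) -> dict[str, float]:
        nmb = self.nmb(horizon, wtp)
        cost = self.cost[horizon]
        # max NMB wins; exact ties broken toward the cheaper strategy
        is_best = nmb == nmb.max(axis=1, keepdims=True)
        winners = np.argmin(np.where(is_best, cost, np.inf), axis=1)
        best = np.zeros(len(self.strategies), dtype=float)
        idx, counts = np.unique(winners, return_counts=True)
        best[idx] = counts / nmb.shape[0]
        return dict(zip(self.strategies, best))

    def summary(self, wtp: float | None = None) -> pd.DataFrame:
        rows = {
            s: {
                f"month_{h}": 100.0 * self.prob_cost_effective(h, wtp)[s]
                for h in self.horizons
            }
            for s in self.strategies
        }
        return pd.DataFrame(rows).T

    def ceac(
        self, horizon: int, wtp_grid: np.ndarray | list[float]
    ) -> pd.DataFrame:
        """Cost-effectiveness acceptability curve over a WTP grid."""
        rows = []
        for w in wtp_grid:
            probs = self.prob_cost_effective(horizon, float(w))
            rows.append({"wtp": float(w), **probs})
        return pd.DataFrame(rows)


def run_psa(
    ps: ParameterSet | None = None,
    horizons: tuple[int, ...] = (12, 24, 36, 48, 60),
    n_iter: int = 10_000,
    seed: int = 1,
    wtp: float = 100_000.0,
    lt: LifeTable | None = None,
    hm: BmiHazardModel | None = None,
    strategies: tuple[str, ...] = ACTIVE_PAIR,
) -> PSAResult:
    """Probabilistic sensitivity analysis by second-order Monte Carlo.

    Each iteration draws one parameter set from the fitted distributions
    (all ranged parameters simultaneously, independently) and evaluates
    every strategy on that same draw at all horizons.  Fully reproducible
    under ``seed``.
    """
    ps = ps if ps is not None else default_parameters()
    lt = lt if lt is not None else load_default_life_table()
    hm = hm if hm is not None else BmiHazardModel()
    if n_iter < 1:
        raise ValueError("need n_iter >= 1")
    horizons = tuple(int(h) for h in horizons)
    h_max = max(horizons)
    rng = np.random.default_rng(seed)
    n_s = len(strategies)
    cost = {h: np.zeros((n_iter, n_s)) for h in horizons}
    qaly = {h: np.zeros((n_iter, n_s)) for h in horizons}
    for i in range(n_iter):
        draw = sample_parameters(ps, rng)
        for j, s in enumerate(strategies):
            tr = run_strategy(s, draw, h_max, lt, hm)
            for h in horizons:
                cost[h][i, j] = tr.disc_cost_at(h)
                qaly[h][i, j] = tr.disc_qaly_at(h)
    return PSAResult(
        strategies=tuple(strategies),
        horizons=horizons,
        n_iter=n_iter,
        seed=seed,
        wtp=wtp,
        cost=cost,
        qaly=qaly,
    )
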