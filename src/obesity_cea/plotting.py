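"""Matplotlib views: tornado bars, cost-effectiveness plane, CEAC."""

from __future__ import annotations

import numpy as np

from .sensitivity import PSAResult, TornadoResult

__all__ = ["plot_tornado", "plot_ce_plane", "plot_ceac"]


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_tornado(result: TornadoResult, top: int = 10, ax=None):
    """Horizontal bars of incremental-NMB swing, widest at the top."""
    ax = _ax(ax)
    df = result.df.head(top).iloc[::-1]
    base = result.base_inc_nmb
    y = np.arange(len(df))
    lo = np.minimum(df["inc_nmb_low"], df["inc_nmb_high"]) - base
    hi = np.maximum(df["inc_nmb_low"], df["inc_nmb_high"]) - base
    ax.barh(y, hi - lo, left=base + lo, color="#4477aa")
    ax.axvline(base, color="k", lw=1)
    ax.set_yticks(y, df["parameter"])
    ax.set_xlabel("incremental NMB, ESG vs semaglutide ($)")
    ax.set_title(f"One-way sensitivity, {result.horizon}-month horizon")
    return ax


def plot_ce_plane(psa: PSAResult, horizon: int | None = None, ax=None):
    """Incremental cost vs incremental QALYs per PSA draw (first vs second)."""
    ax = _ax(ax)
    h = horizon or max(psa.horizons)
    dq = psa.qaly[h][:, 0] - psa.qaly[h][:, 1]
    dc = psa.cost[h][:, 0] - psa.cost[h][:, 1]
    ax.scatter(dq, dc, s=4, alpha=0.3, color="#4477aa")
    ax.axhline(0, color="k", lw=0.8)
    ax.axvline(0, color="k", lw=0.8)
    grid = np.linspace(*ax.get_xlim(), 10)
    ax.plot(grid, psa.wtp * grid, "--", color="#cc6677", label=f"WTP ${psa.wtp:,.0f}/QALY")
    ax.set_xlabel(f"incremental QALYs ({psa.strategies[0]} - {psa.strategies[1]})")
    ax.set_ylabel("incremental cost ($)")
    ax.legend()
    return ax


def plot_ceac(psa: PSAResult, horizon: int | None = None, wtp_grid=None, ax=None):
    """Probability each strategy is cost-effective as a function of WTP."""
    ax = _ax(ax)
    h = horizon or max(psa.horizons)
    if wtp_grid is None:
        wtp_grid = np.linspace(0, 250_000, 26)
    df = psa.ceac(h, wtp_grid)
    for s in psa.strategies:
        ax.plot(df["wtp"], df[s], label=s)
    ax.set_xlabel("willingness to pay ($/QALY)")
    ax.set_ylabel("probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    ax.set_title(f"CEAC, {h}-month horizon")
    return ax
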