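"""Report writers mirroring the published table layouts, plus run manifests.

``basecase_table`` produces one row per (horizon, strategy) with cumulative
and incremental discounted cost and QALYs, the ICER (with dominance
labels), NMB, and the headline BMI.  Incrementals follow the head-to-head
framing: ESG vs semaglutide where both are present, otherwise each active
strategy vs no treatment.  ``psa_table`` formats acceptability percentages
per horizon.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import economics
from .params import ParameterSet
from .sensitivity import PSAResult

__all__ = ["basecase_table", "basecase_report", "psa_table", "psa_report", "RunManifest"]


def _pairing(strategies: list[str]) -> dict[str, str | None]:
    """Comparator per strategy for the incremental columns."""
    out: dict[str, str | None] = {s: None for s in strategies}
    if "esg" in strategies and "semaglutide" in strategies:
        out["esg"] = "semaglutide"
    elif "no_treatment" in strategies:
        for s in strategies:
            if s != "no_treatment":
                out[s] = "no_treatment"
    return out


def basecase_table(results, horizons=(12, 24, 36, 48, 60)) -> pd.DataFrame:
    """Base-case results over time horizons, one row per (horizon, strategy)."""
    horizons = tuple(h for h in horizons if h <= results.horizon_months)
    if not horizons:
        raise ValueError("no horizons inside the fitted range")
    strategies = list(results.traces)
    if not strategies:
        raise ValueError("no strategies fitted")
    wtp = results.model.params.value("wtp")
    pairing = _pairing(strategies)
    rows = []
    for h in horizons:
        for s in strategies:
            tr = results.traces[s]
            c, q = tr.disc_cost_at(h), tr.disc_qaly_at(h)
            row = {
                "horizon_months": h,
                "strategy": s,
                "cost": c,
                "qaly": q,
                "nmb": economics.nmb(q, c, wtp),
                "bmi": tr.bmi_at(h),
                "inc_cost": math.nan,
                "inc_qaly": math.nan,
                "icer": math.nan,
                "icer_label": "",
            }
            comp = pairing[s]
            if comp is not None:
                tc = results.traces[comp]
                dc = c - tc.disc_cost_at(h)
                dq = q - tc.disc_qaly_at(h)
                row["inc_cost"] = dc
                row["inc_qaly"] = dq
                row["icer"] = economics.icer(dc, dq)
                row["icer_label"] = economics._dominance_label(dc, dq)
            rows.append(row)
    return pd.DataFrame(rows)


def basecase_report(results, horizons=(12, 24, 36, 48, 60), out_dir=None):
    """Write the base-case table as CSV + JSON; returns the DataFrame."""
    df = basecase_table(results, horizons)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        df.to_csv(out_dir / "basecase.csv", index=False)
        (out_dir / "basecase.json").write_text(
            df.to_json(orient="records", indent=2)
        )
    return df


def psa_table(psa: PSAResult, wtp: float | None = None) -> pd.DataFrame:
    """Acceptability percentages per horizon (rows = strategies)."""
    df = psa.summary(wtp)
    df.insert(0, "n_iter", psa.n_iter)
    df.insert(1, "seed", psa.seed)
    return df


def psa_report(psa: PSAResult, out_dir=None, wtp: float | None = None):
    """Write PSA acceptability, CE-plane samples, and a CEAC to CSV.

    NMB ties between strategies are broken toward the lower-cost strategy
    (noted in the written footer).
    """
    df = psa_table(psa, wtp)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        df.to_csv(out_dir / "psa_acceptability.csv")
        h = max(psa.horizons)
        plane = pd.DataFrame(
            {
                f"{s}_{kind}": arr[:, j]
                for j, s in enumerate(psa.strategies)
                for kind, arr in (("cost", psa.cost[h]), ("qaly", psa.qaly[h]))
            }
        )
        plane.to_csv(out_dir / f"ce_plane_month_{h}.csv", index=False)
        grid = [0, 20_000, 50_000, 100_000, 150_000, 250_000, 500_000]
        psa.ceac(h, grid).to_csv(out_dir / f"ceac_month_{h}.csv", index=False)
        (out_dir / "psa_footer.txt").write_text(
            "Cost-effectiveness = maximum net monetary benefit; "
            "ties broken toward the lower-cost strategy.\n"
        )
    return df


def parameter_checksum(ps: ParameterSet) -> str:
    payload = ps.to_frame().to_csv(index=False).encode()
    return hashlib.sha256(payload).hexdigest()


@dataclass
class RunManifest:
    """Provenance of one CLI run; written even when the run fails."""

    command: str
    parameter_checksum: str
    seed: int | None
    package_version: str
    started: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )
    finished: str | None = None
    status: str = "running"
    outputs: list[str] = field(default_factory=list)

    def add_output(self, path) -> None:
        self.outputs.append(str(path))

    def finalize(self, status: str = "ok") -> None:
        self.status = status
        self.finished = datetime.now(timezone.utc).isoformat()

    def write(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps(asdict(self), indent=2))
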