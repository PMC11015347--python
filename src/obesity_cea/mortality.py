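"""Background and procedural mortality.

Background mortality comes from an age-by-sex life table of annual death
probabilities (qx).  The model adjusts qx for BMI with a piecewise hazard
ratio (reference band BMI < 25), caps the adjusted annual probability at 1,
and converts it to a monthly probability assuming a constant hazard within
the year.  Endoscopic sleeve gastroplasty adds a one-time 30-day procedural
mortality in the procedure cycle, combined with background mortality on the
survival scale.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LifeTable",
    "BmiHazardModel",
    "monthly_mortality",
    "combine_monthly_probs",
    "load_default_life_table",
]

SEXES = ("female", "male", "combined")


class LifeTable:
    """Annual death probabilities qx indexed by (age, sex)."""

    def __init__(self, df: pd.DataFrame):
        required = {"age", "sex", "qx"}
        if not required <= set(df.columns):
            raise ValueError(f"life table needs columns {sorted(required)}")
        bad = set(df["sex"]) - set(SEXES)
        if bad:
            raise ValueError(f"unknown sex value(s) {sorted(bad)}")
        if ((df["qx"] < 0) | (df["qx"] > 1)).any():
            raise ValueError("qx must lie in [0, 1]")
        self.df = df.reset_index(drop=True)
        self._qx = {
            sex: dict(zip(g["age"].astype(int), g["qx"].astype(float)))
            for sex, g in df.groupby("sex")
        }
        ages = sorted(df["age"].unique())
        self.age_min, self.age_max = int(ages[0]), int(ages[-1])

    def qx(self, age: int, sex: str = "combined") -> float:
        """Annual death probability at completed integer ``age``."""
        try:
            table = self._qx[sex]
        except KeyError:
            raise KeyError(f"life table has no sex {sex!r}") from None
        age = int(age)
        if age not in table:
            raise ValueError(
                f"age {age} outside life-table range "
                f"[{self.age_min}, {self.age_max}]"
            )
        return table[age]

    def qx_mixed(self, age: int, female_fraction: float) -> float:
        """Female/male blend of qx at the cohort's sex mix."""
        return female_fraction * self.qx(age, "female") + (
            1.0 - female_fraction
        ) * self.qx(age, "male")

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def zero(cls, ages=range(20, 111)) -> "LifeTable":
        """A no-mortality table (useful for closed-form checks)."""
        rows = [
            {"age": a, "sex": s, "qx": 0.0} for s in SEXES for a in ages
        ]
        return cls(pd.DataFrame(rows))


def load_default_life_table() -> LifeTable:
    """The bundled synthetic life table (see :mod:`obesity_cea.synth`)."""
    ref = importlib.resources.files("obesity_cea") / "data" / "life_table_synthetic.csv"
    with importlib.resources.as_file(ref) as path:
        return LifeTable.from_csv(path)


@dataclass(frozen=True)
class BmiHazardModel:
    """Piecewise all-cause mortality hazard ratio by BMI band.

    ``edges`` are the band boundaries; ``ratios`` has one more entry than
    ``edges`` and gives the hazard ratio for BMI below the first edge, each
    interior band, and at/above the last edge.  The reference band
    (BMI < 25) must carry HR 1 and ratios must be non-decreasing.
    """

    edges: tuple[float, ...] = (25.0, 30.0, 35.0, 40.0)
    ratios: tuple[float, ...] = (1.0, 1.2, 1.6, 2.0, 2.6)

    def __post_init__(self) -> None:
        if len(self.ratios) != len(self.edges) + 1:
            raise ValueError("need len(ratios) == len(edges) + 1")
        if self.ratios[0] != 1.0:
            raise ValueError("reference band (lowest BMI) must have HR 1.0")
        if any(b < a for a, b in zip(self.ratios, self.ratios[1:])):
            raise ValueError("hazard ratios must be non-decreasing in BMI")
        if any(r < 0 for r in self.ratios):
            raise ValueError("hazard ratios must be >= 0")

    def hr(self, bmi: float) -> float:
        return self.ratios[int(np.searchsorted(self.edges, bmi, side="right"))]

    def hr_array(self, bmi: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.edges, bmi, side="right")
        return np.asarray(self.ratios)[idx]

    @classmethod
    def flat(cls) -> "BmiHazardModel":
        """No BMI adjustment (HR 1 everywhere)."""
        return cls(ratios=(1.0,) * (len(cls().edges) + 1))


def monthly_mortality(
    age: int,
    sex: str | float,
    bmi: float,
    lt: LifeTable,
    hm: BmiHazardModel,
) -> float:
    """Monthly death probability adjusted for age, sex, and BMI.

    ``sex`` is a life-table sex label or a float female fraction.  The BMI
    hazard ratio multiplies the annual probability (capped at 1) before the
    constant-hazard monthly conversion::

        p_month = 1 - (1 - min(1, qx * HR(bmi))) ** (1 / 12)
    """
    if isinstance(sex, str):
        qx = lt.qx(age, sex)
    else:
        qx = lt.qx_mixed(age, float(sex))
    q_adj = min(1.0, qx * hm.hr(bmi))
    return 1.0 - (1.0 - q_adj) ** (1.0 / 12.0)


def combine_monthly_probs(p_background: float, p_event: float) -> float:
    """Combine independent monthly death probabilities on the survival scale."""
    return 1.0 - (1.0 - p_background) * (1.0 - p_event)
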