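"""Model parameter registry, configuration loading, and PSA distributions.

The registry holds every input of the decision model: monthly BMI slopes for
each strategy, dropout and complication rates, the class II obesity utility
and its per-BMI-unit slope, transient procedure disutilities, costs in 2022
USD, and structural settings (horizon, discount rate, willingness to pay,
cohort demographics).  Each entry carries a base-case value, a plausible
(low, high) range, and a distribution family used by the probabilistic
sensitivity analysis: ``normal`` for weight-change slopes, ``gamma`` for
costs, ``beta`` for probabilities and utilities, ``fixed`` for entries with
no published range or for structural constants.

Ranges are interpreted as symmetric 95% intervals, so the fitted standard
deviation is (high - low) / (2 * 1.96).  Beta and gamma distributions are
fitted by the method of moments; utility decrements (negative values with a
beta family) are fitted on the magnitude scale and the sign restored on
sampling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Parameter",
    "ParameterSet",
    "DistributionSpec",
    "ParameterError",
    "ConfigError",
    "default_parameters",
    "load_parameters",
    "write_parameters",
    "fit_distribution",
    "sample_parameters",
]

logger = logging.getLogger(__name__)

FAMILIES = ("beta", "gamma", "normal", "fixed")

#: ranges are read as central 95% intervals: SD = (high - low) / Z95_WIDTH
Z95_WIDTH = 2.0 * 1.96


class ParameterError(ValueError):
    """A parameter value, range, or distribution is inadmissible."""


class ConfigError(ValueError):
    """A configuration file is malformed or names an unknown parameter."""


@dataclass(frozen=True)
class Parameter:
    """One named model input with base value, range, and PSA family."""

    name: str
    base: float
    low: float
    high: float
    family: str = "fixed"
    units: str = ""
    applies_to: str = "all"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ParameterError(
                f"{self.name}: unknown distribution family {self.family!r}"
            )
        if not (self.low <= self.base <= self.high):
            raise ParameterError(
                f"{self.name}: range must satisfy low <= base <= high, got "
                f"({self.low}, {self.base}, {self.high})"
            )
        if self.family == "beta":
            # probabilities/utilities; decrements are validated on magnitude
            lo, hi = sorted((abs(self.low), abs(self.high)))
            if not (0.0 <= lo and hi <= 1.0):
                raise ParameterError(
                    f"{self.name}: beta-family values must lie in [0, 1] on "
                    f"the probability scale, got ({self.low}, {self.high})"
                )
        if self.family == "gamma" and self.low < 0:
            raise ParameterError(f"{self.name}: gamma-family low must be >= 0")

    @property
    def is_fixed(self) -> bool:
        return self.family == "fixed" or self.low == self.high

    @property
    def has_range(self) -> bool:
        return self.low < self.high


@dataclass(frozen=True)
class DistributionSpec:
    """A fitted sampling distribution for one parameter.

    ``a``/``b`` are (mean, sd) for normal, (alpha, beta) for beta, and
    (shape, scale) for gamma.  ``sign`` restores the sign of magnitudes
    (utility decrements are fitted on the positive scale).  A ``fixed`` spec
    is a point mass at ``a``.
    """

    family: str
    a: float
    b: float = 0.0
    sign: float = 1.0

    def mean(self) -> float:
        if self.family == "fixed":
            return self.a
        if self.family == "normal":
            return self.a
        if self.family == "beta":
            return self.sign * self.a / (self.a + self.b)
        if self.family == "gamma":
            return self.sign * self.a * self.b
        raise ParameterError(f"unknown family {self.family!r}")

    def sample(self, rng: np.random.Generator, size: int | None = None):
        if self.family == "fixed":
            return self.a if size is None else np.full(size, self.a)
        if self.family == "normal":
            return rng.normal(self.a, self.b, size)
        if self.family == "beta":
            draw = np.clip(rng.beta(self.a, self.b, size), 0.0, 1.0)
            return self.sign * draw
        if self.family == "gamma":
            draw = np.maximum(rng.gamma(self.a, self.b, size), 0.0)
            return self.sign * draw
        raise ParameterError(f"unknown family {self.family!r}")


def fit_distribution(p: Parameter) -> DistributionSpec:
    """Method-of-moments fit with mean = base and SD = (high - low) / 3.92.

    Beta is fitted on the probability (magnitude) scale, gamma on the cost
    scale, normal is unbounded.  A zero-width range degenerates to a point
    mass.
    """
    if p.is_fixed:
        return DistributionSpec("fixed", p.base)
    sd = (p.high - p.low) / Z95_WIDTH
    if p.family == "normal":
        return DistributionSpec("normal", p.base, sd)
    sign = -1.0 if p.base < 0 else 1.0
    m = abs(p.base)
    if p.family == "gamma":
        if m == 0:
            raise ParameterError(f"{p.name}: gamma fit requires a nonzero mean")
        shape = (m / sd) ** 2
        scale = sd * sd / m
        return DistributionSpec("gamma", shape, scale, sign)
    if p.family == "beta":
        var = sd * sd
        if var >= m * (1.0 - m):
            raise ParameterError(
                f"{p.name}: beta moments infeasible (SD^2 >= mean*(1-mean))"
            )
        k = m * (1.0 - m) / var - 1.0
        return DistributionSpec("beta", m * k, (1.0 - m) * k, sign)
    raise ParameterError(f"{p.name}: cannot fit family {p.family!r}")


class ParameterSet:
    """Ordered registry of :class:`Parameter` keyed by name."""

    def __init__(self, parameters: Iterator[Parameter] | list[Parameter]):
        self._params: dict[str, Parameter] = {}
        for p in parameters:
            if p.name in self._params:
                raise ParameterError(f"duplicate parameter name {p.name!r}")
            self._params[p.name] = p

    # -- access ---------------------------------------------------------
    def get(self, name: str) -> Parameter:
        try:
            return self._params[name]
        except KeyError:
            raise KeyError(f"unknown parameter {name!r}") from None

    def value(self, name: str) -> float:
        return self.get(name).base

    def __getitem__(self, name: str) -> Parameter:
        return self.get(name)

    def __iter__(self) -> Iterator[Parameter]:
        return iter(self._params.values())

    def __len__(self) -> int:
        return len(self._params)

    def __contains__(self, name: str) -> bool:
        return name in self._params

    @property
    def names(self) -> list[str]:
        return list(self._params)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ParameterSet):
            return NotImplemented
        return self._params == other._params

    # -- derived sets ---------------------------------------------------
    def with_values(self, **overrides: float) -> "ParameterSet":
        """Return a copy with the named base values replaced.

        Ranges are widened to keep low <= base <= high when an override
        falls outside the original bracket (needed for sampled sets).
        """
        out = []
        for p in self:
            if p.name in overrides:
                v = float(overrides.pop(p.name))
                out.append(
                    replace(p, base=v, low=min(p.low, v), high=max(p.high, v))
                )
            else:
                out.append(p)
        if overrides:
            raise KeyError(f"unknown parameter(s) {sorted(overrides)}")
        return ParameterSet(out)

    # -- tabular I/O ----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "name": p.name,
                    "base": p.base,
                    "low": p.low,
                    "high": p.high,
                    "family": p.family,
                    "units": p.units,
                    "applies_to": p.applies_to,
                }
                for p in self
            ]
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ParameterSet":
        df = pd.read_csv(path)
        required = {"name", "base", "low", "high", "family", "units"}
        missing = required - set(df.columns)
        if missing:
            raise ConfigError(f"parameter CSV missing columns {sorted(missing)}")
        params = [
            Parameter(
                name=str(r["name"]),
                base=float(r["base"]),
                low=float(r["low"]),
                high=float(r["high"]),
                family=str(r["family"]),
                units=str(r["units"]) if not pd.isna(r["units"]) else "",
                applies_to=str(r.get("applies_to", "all")),
            )
            for _, r in df.iterrows()
        ]
        return cls(params)


def _P(name, base, low, high, family, units, applies_to="all") -> Parameter:
    return Parameter(name, base, low, high, family, units, applies_to)


def default_parameters() -> ParameterSet:
    """The base-case registry.

    BMI slopes are in BMI units per month, rates are annual probabilities,
    costs are 2022 USD.  Entries without a published range (and structural
    constants) are ``fixed`` and do not vary in the PSA unless a range is
    supplied in a configuration file.
    """
    month = "BMI units/month"
    return ParameterSet(
        [
            # -- weight trajectories ------------------------------------
            _P("esg_bmi_slope_y1", -0.40, -0.44, -0.36, "normal", month, "esg"),
            _P("esg_bmi_slope_y2_5", 0.0065, 0.0059, 0.0072, "normal", month, "esg"),
            _P("sema_bmi_slope_y1", -0.34, -0.38, -0.31, "normal", month, "semaglutide"),
            _P("sema_bmi_slope_y2_5", 0.0012, 0.0011, 0.0013, "normal", month, "semaglutide"),
            _P("dropout_bmi_slope", 0.138, 0.124, 0.152, "normal", month, "semaglutide"),
            _P("natural_bmi_slope", 0.0127, 0.0114, 0.0140, "normal", month, "all"),
            # -- treatment-path probabilities ---------------------------
            _P("dropout_y1", 0.10, 0.06, 0.14, "beta", "probability/year", "semaglutide"),
            _P("dropout_y2_5", 0.0325, 0.0195, 0.0455, "beta", "probability/year", "semaglutide"),
            _P("esg_mortality_30d", 0.002, 0.001, 0.003, "beta", "probability", "esg"),
            _P("esg_minor_rate", 0.10, 0.06, 0.14, "beta", "probability/year", "esg"),
            _P("esg_major_rate", 0.02, 0.01, 0.03, "beta", "probability/year", "esg"),
            _P("repeat_esg_prop", 0.16, 0.13, 0.19, "beta", "proportion", "esg"),
            # -- quality of life ----------------------------------------
            _P("utility_class2_obesity", 0.79, 0.79, 0.79, "fixed", "utility", "all"),
            _P("utility_per_bmi_unit", 0.0056, 0.0, 0.017, "beta", "utility/BMI unit", "all"),
            _P("utility_dec_initial", -0.22, -0.24, -0.20, "beta", "utility (1 wk)", "esg"),
            _P("utility_dec_minor", -0.11, -0.12, -0.10, "beta", "utility (2 wk)", "esg"),
            _P("utility_dec_major", -0.36, -0.40, -0.32, "beta", "utility (2 wk)", "esg"),
            # -- costs (2022 USD) ---------------------------------------
            _P("esg_cost", 16360.0, 12270.0, 20450.0, "gamma", "USD", "esg"),
            _P("sema_annual_cost", 13618.0, 10214.0, 17023.0, "gamma", "USD/year", "semaglutide"),
            _P("major_comp_cost", 32840.0, 24630.0, 41050.0, "gamma", "USD", "esg"),
            _P("minor_comp_cost", 2676.0, 2007.0, 3346.0, "gamma", "USD", "esg"),
            # -- structural constants -----------------------------------
            _P("discount_rate", 0.03, 0.03, 0.03, "fixed", "per year"),
            _P("wtp", 100000.0, 100000.0, 100000.0, "fixed", "USD/QALY"),
            _P("baseline_age", 45.0, 45.0, 45.0, "fixed", "years"),
            _P("baseline_bmi", 37.0, 37.0, 37.0, "fixed", "BMI units"),
            _P("horizon_months", 60.0, 60.0, 60.0, "fixed", "months"),
            _P("regain_plateau_months", 3.0, 3.0, 3.0, "fixed", "months"),
            _P("repeat_esg_month", 24.0, 24.0, 24.0, "fixed", "month index", "esg"),
            _P("female_fraction", 0.74, 0.74, 0.74, "fixed", "proportion"),
            _P("dropout_regain_cap", 0.0, 0.0, 0.0, "fixed", "flag (1 = cap at natural history)"),
        ]
    )


# parameters that must stay inside [0, 1] whatever the configuration says
_PROBABILITY_KEYS = {
    "dropout_y1",
    "dropout_y2_5",
    "esg_mortality_30d",
    "esg_minor_rate",
    "esg_major_rate",
    "repeat_esg_prop",
    "utility_class2_obesity",
    "female_fraction",
}
_COST_KEYS = {"esg_cost", "sema_annual_cost", "major_comp_cost", "minor_comp_cost"}


def _validate_registry(ps: ParameterSet) -> ParameterSet:
    for key in _PROBABILITY_KEYS:
        p = ps.get(key)
        if not (0.0 <= p.low and p.high <= 1.0):
            raise ConfigError(f"{key}: probability must lie in [0, 1], got {p.base}")
    for key in _COST_KEYS:
        if ps.get(key).low < 0:
            raise ConfigError(f"{key}: costs must be >= 0")
    if ps.value("horizon_months") < 1:
        raise ConfigError("horizon_months must be >= 1")
    return ps


def load_parameters(path: str | Path) -> ParameterSet:
    """Load a YAML/JSON configuration, filling missing keys from defaults.

    Each top-level key must be a registry name; the value is either a bare
    number (base-value override, range collapsed onto it for overrides that
    escape the default bracket) or a mapping with any of
    ``base``/``low``/``high``/``family``/``units``.  Unknown keys are
    rejected.  A ``.csv`` path is read as a full parameter table.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return _validate_registry(ParameterSet.from_csv(path))
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path}: top level must be a mapping of parameter names")
    defaults = default_parameters()
    known = set(defaults.names)
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown parameter(s) in config: {sorted(unknown)}")
    missing = known - set(raw)
    if missing:
        logger.info(
            "config %s: %d parameter(s) taken from defaults", path, len(missing)
        )
    out = []
    for p in defaults:
        if p.name not in raw:
            out.append(p)
            continue
        spec = raw[p.name]
        if isinstance(spec, (int, float)):
            v = float(spec)
            try:
                out.append(
                    replace(p, base=v, low=min(p.low, v), high=max(p.high, v))
                )
            except ParameterError as exc:
                raise ConfigError(str(exc)) from exc
            continue
        if not isinstance(spec, Mapping):
            raise ConfigError(f"{p.name}: expected a number or mapping")
        bad = set(spec) - {"base", "low", "high", "family", "units", "applies_to"}
        if bad:
            raise ConfigError(f"{p.name}: unknown field(s) {sorted(bad)}")
        try:
            out.append(replace(p, **{k: v for k, v in spec.items()}))
        except ParameterError as exc:
            raise ConfigError(str(exc)) from exc
    return _validate_registry(ParameterSet(out))


def write_parameters(ps: ParameterSet, path: str | Path) -> None:
    """Write a full configuration that :func:`load_parameters` round-trips."""
    doc = {
        p.name: {
            "base": p.base,
            "low": p.low,
            "high": p.high,
            "family": p.family,
            "units": p.units,
            "applies_to": p.applies_to,
        }
        for p in ps
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def sample_parameters(ps: ParameterSet, rng: np.random.Generator) -> ParameterSet:
    """One independent PSA draw of every ranged parameter.

    Fixed entries are returned unchanged.  Draws are kept in their physical
    domain (beta in [0, 1], gamma >= 0); identical generator state yields an
    identical draw.
    """
    overrides: dict[str, float] = {}
    for p in ps:
        if p.is_fixed:
            continue
        spec = fit_distribution(p)
        overrides[p.name] = float(spec.sample(rng))
    return ps.with_values(**overrides)
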