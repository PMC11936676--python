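"""Synthetic data generators for the host-parasitoid thermal-ecology pipeline.

Three generators emulate the statistical structure of the field experiments:

* acute heat-shock survival trials, where survival probability declines
  logistically with shock temperature (used to fit LT50 curves);
* paired control/gradient runs on a linear thermal gradient bar, where the
  implied preferred temperature is a truncated normal on the bar range;
* emergence records from leaves held under daytime-maximum temperature
  treatments, where days-to-emergence follow a degree-day model with a
  host/parasitoid difference in thermal sensitivity.

All generators are pure functions of (design, seed): the seed lives in the
design and the same design always yields identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .records import EmergenceRecord, GradientTrial, HeatShockRecord

__all__ = [
    "HeatShockDesign",
    "GradientDesign",
    "EmergenceDesign",
    "DesignError",
    "simulate_heat_shock",
    "simulate_gradient_trials",
    "simulate_emergence",
    "effective_rearing_temperature",
]

#: hours of light per day in the rearing photoperiod (14:10 L:D)
DAY_HOURS = 14.0
NIGHT_HOURS = 10.0
NIGHT_TEMPERATURE = 10.0  # deg C, constant across treatments


class DesignError(ValueError):
    """A generator design violates one of its invariants."""


@dataclass(frozen=True)
class HeatShockDesign:
    """Design of an acute heat-shock survival trial.

    Survival probability at shock temperature T is
    ``expit(b0 + b*T)`` with ``b = true_slope`` (logit / deg C, negative)
    and ``b0 = -true_slope * true_lt50`` so that survival is exactly 0.5
    at ``true_lt50``.
    """

    shock_temperatures: Sequence[float] = (34.0, 36.0, 38.0, 40.0, 42.0, 44.0)
    n_per_temperature: int = 8
    true_lt50: float = 37.4
    true_slope: float = -0.25
    species: str = "parasitoid"
    seed: int = 0

    def __post_init__(self) -> None:
        temps = np.asarray(self.shock_temperatures, dtype=float)
        if temps.size == 0 or np.any(np.diff(temps) <= 0):
            raise DesignError("shock_temperatures must be strictly increasing")
        if self.n_per_temperature < 1:
            raise DesignError("n_per_temperature must be >= 1")
        if not self.true_slope < 0:
            raise DesignError("true_slope must be negative")


@dataclass(frozen=True)
class GradientDesign:
    """Design of paired control/gradient runs on a thermal gradient bar.

    The bar spans ``bar_cold_end``..``bar_hot_end`` deg C with
    ``n_positions`` equally spaced labelled marks. Position labels increase
    toward the cold end (mark 1 = hot end) unless ``cold_end_first``.
    """

    n_individuals: int = 135
    tpref_mean: float = 20.1
    tpref_sd: float = 4.5
    rearing_temperatures: Sequence[float] = (15.0, 20.0, 25.0, 30.0, 35.0)
    bar_cold_end: float = 12.5
    bar_hot_end: float = 44.5
    n_positions: int = 6
    cold_end_first: bool = False
    continuous_positions: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.bar_cold_end < self.bar_hot_end:
            raise DesignError("bar_cold_end must be below bar_hot_end")
        if not self.tpref_sd > 0:
            raise DesignError("tpref_sd must be positive")
        if self.n_positions < 2:
            raise DesignError("n_positions must be >= 2")
        if not (self.bar_cold_end <= self.tpref_mean <= self.bar_hot_end):
            raise DesignError(
                "tpref_mean must lie within the bar range "
                f"[{self.bar_cold_end}, {self.bar_hot_end}]"
            )
        if self.n_individuals < 1:
            raise DesignError("n_individuals must be >= 1")


@dataclass(frozen=True)
class DegreeDayParams:
    """Degree-day development parameters for one insect type.

    ``days = thermal_constant / (T_eff - base_temperature) + noise`` where
    T_eff is the photoperiod-weighted mean of the square-wave rearing regime.
    """

    thermal_constant: float  # degree-days above base
    base_temperature: float  # deg C
    noise_sd: float = 4.6  # days
    emergence_probability: float = 0.5

    def __post_init__(self) -> None:
        if not self.thermal_constant > 0:
            raise DesignError("thermal_constant must be positive")
        if self.noise_sd < 0:
            raise DesignError("noise_sd must be non-negative")
        if not 0.0 <= self.emergence_probability <= 1.0:
            raise DesignError("emergence_probability must be in [0, 1]")


# Defaults make the host and parasitoid mean-emergence curves cross between
# 15 and 35 deg C daytime maxima: the parasitoid has the higher base
# temperature (more cold-limited, so much slower at 15) but the smaller
# thermal constant, so the curves meet near the 25-30 deg C treatments and
# the parasitoid emerges first at 35.
HOST_DEFAULTS = DegreeDayParams(
    thermal_constant=400.0, base_temperature=2.0, noise_sd=4.6,
    emergence_probability=0.143,
)
PARASITOID_DEFAULTS = DegreeDayParams(
    thermal_constant=270.0, base_temperature=8.0, noise_sd=4.6,
    emergence_probability=0.36,
)


@dataclass(frozen=True)
class EmergenceDesign:
    """Design of the leaf-incubation emergence experiment.

    Each of ``n_leaves_per_temperature`` leaves per daytime-maximum
    treatment yields a host (moth) emergence, a parasitoid emergence, or
    nothing, with the per-type emergence probabilities; the two
    probabilities must sum to at most 1 (a leaf holds one pupa).
    """

    rearing_temperatures: Sequence[float] = (15.0, 20.0, 25.0, 30.0, 35.0)
    n_leaves_per_temperature: int = 150
    host: DegreeDayParams = field(default_factory=lambda: HOST_DEFAULTS)
    parasitoid: DegreeDayParams = field(default_factory=lambda: PARASITOID_DEFAULTS)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_leaves_per_temperature < 0:
            raise DesignError("n_leaves_per_temperature must be >= 0")
        if self.host.emergence_probability + self.parasitoid.emergence_probability > 1.0 + 1e-12:
            raise DesignError("per-type emergence probabilities must sum to <= 1")
        for params in (self.host, self.parasitoid):
            for t_day in self.rearing_temperatures:
                if effective_rearing_temperature(t_day) <= params.base_temperature:
                    raise DesignError(
                        f"effective temperature for daytime max {t_day} deg C does not "
                        f"exceed base temperature {params.base_temperature} deg C"
                    )


def effective_rearing_temperature(t_day: float) -> float:
    """Photoperiod-weighted mean of the square-wave rearing regime.

    The incubators held ``t_day`` for the 14 h photophase and 10 deg C for
    the 10 h scotophase; the degree-day model uses the 24 h mean.
    """
    return (DAY_HOURS * t_day + NIGHT_HOURS * NIGHT_TEMPERATURE) / (DAY_HOURS + NIGHT_HOURS)


def simulate_heat_shock(design: HeatShockDesign) -> list[HeatShockRecord]:
    """Draw Bernoulli survival outcomes from the logistic dose-response."""
    rng = np.random.default_rng(design.seed)
    beta = design.true_slope
    beta0 = -design.true_slope * design.true_lt50
    records: list[HeatShockRecord] = []
    idx = 0
    for temp in design.shock_temperatures:
        p_survive = float(1.0 / (1.0 + np.exp(-(beta0 + beta * temp))))
        outcomes = rng.random(design.n_per_temperature) < p_survive
        for outcome in outcomes:
            records.append(
                HeatShockRecord(
                    individual_id=f"{design.species}-{idx:04d}",
                    species=design.species,
                    shock_temperature=float(temp),
                    survived=int(outcome),
                )
            )
            idx += 1
    return records


def _bar_mark_temperatures(design: GradientDesign) -> np.ndarray:
    """Temperatures at the labelled marks, in label order 1..n_positions."""
    frac = np.arange(design.n_positions) / (design.n_positions - 1)
    if design.cold_end_first:
        return design.bar_cold_end + frac * (design.bar_hot_end - design.bar_cold_end)
    return design.bar_hot_end - frac * (design.bar_hot_end - design.bar_cold_end)


def simulate_gradient_trials(design: GradientDesign) -> list[GradientTrial]:
    """Draw paired control (gradient off) and gradient (gradient on) positions.

    Control positions are uniform over the marks. Gradient positions are
    drawn so the implied temperature is Normal(tpref_mean, tpref_sd)
    truncated to the bar range, then snapped to the nearest mark (insects
    cannot leave the bar, hence truncation rather than censoring).
    """
    rng = np.random.default_rng(design.seed)
    n = design.n_individuals
    lo = (design.bar_cold_end - design.tpref_mean) / design.tpref_sd
    hi = (design.bar_hot_end - design.tpref_mean) / design.tpref_sd
    chosen_temps = stats.truncnorm.rvs(
        lo, hi, loc=design.tpref_mean, scale=design.tpref_sd,
        size=n, random_state=rng,
    )
    mark_temps = _bar_mark_temperatures(design)
    span = design.bar_hot_end - design.bar_cold_end

    if design.continuous_positions:
        # fractional position along the bar on the 1..n_positions axis
        if design.cold_end_first:
            frac = (chosen_temps - design.bar_cold_end) / span
        else:
            frac = (design.bar_hot_end - chosen_temps) / span
        gradient_positions = 1.0 + frac * (design.n_positions - 1)
        control_positions = 1.0 + rng.random(n) * (design.n_positions - 1)
    else:
        gradient_positions = (
            np.argmin(np.abs(chosen_temps[:, None] - mark_temps[None, :]), axis=1) + 1
        ).astype(float)
        control_positions = rng.integers(1, design.n_positions + 1, size=n).astype(float)

    rearing = np.asarray(design.rearing_temperatures, dtype=float)
    trials = [
        GradientTrial(
            individual_id=f"wasp-{i:04d}",
            rearing_temperature=float(rearing[i % rearing.size]),
            position_control=float(control_positions[i]),
            position_gradient=float(gradient_positions[i]),
        )
        for i in range(n)
    ]
    return trials


def simulate_emergence(design: EmergenceDesign) -> list[EmergenceRecord]:
    """Draw degree-day emergence times for leaves under each treatment.

    Per leaf, a single trinomial draw decides host emergence, parasitoid
    emergence, or no emergence. Days to emergence are
    ``DD / (T_eff - T0) + Normal(0, noise_sd)`` floored at 1 day.
    """
    rng = np.random.default_rng(design.seed)
    records: list[EmergenceRecord] = []
    p_host = design.host.emergence_probability
    p_para = design.parasitoid.emergence_probability
    for t_day in design.rearing_temperatures:
        t_eff = effective_rearing_temperature(t_day)
        u = rng.random(design.n_leaves_per_temperature)
        for ui in u:
            if ui < p_host:
                params, insect_type = design.host, "host"
            elif ui < p_host + p_para:
                params, insect_type = design.parasitoid, "parasitoid"
            else:
                continue
            days = params.thermal_constant / (t_eff - params.base_temperature)
            if params.noise_sd > 0:
                days += rng.normal(0.0, params.noise_sd)
            records.append(
                EmergenceRecord(
                    insect_type=insect_type,
                    rearing_temperature=float(t_day),
                    days_to_emergence=float(max(days, 1.0)),
                )
            )
    return records
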