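"""Thermal risk and window-of-opportunity metrics coupling physiology to climate.

Three hour-based metrics connect the measured thermal traits to simulated
microhabitat temperatures:

* thermal risk (host): hours per day with sun-leaf temperature strictly
  above the host LT50;
* thermal risk (parasitoid): hours per day with air temperature strictly
  above the parasitoid LT50;
* window of opportunity (parasitoid): hours per day with air temperature
  inside the closed band T_PREF +/- 1 sd.

Daily values are the mean over the simulated mid-month days (May-July by
default). Safety margins are LT50 minus the maximum of the same series
used for the risk counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .leaf_energy import LeafParameters, leaf_series
from .microclimate import MicroclimateSeries, ScenarioSpec, SiteSpec, generate_microclimate

__all__ = [
    "RiskReport",
    "thermal_risk",
    "opportunity_window",
    "safety_margin",
    "scenario_report",
    "INTERACTION_MONTHS",
]

#: months when adult parasitoids and leaf-miner larvae interact at the site
INTERACTION_MONTHS = (5, 6, 7)


@dataclass(frozen=True)
class RiskReport:
    """Per-scenario risk metrics and the maxima they derive from."""

    scenario: str
    host_thermal_risk: float  # hours/day leaf temperature > host LT50
    parasitoid_thermal_risk: float  # hours/day air temperature > parasitoid LT50
    opportunity_window: float  # hours/day air temperature within T_PREF +/- sd
    host_safety_margin: float  # deg C, host LT50 - max leaf temperature
    parasitoid_safety_margin: float  # deg C, parasitoid LT50 - max air temperature
    max_leaf_temperature: float  # deg C
    max_air_temperature: float  # deg C
    months: tuple[int, ...] = INTERACTION_MONTHS


def _per_day(count: int, n_hours: int) -> float:
    n_days = n_hours // 24 if n_hours % 24 == 0 and n_hours >= 24 else 1
    return count / n_days


def thermal_risk(temperatures: Sequence[float], lt50: float) -> float:
    """Hours with temperature strictly above LT50, averaged per 24 h day
    when whole days are supplied."""
    t = np.asarray(temperatures, dtype=float)
    if t.size == 0:
        raise ValueError("temperature series is empty")
    return float(_per_day(int((t > lt50).sum()), t.size))


def opportunity_window(
    air_temperatures: Sequence[float], tpref_mean: float, tpref_sd: float
) -> float:
    """Hours with air temperature inside the closed band
    [tpref_mean - sd, tpref_mean + sd], averaged per day."""
    if tpref_sd < 0:
        raise ValueError("tpref_sd must be non-negative")
    t = np.asarray(air_temperatures, dtype=float)
    if t.size == 0:
        raise ValueError("temperature series is empty")
    # closed interval; the 1e-9 guard absorbs float noise in mean +/- sd
    inside = (t >= tpref_mean - tpref_sd - 1e-9) & (t <= tpref_mean + tpref_sd + 1e-9)
    return float(_per_day(int(inside.sum()), t.size))


def safety_margin(lt50: float, max_temperature: float) -> float:
    """Thermal safety margin: upper thermal limit minus maximum ambient
    temperature (negative when the maximum exceeds the limit)."""
    return float(lt50 - max_temperature)


def scenario_report(
    site: SiteSpec,
    scenario: ScenarioSpec,
    leaf_params_sun: LeafParameters,
    lt50_host: float,
    lt50_parasitoid: float,
    tpref_mean: float,
    tpref_sd: float,
    months: Sequence[int] = INTERACTION_MONTHS,
) -> RiskReport:
    """Compute all risk metrics for one warming scenario.

    Host exposure is the sun-leaf temperature; adult parasitoid exposure
    is air temperature at the reference height in the sun. Hourly series
    for the mid-days of ``months`` are pooled, and hour counts averaged
    across those days.
    """
    leaf_temps: list[np.ndarray] = []
    air_temps: list[np.ndarray] = []
    for month in months:
        micro: MicroclimateSeries = generate_microclimate(site, month, scenario)
        leaf = leaf_series(micro, leaf_params_sun, elevation=site.elevation)
        leaf_temps.append(leaf.leaf_temperature)
        air_temps.append(micro.air_temperature)
    leaf_all = np.concatenate(leaf_temps)
    air_all = np.concatenate(air_temps)
    return RiskReport(
        scenario=scenario.name,
        host_thermal_risk=thermal_risk(leaf_all, lt50_host),
        parasitoid_thermal_risk=thermal_risk(air_all, lt50_parasitoid),
        opportunity_window=opportunity_window(air_all, tpref_mean, tpref_sd),
        host_safety_margin=safety_margin(lt50_host, float(leaf_all.max())),
        parasitoid_safety_margin=safety_margin(lt50_parasitoid, float(air_all.max())),
        max_leaf_temperature=float(leaf_all.max()),
        max_air_temperature=float(air_all.max()),
        months=tuple(months),
    )
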