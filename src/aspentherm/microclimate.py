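"""Hourly microclimate generator from monthly climate normals.

A desk-scale stand-in for gridded microclimate models: for the middle day
of a month it produces 24 hourly values of air temperature, direct and
diffuse solar radiation, wind, relative humidity and sky temperature at a
reference height, from user-supplied monthly normals plus an additive
warming scenario.

Components:

* solar geometry — Cooper declination and hour-angle zenith, local solar
  time (no longitude or daylight-saving correction);
* diurnal air temperature — Parton-Logan interpolation: daytime sine from
  t_min at sunrise to t_max at solar noon + lag, nocturnal exponential
  decay back to t_min at the next sunrise (periodic day);
* shortwave — Campbell-Norman clear-sky beam transmittance with a simple
  Liu-Jordan-style diffuse fraction, scaled by cloud fraction;
* longwave sky temperature — Brutsaert clear-sky emissivity with a
  quadratic cloud correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "MonthlyNormals",
    "SiteSpec",
    "ScenarioSpec",
    "MicroclimateSeries",
    "MicroclimateError",
    "solar_position",
    "day_length",
    "hourly_air_temperature",
    "generate_microclimate",
    "mid_month_day_of_year",
]

SOLAR_CONSTANT = 1361.0  # W m-2
STEFAN_BOLTZMANN = 5.670374419e-8  # W m-2 K-4
#: mid-month day-of-year per month (non-leap year, 15th)
_MID_DAYS = [15, 46, 74, 105, 135, 166, 196, 227, 258, 288, 319, 349]


class MicroclimateError(ValueError):
    """Invalid site, scenario or month input."""


@dataclass(frozen=True)
class MonthlyNormals:
    """Long-term monthly means driving one simulated day."""

    t_min: float  # deg C, mean daily minimum
    t_max: float  # deg C, mean daily maximum
    wind_mean: float = 2.0  # m s-1 at reference height
    rh_mean: float = 60.0  # %
    cloud_fraction: float = 0.3  # 0-1

    def __post_init__(self) -> None:
        if self.t_min > self.t_max:
            raise MicroclimateError("t_min must not exceed t_max")
        if not 0.0 <= self.cloud_fraction <= 1.0:
            raise MicroclimateError("cloud_fraction must be in [0, 1]")
        if not 0.0 < self.rh_mean <= 100.0:
            raise MicroclimateError("rh_mean must be in (0, 100]")


@dataclass(frozen=True)
class SiteSpec:
    """Location, reference height and monthly normals for a site."""

    latitude: float  # degrees, +N
    longitude: float  # degrees, +E
    elevation: float  # m
    normals: Mapping[int, MonthlyNormals]  # keyed by month 1-12
    reference_height: float = 1.2  # m

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise MicroclimateError("latitude must be in [-90, 90]")
        for m in self.normals:
            if not 1 <= int(m) <= 12:
                raise MicroclimateError(f"month key {m} outside 1-12")


@dataclass(frozen=True)
class ScenarioSpec:
    """Additive air-temperature warming, uniform or per-month (deg C)."""

    name: str = "current"
    delta: float = 0.0
    monthly_deltas: Mapping[int, float] = field(default_factory=dict)

    def delta_for(self, month: int) -> float:
        d = float(self.monthly_deltas.get(month, self.delta))
        if not math.isfinite(d):
            raise MicroclimateError(f"scenario delta for month {month} is not finite")
        return d


@dataclass(frozen=True)
class MicroclimateSeries:
    """24 hourly rows of abiotic forcings for one simulated day."""

    month: int
    day_of_year: int
    scenario: str
    hour: np.ndarray  # 0..23, local solar time
    air_temperature: np.ndarray  # deg C
    direct_solar: np.ndarray  # W m-2, horizontal plane
    diffuse_solar: np.ndarray  # W m-2
    wind: np.ndarray  # m s-1
    relative_humidity: np.ndarray  # %
    sky_temperature: np.ndarray  # deg C
    zenith_angle: np.ndarray  # degrees

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "hour": self.hour,
                "air_temperature": self.air_temperature,
                "direct_solar": self.direct_solar,
                "diffuse_solar": self.diffuse_solar,
                "wind": self.wind,
                "relative_humidity": self.relative_humidity,
                "sky_temperature": self.sky_temperature,
                "zenith_angle": self.zenith_angle,
            }
        )


def mid_month_day_of_year(month: int) -> int:
    """Day-of-year of the month's 15th (the simulated representative day)."""
    if not 1 <= month <= 12:
        raise MicroclimateError(f"month {month} outside 1-12")
    return _MID_DAYS[month - 1]


def solar_declination(day_of_year: int) -> float:
    """Cooper's declination (degrees)."""
    return 23.45 * math.sin(2.0 * math.pi * (284 + day_of_year) / 365.0)


def solar_position(latitude: float, day_of_year: int, hour: float) -> float:
    """Solar zenith angle (degrees) at local solar time; noon is hour 12."""
    decl = math.radians(solar_declination(day_of_year))
    lat = math.radians(latitude)
    hour_angle = math.radians(15.0 * (hour - 12.0))
    cos_z = math.sin(lat) * math.sin(decl) + math.cos(lat) * math.cos(decl) * math.cos(hour_angle)
    return math.degrees(math.acos(max(-1.0, min(1.0, cos_z))))


def day_length(latitude: float, day_of_year: int) -> tuple[float, float, float]:
    """(sunrise hour, sunset hour, day length in hours), clamped for polar
    day (24 h) and polar night (0 h)."""
    decl = math.radians(solar_declination(day_of_year))
    lat = math.radians(latitude)
    x = -math.tan(lat) * math.tan(decl)
    if x <= -1.0:  # polar day
        return 0.0, 24.0, 24.0
    if x >= 1.0:  # polar night
        return 12.0, 12.0, 0.0
    half = math.degrees(math.acos(x)) / 15.0
    return 12.0 - half, 12.0 + half, 2.0 * half


def hourly_air_temperature(
    t_min: float,
    t_max: float,
    hour: float,
    sunrise_hour: float,
    sunset_hour: float,
    peak_lag: float = 1.5,
    night_coeff: float = 2.2,
) -> float:
    """Parton-Logan diurnal air temperature at a (possibly fractional) hour.

    Daytime: ``t_min + (t_max - t_min) * sin(pi (t - sunrise) / (D + 2 lag))``
    so the curve starts at t_min at sunrise and peaks at t_max at solar
    noon + lag. Night: exponential decay from the sunset temperature,
    renormalised to reach exactly t_min at the next sunrise, which makes
    the curve continuous at both junctions.
    """
    if t_min > t_max:
        raise MicroclimateError("t_min must not exceed t_max")
    if t_min == t_max:
        return float(t_min)
    daylength = sunset_hour - sunrise_hour
    if daylength <= 0:  # polar night: no solar heating cycle
        return float(t_min)
    amp = t_max - t_min
    h = hour % 24.0
    if sunrise_hour <= h <= sunset_hour:
        phase = math.pi * (h - sunrise_hour) / (daylength + 2.0 * peak_lag)
        return float(t_min + amp * math.sin(phase))
    # nocturnal branch
    t_sunset = t_min + amp * math.sin(math.pi * daylength / (daylength + 2.0 * peak_lag))
    night_length = 24.0 - daylength
    since_sunset = (h - sunset_hour) % 24.0
    x = since_sunset / night_length
    decay = (math.exp(-night_coeff * x) - math.exp(-night_coeff)) / (
        1.0 - math.exp(-night_coeff)
    )
    return float(t_min + (t_sunset - t_min) * decay)


def _saturation_vapor_pressure(t_celsius: float) -> float:
    """Tetens saturation vapour pressure (kPa)."""
    return 0.6108 * math.exp(17.27 * t_celsius / (t_celsius + 237.3))


def _sky_temperature(t_air: float, rh: float, cloud: float) -> float:
    """Effective radiant sky temperature (deg C) from Brutsaert emissivity
    with a (1 + 0.22 c^2) cloud correction."""
    t_k = t_air + 273.15
    ea_hpa = 10.0 * rh / 100.0 * _saturation_vapor_pressure(t_air)  # hPa
    eps_clear = 1.24 * (ea_hpa / t_k) ** (1.0 / 7.0)
    eps = min(1.0, eps_clear * (1.0 + 0.22 * cloud**2))
    return float(t_k * eps**0.25 - 273.15)


def _solar_fluxes(
    zenith_deg: float, day_of_year: int, elevation: float, cloud: float,
    transmittance: float = 0.72,
) -> tuple[float, float]:
    """(direct, diffuse) shortwave on a horizontal plane, W m-2.

    Clear-sky beam uses atmospheric transmittance raised to the
    pressure-corrected optical air mass; diffuse is 30 % of the flux
    scattered out of the beam. Cloud removes beam and converts half of the
    removed beam to additional diffuse.
    """
    if zenith_deg >= 90.0:
        return 0.0, 0.0
    cos_z = math.cos(math.radians(zenith_deg))
    s0 = SOLAR_CONSTANT * (1.0 + 0.033 * math.cos(2.0 * math.pi * day_of_year / 365.0))
    pressure_ratio = math.exp(-elevation / 8200.0)
    airmass = pressure_ratio / max(cos_z, 1e-4)
    tau_m = transmittance**airmass
    beam_clear = s0 * tau_m * cos_z
    diffuse_clear = 0.3 * (1.0 - tau_m) * s0 * cos_z
    direct = beam_clear * (1.0 - cloud)
    diffuse = diffuse_clear + 0.5 * cloud * beam_clear
    return float(direct), float(diffuse)


def generate_microclimate(
    site: SiteSpec,
    month: int,
    scenario: ScenarioSpec | None = None,
) -> MicroclimateSeries:
    """Hourly forcings for the mid-day of ``month`` under ``scenario``.

    The scenario delta is added to the interpolated air temperature; sky
    temperature is computed from the warmed air so longwave forcing stays
    physically consistent with the scenario.
    """
    scenario = scenario or ScenarioSpec()
    normals = site.normals.get(month) or site.normals.get(str(month))  # type: ignore[call-overload]
    if normals is None:
        raise MicroclimateError(f"no monthly normals supplied for month {month}")
    doy = mid_month_day_of_year(month)
    sunrise, sunset, _ = day_length(site.latitude, doy)
    delta = scenario.delta_for(month)

    hours = np.arange(24, dtype=float)
    zen = np.array([solar_position(site.latitude, doy, h) for h in hours])
    t_air = np.array(
        [
            hourly_air_temperature(normals.t_min, normals.t_max, h, sunrise, sunset)
            + delta
            for h in hours
        ]
    )
    solar = np.array(
        [_solar_fluxes(z, doy, site.elevation, normals.cloud_fraction) for z in zen]
    )
    rh = np.full(24, float(normals.rh_mean))
    wind = np.full(24, float(normals.wind_mean))
    t_sky = np.array(
        [_sky_temperature(t, r, normals.cloud_fraction) for t, r in zip(t_air, rh)]
    )
    return MicroclimateSeries(
        month=month,
        day_of_year=doy,
        scenario=scenario.name,
        hour=hours,
        air_temperature=t_air,
        direct_solar=solar[:, 0],
        diffuse_solar=solar[:, 1],
        wind=wind,
        relative_humidity=rh,
        sky_temperature=t_sky,
        zenith_angle=zen,
    )
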