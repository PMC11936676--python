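"""Steady-state leaf energy budget: radiative-convective-latent balance.

Solves, hour by hour, for the leaf temperature at which absorbed radiation
balances emitted thermal radiation, sensible heat exchange and latent heat
of transpiration (the classic flat-leaf budget of biophysical ecology):

    R_abs = 2 eps sigma T_leaf^4 + 2 c_p g_H (T_leaf - T_air)
            + lambda g_v (e_s(T_leaf) - e_a) / P

with R_abs = alpha_s * shortwave (shade: diffuse only) + eps sigma
(T_sky^4 + T_ground^4). Both leaf faces exchange sensible heat and
longwave; one (hypostomatous) face transpires. The root is found by a
safeguarded Newton iteration with bisection fallback inside the physical
bracket [T_air - 20, T_air + 30].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .microclimate import STEFAN_BOLTZMANN, MicroclimateSeries

__all__ = [
    "LeafParameters",
    "EnergyFluxes",
    "LeafTemperatureSeries",
    "LeafEnergyError",
    "boundary_layer_conductance",
    "solve_leaf_temperature",
    "leaf_series",
    "ValidationReport",
    "validate_against_observations",
]

CP_MOLAR = 29.3  # J mol-1 K-1, molar heat capacity of air
LAMBDA_MOLAR = 44000.0  # J mol-1, molar latent heat of vaporisation
ATM_PRESSURE = 101.3  # kPa at sea level


class LeafEnergyError(ValueError):
    """The leaf energy balance cannot be solved for the given inputs."""


@dataclass(frozen=True)
class LeafParameters:
    """Optical, geometric and stomatal properties of the leaf."""

    shortwave_absorptance: float = 0.5  # fraction of incident shortwave absorbed
    emissivity: float = 0.97  # thermal
    characteristic_dimension: float = 0.05  # m, ~0.7 x leaf width
    stomatal_conductance: float = 0.2  # mol m-2 s-1, one face
    exposure: str = "sun"  # "sun" or "shade"
    free_convection_floor: float = 0.05  # mol m-2 s-1, minimum boundary-layer conductance

    def __post_init__(self) -> None:
        if not 0.0 <= self.shortwave_absorptance <= 1.0:
            raise LeafEnergyError("shortwave_absorptance must be in [0, 1]")
        if not 0.0 <= self.emissivity <= 1.0:
            raise LeafEnergyError("emissivity must be in [0, 1]")
        if not self.characteristic_dimension > 0:
            raise LeafEnergyError("characteristic_dimension must be positive")
        if self.stomatal_conductance < 0:
            raise LeafEnergyError("stomatal_conductance must be non-negative")
        if self.exposure not in ("sun", "shade"):
            raise LeafEnergyError("exposure must be 'sun' or 'shade'")


@dataclass(frozen=True)
class EnergyFluxes:
    """Leaf-area-normalised energy fluxes at the solution (W m-2)."""

    absorbed_radiation: float
    emitted_longwave: float
    sensible: float
    latent: float
    residual: float


@dataclass(frozen=True)
class LeafTemperatureSeries:
    """Solved leaf temperatures paired with their microclimate forcing."""

    microclimate: MicroclimateSeries
    leaf_temperature: np.ndarray  # deg C
    fluxes: tuple[EnergyFluxes, ...]
    exposure: str

    @property
    def excess(self) -> np.ndarray:
        """Leaf-minus-air temperature, deg C."""
        return self.leaf_temperature - self.microclimate.air_temperature

    def to_dataframe(self):
        df = self.microclimate.to_dataframe()
        df["leaf_temperature"] = self.leaf_temperature
        df["excess"] = self.excess
        df["flux_absorbed"] = [f.absorbed_radiation for f in self.fluxes]
        df["flux_longwave_out"] = [f.emitted_longwave for f in self.fluxes]
        df["flux_sensible"] = [f.sensible for f in self.fluxes]
        df["flux_latent"] = [f.latent for f in self.fluxes]
        df["flux_residual"] = [f.residual for f in self.fluxes]
        return df


def boundary_layer_conductance(
    wind: float, d: float, floor: float = 0.05
) -> float:
    """Forced-convection boundary-layer conductance to heat, one face
    (mol m-2 s-1): ``1.4 * 0.135 * sqrt(u/d)``, floored at a
    free-convection minimum for still air."""
    if wind < 0 or d <= 0:
        raise LeafEnergyError("wind must be >= 0 and d > 0")
    return max(1.4 * 0.135 * math.sqrt(wind / d), floor)


def _es_kpa(t_celsius: float) -> float:
    return 0.6108 * math.exp(17.27 * t_celsius / (t_celsius + 237.3))


def _pressure_kpa(elevation: float) -> float:
    return ATM_PRESSURE * math.exp(-elevation / 8200.0)


def energy_balance_residual(
    t_leaf: float,
    *,
    t_air: float,
    shortwave: float,
    t_sky: float,
    t_ground: float,
    wind: float,
    rh: float,
    params: LeafParameters,
    pressure: float = ATM_PRESSURE,
) -> tuple[float, EnergyFluxes]:
    """Net energy input at leaf temperature ``t_leaf``; zero at steady state."""
    eps = params.emissivity
    sigma = STEFAN_BOLTZMANN
    r_abs = (
        params.shortwave_absorptance * shortwave
        + eps * sigma * ((t_sky + 273.15) ** 4 + (t_ground + 273.15) ** 4)
    )
    l_out = 2.0 * eps * sigma * (t_leaf + 273.15) ** 4
    g_bl = boundary_layer_conductance(wind, params.characteristic_dimension,
                                      params.free_convection_floor)
    sensible = 2.0 * CP_MOLAR * g_bl * (t_leaf - t_air)
    g_s = params.stomatal_conductance
    if g_s > 0:
        g_v = g_s * g_bl / (g_s + g_bl)  # stomata and boundary layer in series
        e_a = rh / 100.0 * _es_kpa(t_air)
        vpd_frac = max(_es_kpa(t_leaf) - e_a, 0.0) / pressure
        latent = LAMBDA_MOLAR * g_v * vpd_frac
    else:
        latent = 0.0
    residual = r_abs - l_out - sensible - latent
    fluxes = EnergyFluxes(
        absorbed_radiation=float(r_abs),
        emitted_longwave=float(l_out),
        sensible=float(sensible),
        latent=float(latent),
        residual=float(residual),
    )
    return float(residual), fluxes


def solve_leaf_temperature(
    *,
    t_air: float,
    direct_solar: float,
    diffuse_solar: float,
    t_sky: float,
    wind: float,
    rh: float,
    params: LeafParameters,
    t_ground: float | None = None,
    elevation: float = 0.0,
    tol: float = 0.01,
    max_iter: int = 200,
) -> tuple[float, EnergyFluxes]:
    """Solve the hourly energy balance for leaf temperature.

    Shade leaves absorb diffuse shortwave only. Ground temperature for the
    upward longwave stream defaults to air temperature (no soil model).
    Returns the root with |residual| < ``tol`` W m-2.
    """
    if t_ground is None:
        t_ground = t_air
    shortwave = diffuse_solar if params.exposure == "shade" else direct_solar + diffuse_solar
    pressure = _pressure_kpa(elevation)

    def f(t: float) -> tuple[float, EnergyFluxes]:
        return energy_balance_residual(
            t, t_air=t_air, shortwave=shortwave, t_sky=t_sky, t_ground=t_ground,
            wind=wind, rh=rh, params=params, pressure=pressure,
        )

    lo, hi = t_air - 20.0, t_air + 30.0
    f_lo, _ = f(lo)
    f_hi, _ = f(hi)
    if f_lo * f_hi > 0:
        raise LeafEnergyError(
            "energy balance has no sign change in bracket "
            f"[{lo:g}, {hi:g}] deg C: residuals {f_lo:.3g} and {f_hi:.3g} W m-2"
        )
    # safeguarded Newton: numerical derivative, bisection whenever the
    # Newton step leaves the current bracket
    t = 0.5 * (lo + hi)
    for _ in range(max_iter):
        res, fluxes = f(t)
        if abs(res) < tol:
            return float(t), fluxes
        if res > 0:  # leaf gains energy below the root (f decreasing in T)
            if f_lo > 0:
                lo = t
            else:
                hi = t
        else:
            if f_lo > 0:
                hi = t
            else:
                lo = t
        h = 1e-4
        dres = (f(t + h)[0] - f(t - h)[0]) / (2 * h)
        if dres != 0:
            t_new = t - res / dres
        else:
            t_new = 0.5 * (lo + hi)
        if not (lo < t_new < hi):
            t_new = 0.5 * (lo + hi)
        t = t_new
    raise LeafEnergyError(
        f"leaf-temperature solver did not reach |residual| < {tol} W m-2 "
        f"in {max_iter} iterations"
    )


def leaf_series(
    series: MicroclimateSeries,
    params: LeafParameters,
    elevation: float = 0.0,
) -> LeafTemperatureSeries:
    """Solve the energy balance for every hour of a microclimate day."""
    temps = np.empty(series.hour.size)
    fluxes: list[EnergyFluxes] = []
    for i in range(series.hour.size):
        try:
            t, fl = solve_leaf_temperature(
                t_air=float(series.air_temperature[i]),
                direct_solar=float(series.direct_solar[i]),
                diffuse_solar=float(series.diffuse_solar[i]),
                t_sky=float(series.sky_temperature[i]),
                wind=float(series.wind[i]),
                rh=float(series.relative_humidity[i]),
                params=params,
                elevation=elevation,
            )
        except LeafEnergyError as exc:
            raise LeafEnergyError(f"hour {int(series.hour[i])}: {exc}") from exc
        temps[i] = t
        fluxes.append(fl)
    return LeafTemperatureSeries(
        microclimate=series, leaf_temperature=temps, fluxes=tuple(fluxes),
        exposure=params.exposure,
    )


@dataclass(frozen=True)
class ValidationReport:
    """Comparison of predicted leaf temperature excess against field
    observations, with the two accuracy criteria: the model error must be
    smaller than (i) the observed sun-shade contrast and (ii) the thermal
    safety margin."""

    mean_error: float  # mean(predicted) - mean(observed sun), deg C
    observed_sun_mean: float
    observed_shade_mean: float
    sun_shade_difference: float
    safety_margin: float  # LT50 - max ambient, deg C
    error_below_sun_shade: bool
    error_below_safety_margin: bool

    @property
    def passed(self) -> bool:
        return self.error_below_sun_shade and self.error_below_safety_margin


def validate_against_observations(
    predicted_excess: Sequence[float],
    observed_excess_sun: Sequence[float],
    observed_excess_shade: Sequence[float],
    lt50: float,
    max_ambient: float,
) -> ValidationReport:
    """Score predicted sun-leaf excess against observed sun and shade excess."""
    pred = np.asarray(predicted_excess, dtype=float)
    obs_sun = np.asarray(observed_excess_sun, dtype=float)
    obs_shade = np.asarray(observed_excess_shade, dtype=float)
    if pred.size == 0 or obs_sun.size == 0 or obs_shade.size == 0:
        raise LeafEnergyError("observation and prediction sets must be non-empty")
    error = float(pred.mean() - obs_sun.mean())
    diff = float(obs_sun.mean() - obs_shade.mean())
    margin = float(lt50 - max_ambient)
    return ValidationReport(
        mean_error=error,
        observed_sun_mean=float(obs_sun.mean()),
        observed_shade_mean=float(obs_shade.mean()),
        sun_shade_difference=diff,
        safety_margin=margin,
        error_below_sun_shade=abs(error) < abs(diff),
        error_below_safety_margin=abs(error) < margin,
    )
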