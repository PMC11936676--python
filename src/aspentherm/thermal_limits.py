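"""Binomial-logistic dose-response of survival on heat-shock temperature.

Fits survival ~ shock temperature by maximum likelihood (iteratively
reweighted least squares), extracts the median lethal temperature
LT50 = -b0/b with a delta-method standard error, and compares LT50
between species. Complete separation is detected and reported rather
than returned as a silently huge slope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from scipy.special import expit

from .records import HeatShockRecord

__all__ = [
    "DoseResponseFit",
    "FitError",
    "SeparationError",
    "fit_logistic_survival",
    "lt50",
    "compare_lt50",
    "death_fractions",
]

_SLOPE_TOL = 1e-6  # below this |slope| the median dose is unstable


class FitError(ValueError):
    """The dose-response fit cannot be computed or has not converged."""


class SeparationError(FitError):
    """Complete separation: all survivors' temperatures lie strictly on one
    side of all deaths' temperatures, so the MLE slope is infinite."""


@dataclass(frozen=True)
class DoseResponseFit:
    """A fitted logistic (or probit) survival-temperature curve."""

    intercept: float  # logit units
    slope: float  # logit units per deg C
    covariance: np.ndarray  # 2x2, order (intercept, slope)
    lt50: float  # deg C
    lt50_se: float  # deg C
    n: int
    deviance: float
    converged: bool
    link: str = "logit"

    def predict(self, temperature: np.ndarray | float) -> np.ndarray | float:
        """Survival probability at the given shock temperature(s)."""
        eta = self.intercept + self.slope * np.asarray(temperature, dtype=float)
        if self.link == "probit":
            return stats.norm.cdf(eta)
        return expit(eta)


def _design(records: Sequence[HeatShockRecord]) -> tuple[np.ndarray, np.ndarray]:
    temps = np.array([r.shock_temperature for r in records], dtype=float)
    y = np.array([r.survived for r in records], dtype=float)
    return temps, y


def _check_preconditions(temps: np.ndarray, y: np.ndarray) -> None:
    if np.unique(temps).size < 2:
        raise FitError("need at least 2 distinct shock temperatures")
    if np.all(y == 1) or np.all(y == 0):
        raise FitError("single outcome class: both survivors and deaths are required")
    survivors = temps[y == 1]
    deaths = temps[y == 0]
    if survivors.max() < deaths.min() or deaths.max() < survivors.min():
        raise SeparationError(
            "complete separation: survivor and death temperatures do not overlap "
            f"(survivors in [{survivors.min():g}, {survivors.max():g}], "
            f"deaths in [{deaths.min():g}, {deaths.max():g}]); the slope MLE is infinite"
        )


def _deviance(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


def fit_logistic_survival(
    records: Iterable[HeatShockRecord],
    *,
    link: str = "logit",
    tol: float = 1e-10,
    max_iter: int = 100,
    deviance_trace: list[float] | None = None,
) -> DoseResponseFit:
    """Maximum-likelihood dose-response fit via IRLS with step halving.

    Step halving guarantees the deviance is non-increasing across
    iterations; convergence is declared when the relative deviance change
    drops below ``tol``. The covariance is the inverse observed (= expected,
    canonical link) information at the optimum.
    """
    records = list(records)
    temps, y = _design(records)
    _check_preconditions(temps, y)
    if link not in ("logit", "probit"):
        raise FitError(f"unknown link {link!r}")

    X = np.column_stack([np.ones_like(temps), temps])
    beta = np.zeros(2)
    mu = _predict_mu(X, beta, link)
    dev = _deviance(y, mu)
    if deviance_trace is not None:
        deviance_trace.append(dev)
    converged = False
    for _ in range(max_iter):
        W, z = _irls_working(X, y, beta, link)
        XtW = X.T * W
        try:
            beta_new = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError as exc:  # singular weights
            raise FitError("singular information matrix during IRLS") from exc
        # step halving: never let the deviance increase
        step = beta_new - beta
        dev_new = _deviance(y, _predict_mu(X, beta + step, link))
        halvings = 0
        while dev_new > dev + 1e-12 and halvings < 30:
            step /= 2.0
            dev_new = _deviance(y, _predict_mu(X, beta + step, link))
            halvings += 1
        beta = beta + step
        rel_change = abs(dev - dev_new) / (abs(dev) + 0.1)
        dev = dev_new
        if deviance_trace is not None:
            deviance_trace.append(dev)
        if rel_change < tol:
            converged = True
            break

    mu = _predict_mu(X, beta, link)
    W, _ = _irls_working(X, y, beta, link)
    info = (X.T * W) @ X
    covariance = np.linalg.inv(info)

    b0, b1 = float(beta[0]), float(beta[1])
    if abs(b1) > _SLOPE_TOL:
        value, se = _lt50_delta(b0, b1, covariance)
    else:
        value, se = float("nan"), float("nan")
    return DoseResponseFit(
        intercept=b0,
        slope=b1,
        covariance=covariance,
        lt50=value,
        lt50_se=se,
        n=len(records),
        deviance=dev,
        converged=converged,
        link=link,
    )


def _predict_mu(X: np.ndarray, beta: np.ndarray, link: str) -> np.ndarray:
    eta = X @ beta
    if link == "probit":
        return np.clip(stats.norm.cdf(eta), 1e-10, 1 - 1e-10)
    return np.clip(expit(eta), 1e-10, 1 - 1e-10)


def _irls_working(
    X: np.ndarray, y: np.ndarray, beta: np.ndarray, link: str
) -> tuple[np.ndarray, np.ndarray]:
    """IRLS weights and working response at the current coefficients."""
    eta = X @ beta
    if link == "probit":
        mu = np.clip(stats.norm.cdf(eta), 1e-10, 1 - 1e-10)
        dmu = stats.norm.pdf(eta)
        dmu = np.maximum(dmu, 1e-10)
        W = dmu**2 / (mu * (1 - mu))
        z = eta + (y - mu) / dmu
    else:
        mu = np.clip(expit(eta), 1e-10, 1 - 1e-10)
        W = mu * (1 - mu)
        z = eta + (y - mu) / W
    return W, z


def _lt50_delta(b0: float, b1: float, cov: np.ndarray) -> tuple[float, float]:
    value = -b0 / b1
    grad = np.array([-1.0 / b1, b0 / b1**2])
    var = float(grad @ cov @ grad)
    return float(value), float(np.sqrt(max(var, 0.0)))


def lt50(fit: DoseResponseFit) -> tuple[float, float]:
    """Median lethal temperature and its delta-method standard error."""
    if not fit.converged:
        raise FitError("fit did not converge; LT50 is not reliable")
    if abs(fit.slope) <= _SLOPE_TOL:
        raise FitError(
            f"|slope| = {abs(fit.slope):.2g} is below tolerance; "
            "the median dose -b0/b is unstable (flat dose-response)"
        )
    return _lt50_delta(fit.intercept, fit.slope, fit.covariance)


def compare_lt50(fit_a: DoseResponseFit, fit_b: DoseResponseFit) -> tuple[float, float, float]:
    """LT50 difference (a minus b), its SE for independent samples, and z.

    Returns ``(difference, se, z)``; z is 0 when both SEs are 0 and the
    difference is 0 (identical fits).
    """
    if not (fit_a.converged and fit_b.converged):
        raise FitError("both fits must have converged to compare LT50s")
    va, sa = lt50(fit_a)
    vb, sb = lt50(fit_b)
    difference = va - vb
    se = float(np.hypot(sa, sb))
    z = difference / se if se > 0 else (0.0 if difference == 0 else float("inf"))
    return float(difference), se, float(z)


def death_fractions(records: Iterable[HeatShockRecord]) -> dict[float, float]:
    """Observed per-temperature death fractions (descriptive companion to
    the regression median; the two LT50 notions need not coincide)."""
    temps, y = _design(list(records))
    out: dict[float, float] = {}
    for t in np.unique(temps):
        mask = temps == t
        out[float(t)] = float(1.0 - y[mask].mean())
    return out
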