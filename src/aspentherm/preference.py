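"""Thermal-preference analysis for gradient-bar choice trials.

Maps labelled bar positions to temperatures, tests whether the gradient
narrows the spread of positions (Levene / Brown-Forsythe), tests whether
paired control-vs-gradient position shifts differ from zero (one-sample t),
summarises the preferred temperature T_PREF (mean, sd, 95 % CI), and tests
whether T_PREF depends on rearing temperature (single-df regression ANOVA).

The test statistics are computed from the textbook formulas directly so
that every degree of freedom comes from the data supplied, never from a
published table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .records import GradientTrial

__all__ = [
    "GradientSpec",
    "PreferenceSummary",
    "PreferenceError",
    "position_to_temperature",
    "levene_test",
    "paired_position_test",
    "summarize_tpref",
    "tpref_confidence_interval",
    "anova_tpref_by_rearing",
    "preference_summary",
]


class PreferenceError(ValueError):
    """Invalid input to a preference-analysis operation."""


@dataclass(frozen=True)
class GradientSpec:
    """Geometry of the linear thermal gradient bar.

    ``cold_end_position`` says whether mark 1 ("first") or mark
    ``n_positions`` ("last") sits at the cold end. In the study apparatus
    higher labels were closer to the cold side, i.e. "last".
    """

    cold_end: float = 12.5  # deg C
    hot_end: float = 44.5  # deg C
    n_positions: int = 6
    cold_end_position: str = "last"

    def __post_init__(self) -> None:
        if not self.cold_end < self.hot_end:
            raise PreferenceError("cold_end must be below hot_end")
        if self.n_positions < 2:
            raise PreferenceError("n_positions must be >= 2")
        if self.cold_end_position not in ("first", "last"):
            raise PreferenceError("cold_end_position must be 'first' or 'last'")


@dataclass(frozen=True)
class PreferenceSummary:
    """Complete statistical summary of one gradient experiment."""

    n: int
    tpref_mean: float
    tpref_sd: float
    ci95: tuple[float, float]
    levene_F: float
    levene_df: tuple[int, int]
    levene_p: float
    paired_mean_diff: float
    paired_t: float
    paired_df: int
    paired_p: float
    rearing_anova_F: float
    rearing_anova_df: tuple[int, int]
    rearing_anova_p: float


def position_to_temperature(
    position: float | np.ndarray, spec: GradientSpec
) -> float | np.ndarray:
    """Temperature at a bar mark by linear interpolation between the ends."""
    pos = np.asarray(position, dtype=float)
    if np.any(pos < 1) or np.any(pos > spec.n_positions):
        raise PreferenceError(
            f"position outside marks [1, {spec.n_positions}]"
        )
    frac = (pos - 1.0) / (spec.n_positions - 1.0)
    if spec.cold_end_position == "last":
        temp = spec.hot_end - frac * (spec.hot_end - spec.cold_end)
    else:
        temp = spec.cold_end + frac * (spec.hot_end - spec.cold_end)
    return float(temp) if np.isscalar(position) else temp


def levene_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    center: str = "median",
) -> tuple[float, tuple[int, int], float]:
    """Two-group Levene test of equality of variances.

    One-way ANOVA on absolute deviations from each group's center. The
    default median center is the robust Brown-Forsythe form.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise PreferenceError("each group needs at least 2 values")
    if center == "median":
        da, db = np.abs(a - np.median(a)), np.abs(b - np.median(b))
    elif center == "mean":
        da, db = np.abs(a - a.mean()), np.abs(b - b.mean())
    else:
        raise PreferenceError("center must be 'median' or 'mean'")
    n_a, n_b = da.size, db.size
    grand = (da.sum() + db.sum()) / (n_a + n_b)
    ss_between = n_a * (da.mean() - grand) ** 2 + n_b * (db.mean() - grand) ** 2
    ss_within = ((da - da.mean()) ** 2).sum() + ((db - db.mean()) ** 2).sum()
    df = (1, n_a + n_b - 2)
    if ss_within <= 0:
        raise PreferenceError("zero within-group deviation everywhere; F undefined")
    F = (ss_between / df[0]) / (ss_within / df[1])
    p = float(stats.f.sf(F, *df))
    return float(F), df, p


def paired_position_test(
    trials: Iterable[GradientTrial],
) -> tuple[float, float, int, float]:
    """One-sample t test of gradient-minus-control position differences.

    Returns ``(mean_difference, t, df, p)`` with df = n - 1.
    """
    diffs = np.array(
        [t.position_gradient - t.position_control for t in trials], dtype=float
    )
    if diffs.size < 2:
        raise PreferenceError("need at least 2 paired trials")
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    if sd == 0:
        raise PreferenceError(
            f"zero variance of position differences (all equal {mean:g}); t undefined"
        )
    n = diffs.size
    t_stat = mean / (sd / np.sqrt(n))
    df = n - 1
    p = float(2.0 * stats.t.sf(abs(t_stat), df))
    return mean, float(t_stat), df, p


def tpref_confidence_interval(
    mean: float, sd: float, n: int, level: float = 0.95
) -> tuple[float, float]:
    """Student-t confidence interval for a mean from its sample moments."""
    if n < 2:
        raise PreferenceError("need n >= 2 for a confidence interval")
    half = stats.t.ppf(0.5 + level / 2.0, n - 1) * sd / np.sqrt(n)
    return (float(mean - half), float(mean + half))


def summarize_tpref(
    temperatures: Sequence[float], level: float = 0.95
) -> tuple[float, float, tuple[float, float]]:
    """Sample mean, sd, and t-based CI of preferred temperatures."""
    x = np.asarray(temperatures, dtype=float)
    if x.size < 2:
        raise PreferenceError("need at least 2 temperatures")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    return mean, sd, tpref_confidence_interval(mean, sd, x.size, level)


def anova_tpref_by_rearing(
    temperatures: Sequence[float],
    rearing_temperatures: Sequence[float],
    categorical: bool = False,
) -> tuple[float, tuple[int, int], float]:
    """ANOVA of preferred temperature on rearing temperature.

    Default: rearing temperature enters as a continuous covariate, giving
    the single-df regression F with df (1, n-2). ``categorical=True``
    treats rearing levels as a factor with df (k-1, n-k).
    """
    y = np.asarray(temperatures, dtype=float)
    x = np.asarray(rearing_temperatures, dtype=float)
    if y.size != x.size:
        raise PreferenceError("temperatures and rearing_temperatures must align")
    levels = np.unique(x)
    if levels.size < 2:
        raise PreferenceError("rearing temperature is constant; ANOVA undefined")

    ss_total = ((y - y.mean()) ** 2).sum()
    if categorical:
        ss_between = sum(
            (x == lv).sum() * (y[x == lv].mean() - y.mean()) ** 2 for lv in levels
        )
        df = (int(levels.size - 1), int(y.size - levels.size))
        ss_resid = ss_total - ss_between
        ss_model = ss_between
    else:
        sxx = ((x - x.mean()) ** 2).sum()
        slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
        ss_model = slope**2 * sxx
        ss_resid = ss_total - ss_model
        df = (1, int(y.size - 2))
    if ss_resid <= 1e-12 * max(ss_total, 1.0):
        raise PreferenceError("perfect fit: residual SS is zero, F is unbounded")
    F = (ss_model / df[0]) / (ss_resid / df[1])
    p = float(stats.f.sf(F, *df))
    return float(F), df, p


def preference_summary(
    trials: Sequence[GradientTrial],
    spec: GradientSpec | None = None,
    levene_center: str = "median",
) -> PreferenceSummary:
    """Run the full preference analysis on paired gradient trials.

    T_PREF statistics are computed on the temperatures at the chosen marks
    during the gradient run (the apparatus recorded marked intervals).
    """
    spec = spec or GradientSpec()
    trials = list(trials)
    control = np.array([t.position_control for t in trials], dtype=float)
    gradient = np.array([t.position_gradient for t in trials], dtype=float)
    temps = np.asarray(position_to_temperature(gradient, spec), dtype=float)
    rearing = np.array([t.rearing_temperature for t in trials], dtype=float)

    mean, sd, ci = summarize_tpref(temps)
    lev_F, lev_df, lev_p = levene_test(control, gradient, center=levene_center)
    mean_diff, t_stat, t_df, t_p = paired_position_test(trials)
    an_F, an_df, an_p = anova_tpref_by_rearing(temps, rearing)
    return PreferenceSummary(
        n=len(trials),
        tpref_mean=mean,
        tpref_sd=sd,
        ci95=ci,
        levene_F=lev_F,
        levene_df=lev_df,
        levene_p=lev_p,
        paired_mean_diff=mean_diff,
        paired_t=t_stat,
        paired_df=t_df,
        paired_p=t_p,
        rearing_anova_F=an_F,
        rearing_anova_df=an_df,
        rearing_anova_p=an_p,
    )
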