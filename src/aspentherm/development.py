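"""Emergence-timing linear model and sequential ANOVA decomposition.

Days to adult emergence are modelled by ordinary least squares on
[intercept, rearing temperature (continuous), insect type (0/1 indicator),
temperature x type]. The ANOVA is the sequential (Type-I) decomposition in
that entry order, matching R's ``aov``-style output: each term's sum of
squares is the drop in residual SS when the term's columns join the model.

Temperature enters as a continuous covariate by default (a 5-level factor
would carry 4 df, but the published decomposition shows 1); a categorical
option is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .records import EmergenceRecord

__all__ = [
    "EmergenceFit",
    "AnovaRow",
    "AnovaTable",
    "ModelError",
    "fit_emergence_lm",
    "anova_sequential",
    "lm_aic",
    "development_rate",
    "emergence_proportions",
]


class ModelError(ValueError):
    """The linear model cannot be fitted or decomposed."""


@dataclass(frozen=True)
class AnovaRow:
    term: str
    df: int
    sum_sq: float
    mean_sq: float
    F: float | None
    p: float | None


@dataclass(frozen=True)
class AnovaTable:
    """Sequential sum-of-squares decomposition with a residual row."""

    rows: tuple[AnovaRow, ...]
    residual: AnovaRow

    @property
    def total_df(self) -> int:
        return sum(r.df for r in self.rows) + self.residual.df

    @property
    def total_sum_sq(self) -> float:
        return sum(r.sum_sq for r in self.rows) + self.residual.sum_sq

    @classmethod
    def from_components(
        cls,
        terms: Sequence[tuple[str, int, float]],
        residual_ss: float,
        residual_df: int,
    ) -> "AnovaTable":
        """Build a table from (term, df, SS) components plus the residual,
        recomputing each F as the mean-square ratio and p from the F
        distribution. Useful for auditing a published decomposition."""
        if residual_df <= 0:
            raise ModelError("residual df must be positive")
        ms_resid = residual_ss / residual_df
        rows = []
        for term, df, ss in terms:
            ms = ss / df
            F = ms / ms_resid
            rows.append(
                AnovaRow(term, df, ss, ms, float(F), float(stats.f.sf(F, df, residual_df)))
            )
        resid = AnovaRow("residuals", residual_df, residual_ss, ms_resid, None, None)
        return cls(tuple(rows), resid)


@dataclass(frozen=True)
class EmergenceFit:
    """OLS fit of days-to-emergence on temperature, type and interaction."""

    coefficients: np.ndarray  # order: intercept, temperature, type, temp:type
    term_names: tuple[str, ...]
    residual_ss: float
    residual_df: int
    n: int
    sequential_ss: tuple[float, ...]  # one per non-intercept term
    sequential_df: tuple[int, ...]
    total_ss: float  # corrected

    @property
    def k(self) -> int:
        """Number of estimated mean-model coefficients."""
        return len(self.coefficients)


def _design_matrix(
    records: Sequence[EmergenceRecord], categorical_temperature: bool
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, int]]]:
    temps = np.array([r.rearing_temperature for r in records], dtype=float)
    types = np.array(
        [1.0 if r.insect_type == "parasitoid" else 0.0 for r in records]
    )
    y = np.array([r.days_to_emergence for r in records], dtype=float)

    blocks: list[tuple[str, np.ndarray]] = []
    if categorical_temperature:
        levels = np.unique(temps)
        cols = np.column_stack([(temps == lv).astype(float) for lv in levels[1:]])
        blocks.append(("temperature", cols))
        inter = cols * types[:, None]
        type_col = types[:, None]
    else:
        blocks.append(("temperature", temps[:, None]))
        inter = (temps * types)[:, None]
        type_col = types[:, None]
    blocks.append(("type", type_col))
    blocks.append(("temperature:type", inter))

    X = np.column_stack([np.ones_like(y)[:, None]] + [b for _, b in blocks])
    term_cols = [(name, b.shape[1]) for name, b in blocks]
    return X, y, term_cols


def fit_emergence_lm(
    records: Iterable[EmergenceRecord],
    categorical_temperature: bool = False,
) -> EmergenceFit:
    """Fit the emergence linear model by QR-based least squares.

    The sequential SS for each term is accumulated while the terms are
    added in entry order (temperature, type, interaction), so the ANOVA
    decomposition falls out of the same orthogonal factorisation.
    """
    records = list(records)
    types_present = {r.insect_type for r in records}
    if types_present != {"host", "parasitoid"}:
        raise ModelError(
            "both insect types must be present; got " + (", ".join(sorted(types_present)) or "none")
        )
    if np.unique([r.rearing_temperature for r in records]).size < 2:
        raise ModelError("need at least 2 rearing temperatures")

    X, y, term_cols = _design_matrix(records, categorical_temperature)
    n = y.size

    # grow the model term by term; RSS drops are the sequential SS
    rss_prev = float(((y - y.mean()) ** 2).sum())  # intercept-only RSS
    total_ss = rss_prev
    seq_ss: list[float] = []
    seq_df: list[int] = []
    ncols = 1
    rank_prev = 1
    for name, width in term_cols:
        ncols += width
        Xk = X[:, :ncols]
        rank = np.linalg.matrix_rank(Xk)
        if rank < rank_prev + width:
            raise ModelError(f"design is rank-deficient: term '{name}' is aliased")
        beta_k, _, _, _ = np.linalg.lstsq(Xk, y, rcond=None)
        rss = float(((y - Xk @ beta_k) ** 2).sum())
        seq_ss.append(rss_prev - rss)
        seq_df.append(width)
        rss_prev = rss
        rank_prev = rank

    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    residual_df = n - X.shape[1]
    if residual_df < 0:
        raise ModelError("more coefficients than observations")
    names = ("intercept",) + tuple(name for name, _ in term_cols)
    return EmergenceFit(
        coefficients=beta,
        term_names=names,
        residual_ss=rss_prev,
        residual_df=residual_df,
        n=n,
        sequential_ss=tuple(seq_ss),
        sequential_df=tuple(seq_df),
        total_ss=total_ss,
    )


def anova_sequential(fit: EmergenceFit) -> AnovaTable:
    """Type-I ANOVA table from a fitted emergence model."""
    if fit.residual_df <= 0:
        raise ModelError("zero residual df; F ratios undefined")
    terms = [
        (name, df, ss)
        for name, df, ss in zip(fit.term_names[1:], fit.sequential_df, fit.sequential_ss)
    ]
    return AnovaTable.from_components(terms, fit.residual_ss, fit.residual_df)


def lm_aic(fit: EmergenceFit) -> float:
    """Gaussian maximum-likelihood AIC of the fitted model.

    AIC = n log(2 pi RSS / n) + n + 2 (k + 1), counting the error variance
    as an estimated parameter alongside the k mean coefficients.
    """
    if fit.residual_ss <= 0:
        raise ModelError("zero residual SS: the Gaussian likelihood is degenerate")
    n = fit.n
    return float(n * np.log(2 * np.pi * fit.residual_ss / n) + n + 2 * (fit.k + 1))


def development_rate(records: Iterable[EmergenceRecord]) -> list[tuple[EmergenceRecord, float]]:
    """Append the development rate 1/days to each record."""
    return [(r, 1.0 / r.days_to_emergence) for r in records]


def emergence_proportions(
    n_host: int, n_parasitoid: int, n_leaves_total: int
) -> dict[str, float]:
    """Emergence bookkeeping: per-type and overall proportions (percent)."""
    if n_leaves_total <= 0 or n_host + n_parasitoid > n_leaves_total:
        raise ModelError("counts must be non-negative and sum to at most the leaf total")
    none = n_leaves_total - n_host - n_parasitoid
    return {
        "host_pct": 100.0 * n_host / n_leaves_total,
        "parasitoid_pct": 100.0 * n_parasitoid / n_leaves_total,
        "none_pct": 100.0 * none / n_leaves_total,
    }
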