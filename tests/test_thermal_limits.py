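"""Dose-response fitting: closed forms, oracles, invariants, error surface."""

import numpy as np
import pytest
from scipy.special import expit, logit

import aspentherm as at
from aspentherm.thermal_limits import FitError, SeparationError, death_fractions


def make_records(temps, outcomes):
    return [
        at.HeatShockRecord(f"id{i}", "parasitoid", float(t), int(s))
        for i, (t, s) in enumerate(zip(temps, outcomes))
    ]


def grouped_records(spec):
    """spec: list of (temperature, n_survived, n_died)."""
    records = []
    for t, n_s, n_d in spec:
        records += make_records([t] * (n_s + n_d), [1] * n_s + [0] * n_d)
    return records


def _loglik(temps, y, b0, b1):
    mu = np.clip(expit(b0 + b1 * temps[None, :]), 1e-12, 1 - 1e-12)
    return (y * np.log(mu) + (1 - y) * np.log(1 - mu)).sum(axis=-1)


def loglik_grid_argmax(temps, y, b_range, spacing_target=0.001):
    """Independent brute-force ML oracle on a (b0, b) lattice.

    The likelihood ridge is nearly a line b0 = -b * lt50, so the search
    profiles the intercept: for every slope on the lattice the best
    intercept is found on its own refined lattice, then the slope lattice
    is refined around the profile maximum down to ``spacing_target``.
    """
    temps = np.asarray(temps, float)
    y = np.asarray(y, float)

    def best_b0_for(b1s):
        b0_best = np.empty_like(b1s)
        for k, b1 in enumerate(b1s):
            lo0, hi0 = -60.0 - 50.0 * abs(b1), 60.0 + 50.0 * abs(b1)
            while True:
                b0s = np.linspace(lo0, hi0, 201)
                ll = _loglik(temps, y, b0s[:, None], b1)
                i = int(np.argmax(ll))
                step = b0s[1] - b0s[0]
                if step <= spacing_target:
                    b0_best[k] = b0s[i]
                    break
                lo0, hi0 = b0s[i] - 2 * step, b0s[i] + 2 * step
        return b0_best

    lo1, hi1 = b_range
    while True:
        b1s = np.linspace(lo1, hi1, 41)
        b0s = best_b0_for(b1s)
        ll = np.array([_loglik(temps, y, b0, b1) for b0, b1 in zip(b0s, b1s)])
        j = int(np.argmax(ll))
        step = b1s[1] - b1s[0]
        if step <= spacing_target:
            return b0s[j], b1s[j]
        lo1, hi1 = b1s[j] - 2 * step, b1s[j] + 2 * step


class TestFit:
    def test_two_point_closed_form(self):
        # survival 0.75 at 36 and 0.25 at 38: slope = (logit .25 - logit .75)/2
        records = grouped_records([(36.0, 3, 1), (38.0, 1, 3)])
        fit = at.fit_logistic_survival(records)
        slope_expected = (logit(0.25) - logit(0.75)) / 2.0  # -1.0986...
        assert fit.slope == pytest.approx(slope_expected, abs=1e-6)
        assert fit.lt50 == pytest.approx(37.0, abs=1e-6)

    def test_large_n_recovers_truth(self, large_heat_shock):
        fit = at.fit_logistic_survival(large_heat_shock)
        assert fit.converged
        assert abs(fit.lt50 - 37.4) < 0.3
        assert abs(fit.slope - (-0.25)) < 0.03

    def test_agrees_with_grid_search_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            temps = rng.choice([34, 36, 38, 40, 42, 44], size=50)
            p = expit(9.35 - 0.25 * temps)
            y = (rng.random(50) < p).astype(int)
            records = make_records(temps, y)
            try:
                fit = at.fit_logistic_survival(records)
            except SeparationError:
                continue
            b0, b1 = loglik_grid_argmax(temps, y, (-3, 1))
            assert fit.intercept == pytest.approx(b0, abs=0.002)
            assert fit.slope == pytest.approx(b1, abs=0.002)

    def test_agrees_with_statsmodels_glm(self, large_heat_shock):
        sm = pytest.importorskip("statsmodels.api")
        temps = np.array([r.shock_temperature for r in large_heat_shock])
        y = np.array([r.survived for r in large_heat_shock])
        X = np.column_stack([np.ones_like(temps), temps])
        oracle = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        fit = at.fit_logistic_survival(large_heat_shock)
        assert fit.intercept == pytest.approx(oracle.params[0], rel=1e-6)
        assert fit.slope == pytest.approx(oracle.params[1], rel=1e-6)
        assert np.allclose(fit.covariance, oracle.cov_params(), rtol=1e-4)

    def test_deviance_nonincreasing_per_iteration(self, large_heat_shock):
        trace: list[float] = []
        at.fit_logistic_survival(large_heat_shock, deviance_trace=trace)
        assert len(trace) > 2
        assert all(a >= b - 1e-9 for a, b in zip(trace, trace[1:]))

    def test_shift_equivariance(self, large_heat_shock):
        fit = at.fit_logistic_survival(large_heat_shock)
        shifted = [
            at.HeatShockRecord(r.individual_id, r.species, r.shock_temperature + 10.0, r.survived)
            for r in large_heat_shock
        ]
        fit_shift = at.fit_logistic_survival(shifted)
        assert fit_shift.lt50 == pytest.approx(fit.lt50 + 10.0, abs=1e-6)
        assert fit_shift.slope == pytest.approx(fit.slope, abs=1e-8)

    def test_complete_separation_raises_named_error(self):
        records = grouped_records([(34.0, 5, 0), (36.0, 5, 0), (42.0, 0, 5), (44.0, 0, 5)])
        with pytest.raises(SeparationError, match="separation"):
            at.fit_logistic_survival(records)

    def test_single_outcome_class_raises(self):
        records = grouped_records([(34.0, 5, 0), (44.0, 5, 0)])
        with pytest.raises(FitError, match="single outcome"):
            at.fit_logistic_survival(records)

    def test_flat_likelihood_surfaces_lt50_error(self):
        records = grouped_records([(30.0, 2, 2), (45.0, 2, 2)])
        fit = at.fit_logistic_survival(records)
        assert abs(fit.slope) < 1e-6
        with pytest.raises(FitError, match="slope"):
            at.lt50(fit)

    def test_field_design_scale_bias(self):
        # replicate-level spread at n ~ 8/temperature is wide; the bias of
        # the median estimate is what must stay small
        estimates = []
        for seed in range(300):
            design = at.HeatShockDesign(n_per_temperature=8, seed=seed)
            try:
                fit = at.fit_logistic_survival(at.simulate_heat_shock(design))
            except FitError:
                continue
            if fit.converged and np.isfinite(fit.lt50):
                estimates.append(fit.lt50)
        assert len(estimates) > 250
        assert abs(np.median(estimates) - 37.4) < 0.5


class TestLt50:
    def test_point_estimate_from_pinned_coefficients(self):
        fit = at.DoseResponseFit(
            intercept=9.35, slope=-0.25, covariance=np.zeros((2, 2)),
            lt50=-9.35 / -0.25, lt50_se=0.0, n=47, deviance=1.0, converged=True,
        )
        value, se = at.lt50(fit)
        assert value == pytest.approx(37.4)
        assert se == 0.0

    def test_zero_intercept(self):
        fit = at.DoseResponseFit(
            intercept=0.0, slope=-1.0, covariance=np.zeros((2, 2)),
            lt50=0.0, lt50_se=0.0, n=10, deviance=1.0, converged=True,
        )
        assert at.lt50(fit)[0] == 0.0

    def test_delta_method_matches_analytic_variance(self):
        cov = np.array([[4.0, 0.3], [0.3, 0.01]])
        b0, b1 = 9.35, -0.25
        fit = at.DoseResponseFit(
            intercept=b0, slope=b1, covariance=cov,
            lt50=-b0 / b1, lt50_se=0.0, n=47, deviance=1.0, converged=True,
        )
        g = np.array([-1 / b1, b0 / b1**2])
        _, se = at.lt50(fit)
        assert se == pytest.approx(np.sqrt(g @ cov @ g))


class TestCompare:
    @staticmethod
    def pinned(lt50_value, se):
        slope = -1.0
        return at.DoseResponseFit(
            intercept=lt50_value, slope=slope, covariance=np.diag([se**2, 0.0]),
            lt50=lt50_value, lt50_se=se, n=50, deviance=1.0, converged=True,
        )

    def test_difference_of_published_limits(self):
        diff, _, _ = at.compare_lt50(self.pinned(42.1, 0.5), self.pinned(37.4, 0.5))
        assert diff == pytest.approx(4.7)

    def test_identical_fits_give_zero(self):
        fit = self.pinned(37.4, 0.5)
        diff, _, z = at.compare_lt50(fit, fit)
        assert diff == 0.0 and z == 0.0

    def test_se_combines_in_quadrature(self):
        _, se, _ = at.compare_lt50(self.pinned(40.0, 3.0), self.pinned(38.0, 4.0))
        assert se == pytest.approx(5.0)

    def test_unconverged_fit_rejected(self):
        bad = at.DoseResponseFit(
            intercept=1.0, slope=-1.0, covariance=np.zeros((2, 2)),
            lt50=1.0, lt50_se=0.0, n=5, deviance=1.0, converged=False,
        )
        with pytest.raises(FitError, match="converge"):
            at.compare_lt50(bad, self.pinned(37.4, 0.5))


def test_death_fractions_reports_per_temperature():
    records = grouped_records([(34.0, 3, 1), (44.0, 1, 3)])
    fractions = death_fractions(records)
    assert fractions == {34.0: pytest.approx(0.25), 44.0: pytest.approx(0.75)}
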