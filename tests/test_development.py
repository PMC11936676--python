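"""Emergence linear model, sequential ANOVA, AIC, development rates."""

import numpy as np
import pytest
from scipy import stats

import aspentherm as at
from aspentherm.development import AnovaTable, ModelError


def records_from_arrays(temps, types, days):
    return [
        at.EmergenceRecord(ty, float(t), float(d))
        for t, ty, d in zip(temps, types, days)
    ]


def random_records(rng, n=40):
    temps = rng.choice([15.0, 20.0, 25.0, 30.0, 35.0], n)
    types = rng.choice(["host", "parasitoid"], n)
    days = 40 - temps * 0.8 + (types == "parasitoid") * 3 + rng.normal(0, 4, n)
    return records_from_arrays(temps, types, np.maximum(days, 1.0))


class TestFit:
    def test_noise_free_surface_recovered(self):
        temps = np.tile([15.0, 25.0, 35.0], 4)
        types = np.repeat(["host", "parasitoid"], 6)
        tt = (types == "parasitoid").astype(float)
        days = 50 - 0.9 * temps - 4 * tt + 0.1 * temps * tt
        fit = at.fit_emergence_lm(records_from_arrays(temps, types, days))
        assert np.allclose(fit.coefficients, [50, -0.9, -4, 0.1], atol=1e-10)
        assert fit.residual_ss == pytest.approx(0.0, abs=1e-18)

    def test_residual_ss_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(30)
        records = random_records(rng)
        fit = at.fit_emergence_lm(records)
        temps = np.array([r.rearing_temperature for r in records])
        tt = np.array([r.insect_type == "parasitoid" for r in records], float)
        y = np.array([r.days_to_emergence for r in records])
        X = np.column_stack([np.ones_like(y), temps, tt, temps * tt])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        rss = float(((y - X @ beta) ** 2).sum())
        assert fit.residual_ss == pytest.approx(rss, rel=1e-8)

    def test_single_type_rejected(self):
        temps = [15.0, 25.0, 35.0]
        records = records_from_arrays(temps, ["host"] * 3, [30.0, 20.0, 10.0])
        with pytest.raises(ModelError, match="both insect types"):
            at.fit_emergence_lm(records)

    def test_aliased_design_names_term(self):
        # parasitoids only at one temperature: interaction aliased with type
        temps = [15.0, 25.0, 35.0, 25.0, 25.0, 25.0]
        types = ["host", "host", "host", "parasitoid", "parasitoid", "parasitoid"]
        with pytest.raises(ModelError, match="temperature:type"):
            at.fit_emergence_lm(records_from_arrays(temps, types, [30, 20, 10, 22, 21, 20]))


class TestSequentialAnova:
    def test_published_decomposition_recomputes_f(self):
        table = AnovaTable.from_components(
            [("temperature", 1, 24446.8), ("insect type", 1, 932.7), ("temperature: type", 1, 324.2)],
            residual_ss=7781.8,
            residual_df=367,
        )
        F = [row.F for row in table.rows]
        assert round(F[0], 1) == 1152.9
        assert round(F[1]) == 44
        assert round(F[2], 1) == 15.3

    def test_ss_additivity(self, emergence_records):
        fit = at.fit_emergence_lm(emergence_records)
        table = at.anova_sequential(fit)
        assert table.total_sum_sq == pytest.approx(fit.total_ss, rel=1e-8)
        assert table.total_df == fit.n - 1

    def test_matches_statsmodels_type1_oracle(self):
        smf = pytest.importorskip("statsmodels.formula.api")
        anova_lm = pytest.importorskip("statsmodels.stats.anova").anova_lm
        import pandas as pd

        rng = np.random.default_rng(31)
        records = random_records(rng, 60)
        df = pd.DataFrame(
            {
                "days": [r.days_to_emergence for r in records],
                "temp": [r.rearing_temperature for r in records],
                "t01": [float(r.insect_type == "parasitoid") for r in records],
            }
        )
        oracle = anova_lm(smf.ols("days ~ temp + t01 + temp:t01", df).fit())
        table = at.anova_sequential(at.fit_emergence_lm(records))
        for row, (_, orow) in zip(table.rows, oracle.iloc[:3].iterrows()):
            assert row.sum_sq == pytest.approx(orow["sum_sq"], rel=1e-8)
            assert row.F == pytest.approx(orow["F"], rel=1e-8)

    def test_balanced_orthogonal_design_sequential_equals_marginal(self):
        # balanced full factorial with centred covariate: SS do not depend
        # on entry order
        temps = np.tile(np.repeat([15.0, 25.0, 35.0], 2), 2)
        types = np.repeat(["host", "parasitoid"], 6)
        rng = np.random.default_rng(32)
        days = 30 - 0.5 * temps + rng.normal(0, 2, 12)
        records = records_from_arrays(temps, types, days)
        table = at.anova_sequential(at.fit_emergence_lm(records))
        # reversed entry order via a manual nested-RSS computation
        y = days
        tt = (types == "parasitoid").astype(float)
        X_full = np.column_stack([np.ones(12), temps, tt, temps * tt])
        orders = {"temperature": 1, "type": 2}
        for term, col in orders.items():
            others = [c for c in range(1, 3) if c != col]
            X_without = X_full[:, [0] + others]
            X_with = X_full[:, [0, col] + others]
            rss_without = _rss(X_without, y)
            rss_with = _rss(X_with, y)
            marginal = rss_without - rss_with
            seq = next(r.sum_sq for r in table.rows if r.term.startswith(term))
            assert seq == pytest.approx(marginal, rel=1e-8)

    def test_qualitative_significance_at_study_scale(self, emergence_records):
        table = at.anova_sequential(at.fit_emergence_lm(emergence_records))
        assert all(row.p < 0.001 for row in table.rows)

    def test_null_terms_produce_uniform_p(self):
        # no type effect, no interaction: their p-values are U(0,1)
        rng = np.random.default_rng(33)
        p_type, p_inter = [], []
        for _ in range(300):
            temps = np.tile([15.0, 20.0, 25.0, 30.0, 35.0], 12)
            types = rng.permutation(np.repeat(["host", "parasitoid"], 30))
            days = 45 - temps + rng.normal(0, 4, 60)
            table = at.anova_sequential(
                at.fit_emergence_lm(records_from_arrays(temps, types, np.maximum(days, 1)))
            )
            p_type.append(table.rows[1].p)
            p_inter.append(table.rows[2].p)
        assert stats.kstest(p_type, "uniform").pvalue > 0.01
        assert stats.kstest(p_inter, "uniform").pvalue > 0.01


def _rss(X, y):
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    return float(((y - X @ beta) ** 2).sum())


class TestAic:
    def test_plug_in_arithmetic(self):
        rng = np.random.default_rng(34)
        temps = np.tile([15.0, 25.0, 35.0], 4)[:10]
        types = np.array(["host", "parasitoid"] * 5)
        days = 40 - 0.5 * temps + rng.normal(0, 3, 10)
        real = at.fit_emergence_lm(records_from_arrays(temps, types, np.maximum(days, 1)))
        expected = 10 * np.log(2 * np.pi * real.residual_ss / 10) + 10 + 2 * (4 + 1)
        assert at.lm_aic(real) == pytest.approx(expected)

    def test_nested_models_rss_monotone(self):
        rng = np.random.default_rng(35)
        records = random_records(rng, 50)
        full = at.fit_emergence_lm(records)
        # smaller model: drop the interaction by refitting with a constant type
        temps = np.array([r.rearing_temperature for r in records])
        tt = np.array([r.insect_type == "parasitoid" for r in records], float)
        y = np.array([r.days_to_emergence for r in records])
        X_small = np.column_stack([np.ones_like(y), temps, tt])
        assert full.residual_ss <= _rss(X_small, y) + 1e-10

    def test_noise_column_aic_identity(self):
        # adding one pure-noise regressor changes AIC by 2 - n log(RSS_old/RSS_new)
        rng = np.random.default_rng(36)
        n = 80
        x = rng.normal(size=n)
        y = 1.0 + 2.0 * x + rng.normal(size=n)
        X_old = np.column_stack([np.ones(n), x])
        X_new = np.column_stack([X_old, rng.normal(size=n)])
        rss_old, rss_new = _rss(X_old, y), _rss(X_new, y)
        aic_old = n * np.log(2 * np.pi * rss_old / n) + n + 2 * (2 + 1)
        aic_new = n * np.log(2 * np.pi * rss_new / n) + n + 2 * (3 + 1)
        assert aic_new - aic_old == pytest.approx(2 - n * np.log(rss_old / rss_new))


class TestRates:
    def test_reciprocal(self):
        records = [at.EmergenceRecord("host", 20.0, 20.0)]
        assert at.development_rate(records)[0][1] == pytest.approx(0.05)

    def test_monotone_in_temperature_for_noise_free_degree_days(self):
        quiet = at.synthetic.DegreeDayParams(400.0, 2.0, 0.0, 1.0)
        silent = at.synthetic.DegreeDayParams(259.0, 8.0, 0.0, 0.0)
        design = at.EmergenceDesign(host=quiet, parasitoid=silent, n_leaves_per_temperature=1, seed=1)
        rates = [rate for _, rate in at.development_rate(at.simulate_emergence(design))]
        assert all(a < b for a, b in zip(rates, rates[1:]))

    def test_empty_input(self):
        assert at.development_rate([]) == []


class TestProportions:
    def test_published_counts(self):
        props = at.emergence_proportions(107, 270, 750)
        assert props["parasitoid_pct"] == pytest.approx(36.0)
        assert props["host_pct"] == pytest.approx(14.266, abs=0.001)
        assert props["none_pct"] == pytest.approx(49.733, abs=0.001)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ModelError):
            at.emergence_proportions(500, 400, 750)
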