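"""Baseline statistics, improvement rates, and the mGOS outcome regression."""

import numpy as np
import pandas as pd
import pytest

from capeneeg import chi2_2x2, improvement_rate, mgos_regression, pooled_t
from capeneeg.cohort_stats import baseline_table, improvement_table, regression_frame
from capeneeg.errors import CollinearityError, DegenerateTableError
from capeneeg.synthetic import gen_regression_cohort


class TestPooledT:
    def test_published_age_summaries(self):
        t, p = pooled_t(44.88, 13.68, 50, 50.69, 13.05, 35)
        # printed summaries are rounded to 2 dp, which moves t by ~2e-3
        assert t == pytest.approx(-1.963, abs=2e-3)
        assert p == pytest.approx(0.053, abs=1e-3)

    def test_published_duration_summaries(self):
        t, _ = pooled_t(134.28, 62.45, 50, 111.91, 50.72, 35)
        assert round(t, 3) == 1.752

    def test_identical_groups_give_zero(self):
        t, p = pooled_t(5.0, 1.0, 10, 5.0, 1.0, 12)
        assert t == 0.0

    def test_antisymmetric_under_group_swap(self):
        t1, p1 = pooled_t(10.0, 2.0, 20, 12.0, 3.0, 15)
        t2, p2 = pooled_t(12.0, 3.0, 15, 10.0, 2.0, 20)
        assert t1 == -t2 and p1 == p2

    def test_degenerate_variance(self):
        assert pooled_t(3.0, 0.0, 5, 3.0, 0.0, 5) == (0.0, 1.0)
        with pytest.raises(ValueError, match="infinite"):
            pooled_t(3.0, 0.0, 5, 4.0, 0.0, 5)


class TestChi2:
    def test_published_sex_table(self):
        stat, p = chi2_2x2([[37, 13], [24, 11]])
        assert round(stat, 3) == 0.299

    def test_published_lesion_table(self):
        stat, _ = chi2_2x2([[34, 16], [24, 11]])
        assert round(stat, 3) == 0.003

    def test_proportional_table_gives_zero(self):
        stat, p = chi2_2x2([[20, 10], [40, 20]])
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_invariant_under_transposition(self):
        t = [[12, 7], [9, 14]]
        assert chi2_2x2(t)[0] == pytest.approx(chi2_2x2(np.transpose(t))[0])
        assert chi2_2x2(t)[0] == pytest.approx(chi2_2x2(t[::-1])[0])

    def test_zero_margin_rejected(self):
        with pytest.raises(DegenerateTableError):
            chi2_2x2([[0, 0], [5, 3]])


class TestImprovementRate:
    @pytest.mark.parametrize(
        "improved,total,expected", [(11, 50, 22.0), (13, 35, 37.1), (0, 7, 0.0)]
    )
    def test_rates(self, improved, total, expected):
        assert improvement_rate(improved, total) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            improvement_rate(1, 0)
        with pytest.raises(ValueError):
            improvement_rate(5, 3)


class TestRegression:
    def test_orthonormal_predictors_have_unit_vif(self, rng):
        # center before QR so the columns are also orthogonal to the intercept
        x = rng.normal(size=(40, 3))
        q, _ = np.linalg.qr(x - x.mean(axis=0))
        design = pd.DataFrame(q, columns=["x1", "x2", "x3"])
        design["mgos"] = rng.normal(size=40)
        rows = mgos_regression(design, dependent="mgos")
        for r in rows[1:]:
            assert r.tolerance == pytest.approx(1.0, abs=1e-10)
            assert r.vif == pytest.approx(1.0, abs=1e-10)

    def test_duplicated_predictor_rejected(self, rng):
        x = rng.normal(size=30)
        design = pd.DataFrame({"x1": x, "x2": x, "mgos": rng.normal(size=30)})
        with pytest.raises(CollinearityError, match="x2"):
            mgos_regression(design, dependent="mgos")

    def test_residuals_orthogonal_to_predictors(self, rng):
        design, _ = gen_regression_cohort(120, seed=2)
        rows = mgos_regression(design, dependent="mgos")
        coef = {r.predictor: r.B for r in rows}
        X = design.drop(columns="mgos")
        fitted = coef["(Constant)"] + sum(coef[c] * X[c] for c in X.columns)
        resid = design["mgos"] - fitted
        for c in X.columns:
            assert abs(np.dot(resid, X[c] - X[c].mean())) < 1e-6

    def test_standardized_beta_definition(self, rng):
        design, _ = gen_regression_cohort(80, seed=3)
        rows = mgos_regression(design, dependent="mgos")
        sd_y = design["mgos"].std(ddof=1)
        for r in rows[1:]:
            sd_x = design[r.predictor].std(ddof=1)
            assert r.beta == pytest.approx(r.B * sd_x / sd_y, rel=1e-9)

    def test_vif_is_reciprocal_tolerance_and_matches_statsmodels(self, rng):
        from statsmodels.stats.outliers_influence import variance_inflation_factor
        import statsmodels.api as sm

        design, _ = gen_regression_cohort(100, seed=4)
        rows = mgos_regression(design, dependent="mgos")
        X = sm.add_constant(design.drop(columns="mgos").astype(float))
        for i, r in enumerate(rows[1:], start=1):
            assert r.vif == pytest.approx(1.0 / r.tolerance, rel=1e-12)
            assert r.vif == pytest.approx(
                variance_inflation_factor(X.to_numpy(), i), rel=1e-8
            )

    def test_single_binary_predictor_matches_pooled_t(self, rng):
        g = np.repeat([0.0, 1.0], [20, 15])
        y = rng.normal(size=35) + 0.8 * g
        design = pd.DataFrame({"g": g, "mgos": y})
        rows = mgos_regression(design, dependent="mgos")
        t_ols = rows[1].t
        y0, y1 = y[g == 0], y[g == 1]
        t_pooled, _ = pooled_t(y1.mean(), y1.std(ddof=1), 15, y0.mean(), y0.std(ddof=1), 20)
        assert t_ols == pytest.approx(t_pooled, abs=1e-9)

    def test_too_few_cases_rejected(self, rng):
        design = pd.DataFrame(rng.normal(size=(4, 4)), columns=["a", "b", "c", "mgos"])
        with pytest.raises(ValueError, match="n > p"):
            mgos_regression(design, dependent="mgos")

    def test_coefficient_recovery_single_replicate(self):
        design, truth = gen_regression_cohort(200, seed=0)
        rows = mgos_regression(design, dependent="mgos")
        cu_fpu = next(r for r in rows if r.predictor == "Cu-FPu@pain_unaffected")
        assert cu_fpu.ci_low <= truth["Cu-FPu@pain_unaffected"] <= cu_fpu.ci_high


@pytest.fixture(scope="module")
def cohort():
    rng = np.random.default_rng(11)
    n = 40
    return (
        pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(n)],
                "age": rng.normal(47, 14, n),
                "sex": rng.choice(["male", "female"], n, p=[0.7, 0.3]),
                "lesion": rng.choice(["TBI", "hemorrhage"], n, p=[0.7, 0.3]),
                "duration_days": rng.uniform(60, 298, n),
                "crsr": rng.integers(5, 11, n),
                "group": ["control"] * 25 + ["tDCS"] * 15,
                "mgos": rng.integers(1, 7, n),
            }
        ).assign(improved=lambda d: d["mgos"] >= 3)
    )


class TestCohortTables:
    def test_baseline_table_rows_and_pvalues(self, cohort):
        table = baseline_table(cohort)
        assert set(table["variable"]) == {"age", "duration", "crsr", "sex_male", "lesion_tbi"}
        assert ((table["p"] >= 0) & (table["p"] <= 1)).all()

    def test_improvement_table_matches_direct_counts(self, cohort):
        table = improvement_table(cohort).set_index("group")
        for group in ("control", "tDCS"):
            sub = cohort[cohort["group"] == group]
            assert table.loc[group, "improved"] == sub["improved"].sum()
            assert table.loc[group, "rate_pct"] == improvement_rate(
                int(sub["improved"].sum()), len(sub)
            )

    def test_regression_frame_layout(self):
        design, _ = gen_regression_cohort(60, seed=8)
        frame = regression_frame(mgos_regression(design, dependent="mgos"))
        assert list(frame.columns) == [
            "predictor", "B", "se", "beta", "t", "p",
            "ci_low", "ci_high", "tolerance", "vif",
        ]
        assert frame.loc[0, "predictor"] == "(Constant)"
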