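"""Mixed-effects models: centering, the model sequence, OLS limit,
boundary reporting and centering invariance."""

import warnings

import numpy as np
import pandas as pd
import pytest

import actiflux as af
from actiflux.simulate import AffectDGPParams


def day_table(panel):
    return panel.assign(day_index=panel["day"])


@pytest.fixture(scope="module")
def medium_panel():
    dgp = AffectDGPParams(gamma30=0.3, var_sigma3=0.1)
    panel, _ = af.simulate_affect_panel(dgp, 60, 15, seed=11, pa_within_sd=0.1)
    return day_table(panel)


class TestDesign:
    def test_person_mean_centering_arithmetic(self):
        df = pd.DataFrame({
            "child_id": ["a"] * 3 + ["b"] * 3,
            "day_index": [0, 1, 2] * 2,
            "pa": [0.1, 0.2, 0.3, 0.5, 0.5, 0.5],
            "y": 1.0,
        })
        d = af.build_design(df, "y", "pa")
        a = d.data[d.data["group"] == "a"]
        assert np.allclose(a["pa_between"], 0.2)
        assert np.allclose(a["pa_within"], [-0.1, 0.0, 0.1])

    def test_within_deviations_sum_to_zero(self, medium_panel):
        d = af.build_design(medium_panel, "affect", "pa")
        sums = d.data.groupby("group")["pa_within"].sum()
        assert np.abs(sums).max() < 1e-10
        assert (d.data.groupby("group")["pa_between"].nunique() == 1).all()

    def test_constant_pa_flagged_degenerate(self):
        df = pd.DataFrame({
            "child_id": np.repeat(["a", "b"], 4),
            "day_index": np.tile(range(4), 2),
            "pa": 0.3,
            "y": np.random.default_rng(0).normal(size=8),
        })
        with pytest.warns(UserWarning, match="constant"):
            d = af.build_design(df, "y", "pa")
        assert d.degenerate_pa
        with pytest.raises(ValueError, match="daily-activity"):
            af.fit_hlm(d, "fixed_only")

    def test_listwise_deletion_and_minimums(self):
        df = pd.DataFrame({
            "child_id": ["a", "a", "b", "b"],
            "day_index": [0, 1, 0, 1],
            "pa": [0.1, np.nan, 0.2, 0.3],
            "y": [1.0, 2.0, 3.0, 4.0],
        })
        with pytest.raises(ValueError, match="at least 2 children"):
            af.build_design(df, "y", "pa")  # child a drops below 2 days


class TestFitting:
    def test_empty_model_recovers_variance_split(self):
        rng = np.random.default_rng(21)
        b = rng.normal(0, 1.0, size=(300, 1))
        e = rng.normal(0, np.sqrt(3.0), size=(300, 10))
        y = b + e
        df = pd.DataFrame({
            "child_id": np.repeat([f"c{i}" for i in range(300)], 10),
            "day_index": np.tile(range(10), 300),
            "pa": 0.0, "y": y.ravel(),
        })
        d = af.build_design(df, "y", "pa", allow_constant_pa=True)
        fit = af.fit_hlm(d, "empty")
        # REML should track the realized (empirical) variance components
        assert fit.var_sigma0 == pytest.approx(float(b.var(ddof=1)), rel=0.10)
        assert fit.var_epsilon == pytest.approx(float(e.var(ddof=1)), rel=0.05)

    def test_sequence_order_and_nesting(self, medium_panel):
        d = af.build_design(medium_panel, "affect", "pa")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fits = af.model_sequence(d)
        assert [f.model_tag for f in fits] == list(af.models.MODEL_TAGS)
        # under ML the richer model can only improve the deviance
        ml = [af.fit_hlm(d, t, reml=False) for t in ("fixed_only", "fixed_and_random")]
        # nesting, up to optimizer tolerance
        assert ml[0].neg2loglik >= ml[1].neg2loglik - 1e-3

    def test_strong_effect_detected(self):
        dgp = AffectDGPParams(gamma30=0.8, var_sigma3=0.0, var_epsilon=0.05)
        panel, _ = af.simulate_affect_panel(dgp, 100, 20, seed=31, pa_within_sd=0.1)
        d = af.build_design(day_table(panel), "affect", "pa")
        for tag in ("fixed_only", "fixed_and_random"):
            fit = af.fit_hlm(d, tag)
            assert fit.fixed.loc["daily_activity", "p"] < 0.05
            est, se = fit.fixed_effect("daily_activity")
            assert est == pytest.approx(0.8, abs=3 * se)

    def test_boundary_variance_reported_as_zero_na(self):
        # truth var_sigma3 = 0; this replicate's REML estimate lands on
        # the boundary, exercising the "0.00 (NA)" reporting convention
        dgp = AffectDGPParams(gamma30=0.0, var_sigma3=0.0, var_epsilon=0.02,
                              var_sigma1=0.0)
        panel, _ = af.simulate_affect_panel(dgp, 80, 10, seed=44)
        d = af.build_design(day_table(panel), "affect", "pa")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = af.fit_hlm(d, "fixed_and_random")
        assert fit.var_sigma3 == 0.0
        assert np.isnan(fit.var_se["var_sigma3"])
        table = af.results_table([fit])
        assert "(NA)" in table.loc["daily_activity_var", "fixed_and_random"]

    def test_ols_limit_matches_ols(self, medium_panel):
        import statsmodels.formula.api as smf

        d = af.build_design(medium_panel, "affect", "pa")
        fit = af.fit_hlm(d, "fixed_only", include_random=False)
        ref = smf.ols("y ~ trend + pa_between + pa_within", data=d.data).fit()
        assert np.allclose(fit.fixed["estimate"].to_numpy(), ref.params.to_numpy(),
                           atol=1e-6)

    def test_centering_invariance(self, medium_panel):
        d1 = af.build_design(medium_panel, "affect", "pa")
        shifted = medium_panel.assign(pa=medium_panel["pa"] + 5.0)
        d2 = af.build_design(shifted, "affect", "pa")
        f1 = af.fit_hlm(d1, "fixed_and_random")
        f2 = af.fit_hlm(d2, "fixed_and_random")
        assert f1.fixed.loc["daily_activity", "estimate"] == pytest.approx(
            f2.fixed.loc["daily_activity", "estimate"], abs=1e-8)
        assert f1.var_sigma3 == pytest.approx(f2.var_sigma3, abs=1e-8)

    def test_unknown_tag_rejected(self, medium_panel):
        d = af.build_design(medium_panel, "affect", "pa")
        with pytest.raises(ValueError, match="model tag"):
            af.fit_hlm(d, "saturated")


class TestResultsTable:
    def test_table_mirrors_model_columns(self, medium_panel):
        d = af.build_design(medium_panel, "affect", "pa")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fits = af.model_sequence(d)
        table = af.results_table(fits)
        assert list(table.columns) == list(af.models.MODEL_TAGS)
        assert table.loc["trend", "empty"] == ""
        assert table.loc["daily_activity_var", "fixed_only"] == ""
        text = af.format_results_text(fits)
        assert "REML" in text and "neg2loglik" in text
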