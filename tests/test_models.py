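"""Mixed-model machinery: standardization, estimation, marginal means,
simple slopes and the model suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import patsy

from gazebias.models import (
    MixedModel,
    ModelError,
    ModelSpec,
    fit_lmm,
    run_model_suite,
    standardize,
)


def _lmm_data(rng, n_sub=40, n_per=12, beta_x=0.0, beta_f=0.0, beta_xf=0.0, u_sd=0.5):
    """Balanced two-level-factor LMM data with known standardized effects."""
    sid = np.repeat([f"s{i}" for i in range(n_sub)], n_per)
    x = np.repeat(rng.normal(size=n_sub), n_per)
    f = np.tile(["a", "b"], n_sub * n_per // 2)
    code = np.where(np.array(f) == "a", 1.0, -1.0)
    u = np.repeat(rng.normal(0, u_sd, n_sub), n_per)
    y = beta_x * x + beta_f * code + beta_xf * x * code + u + rng.normal(size=n_sub * n_per)
    return pd.DataFrame({"subject_id": sid, "x": x, "f": f, "y": y})


class TestStandardize:
    def test_basic_and_round_trip(self, rng):
        df = pd.DataFrame({"v": rng.normal(5.0, 2.0, 100)})
        out, rec = standardize(df, ["v"])
        assert out["v"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out["v"].std(ddof=1) == pytest.approx(1.0, abs=1e-12)
        mean, sd = rec.scales["v"]
        value = (7.0 - mean) / sd
        assert rec.inverse("v", [value])[0] == pytest.approx(7.0)
        back = rec.inverse("v", out["v"].to_numpy())
        np.testing.assert_allclose(back, df["v"].to_numpy(), atol=1e-10)

    def test_idempotent_within_tolerance(self, rng):
        df = pd.DataFrame({"v": rng.normal(size=200)})
        once, _ = standardize(df, ["v"])
        twice, _ = standardize(once, ["v"])
        np.testing.assert_allclose(once["v"], twice["v"], atol=1e-10)

    def test_zero_variance_names_variable(self):
        with pytest.raises(ModelError, match="flatline"):
            standardize(pd.DataFrame({"flatline": [1.0] * 5, "ok": [1.0, 2.0, 3.0, 4.0, 5.0]}), ["ok", "flatline"])


class TestFitLmm:
    def test_planted_effect_recovery(self, rng):
        """A planted standardized emotion-sized effect (0.37) is recovered."""
        df = _lmm_data(rng, n_sub=60, n_per=16, beta_f=0.37)
        fit = MixedModel("y ~ x * C(f, Sum)", df, standardize_vars=("y", "x")).fit()
        fe = fit.fixed_effects().set_index("term")
        est = fe.loc["C(f, Sum)[S.a]", "estimate"]
        se = fe.loc["C(f, Sum)[S.a]", "se"]
        # the DV is standardized, so the planted effect shrinks by sd(y)
        target = 0.37 / df["y"].std(ddof=1)
        assert est == pytest.approx(target, abs=4 * se)
        assert fe.loc["C(f, Sum)[S.a]", "p"] < 0.001

    def test_null_data_calibration(self):
        """On null data no more than a few terms reach significance and the
        standardized coefficients stay near zero."""
        rng = np.random.default_rng(7)
        n_sig, n_terms = 0, 0
        for _ in range(20):
            df = _lmm_data(rng, n_sub=50, n_per=10)
            fit = MixedModel("y ~ x * C(f, Sum)", df, standardize_vars=("y", "x")).fit()
            fe = fit.fixed_effects()
            body = fe.loc[fe["term"] != "Intercept"]
            assert (body["estimate"].abs() < 0.25).all()
            n_sig += int((body["p"] < 0.05).sum())
            n_terms += len(body)
        assert n_sig / n_terms < 0.15

    def test_zero_random_variance_boundary(self, rng):
        df = _lmm_data(rng, u_sd=0.0)
        fit = MixedModel("y ~ x * C(f, Sum)", df, standardize_vars=("y", "x")).fit()
        assert fit.sigma2_subject < 0.05
        assert np.isfinite(fit.fixed_effects()["p"]).all()

    def test_satterthwaite_df_between_vs_within(self, rng):
        """Between-subject terms get near-subject df; within-subject terms get
        near-observation df."""
        df = _lmm_data(rng, n_sub=40, n_per=12, u_sd=1.0)
        fit = MixedModel("y ~ x * C(f, Sum)", df, standardize_vars=("y", "x")).fit()
        fe = fit.fixed_effects().set_index("term")
        assert fe.loc["x", "df_method"] == "satterthwaite"
        assert fe.loc["x", "df"] < 80  # between-subject: close to n_sub
        assert fe.loc["C(f, Sum)[S.a]", "df"] > 200  # within-subject

    def test_single_level_factor_rejected(self, rng):
        df = _lmm_data(rng)
        df["f"] = "a"
        with pytest.raises(ModelError, match="single level"):
            MixedModel("y ~ x * C(f, Sum)", df)

    def test_reproducible_estimates(self, rng):
        df = _lmm_data(rng, beta_x=0.3)
        a = MixedModel("y ~ x * C(f, Sum)", df, standardize_vars=("y", "x")).fit()
        b = MixedModel("y ~ x * C(f, Sum)", df, standardize_vars=("y", "x")).fit()
        np.testing.assert_allclose(a.params, b.params, rtol=1e-10)

    def test_empty_subset_errors(self, rng):
        df = _lmm_data(rng)
        spec = ModelSpec("y ~ x", data_filter=lambda d: d.iloc[0:0])
        with pytest.raises(ModelError, match="empty"):
            fit_lmm(spec, df)


@pytest.fixture(scope="module")
def fit():
    rng = np.random.default_rng(11)
    df = _lmm_data(rng, n_sub=40, n_per=12, beta_x=0.2, beta_f=0.3, beta_xf=0.25)
    return MixedModel("y ~ x * C(f, Sum)", df, standardize_vars=("y", "x")).fit()


class TestMarginalMachinery:

    def test_contrast_two_routes_agree(self, fit):
        """Explicit linear combination equals prediction averaging."""
        grid = pd.DataFrame({"x": np.linspace(-1, 1, 9)})
        rows_a = pd.DataFrame({"x": grid["x"], "f": "a"})
        rows_b = pd.DataFrame({"x": grid["x"], "f": "b"})
        (ma,) = patsy.build_design_matrices([fit.model.design_info], rows_a)
        (mb,) = patsy.build_design_matrices([fit.model.design_info], rows_b)
        direct = float(np.asarray(ma).mean(axis=0) @ fit.params - np.asarray(mb).mean(axis=0) @ fit.params)
        ce = fit.emmeans_over_range("f", "a", "b", covariate="x", covariate_values=grid["x"].tolist())
        assert ce.estimate == pytest.approx(direct, abs=1e-10)

    def test_collapsibility_without_interaction(self):
        rng = np.random.default_rng(13)
        df = _lmm_data(rng, beta_x=0.2, beta_f=0.3, beta_xf=0.0)
        fit = MixedModel("y ~ x + C(f, Sum)", df, standardize_vars=("y", "x")).fit()
        plain = fit.emmeans_over_range("f", "a", "b")
        averaged = fit.emmeans_over_range("f", "a", "b", covariate="x", covariate_values=[-2.0, 0.0, 2.0])
        assert plain.estimate == pytest.approx(averaged.estimate, abs=1e-10)

    def test_planted_moderation_separates_ranges(self, fit):
        """With a planted x-by-f interaction the contrast differs across
        disjoint x ranges in the planted direction."""
        low = fit.emmeans_over_range("f", "a", "b", covariate="x", covariate_values=[-2.0, -1.0])
        high = fit.emmeans_over_range("f", "a", "b", covariate="x", covariate_values=[1.0, 2.0])
        assert high.estimate > low.estimate  # beta_xf > 0 planted

    def test_linearity_in_fixed_effects(self, fit):
        """Doubling all fixed effects doubles every marginal estimate."""
        ce = fit.emmeans_over_range("f", "a", "b", covariate="x", covariate_values=[0.0, 1.0])
        slopes = fit.simple_slopes("x", "x", [0.0])
        original = fit.params.copy()
        try:
            fit.params = original * 2
            ce2 = fit.emmeans_over_range("f", "a", "b", covariate="x", covariate_values=[0.0, 1.0])
            sl2 = fit.simple_slopes("x", "x", [0.0])
        finally:
            fit.params = original
        assert ce2.estimate == pytest.approx(2 * ce.estimate, abs=1e-10)
        assert sl2["slope"].iloc[0] == pytest.approx(2 * slopes["slope"].iloc[0], abs=1e-10)

    def test_simple_slope_recentering_identity(self):
        """The slope at moderator level L from the linear-combination route
        equals the main-effect coefficient after recentering the moderator."""
        rng = np.random.default_rng(17)
        df = _lmm_data(rng, beta_x=0.2, beta_xf=0.3)
        df["m"] = df["x"]  # moderator
        df["w"] = rng.normal(size=len(df))
        data = df.assign(w=df["w"])
        level = 0.8
        fit = MixedModel("y ~ w * m", data).fit()
        slope = fit.simple_slopes("w", "m", [level])["slope"].iloc[0]
        recentered = data.assign(m=data["m"] - level)
        fit2 = MixedModel("y ~ w * m", recentered).fit()
        beta_w = fit2.fixed_effects().set_index("term").loc["w", "estimate"]
        assert slope == pytest.approx(beta_w, abs=1e-5)

    def test_zero_interaction_constant_slopes(self, fit):
        original = fit.params.copy()
        names = fit.model.exog_names
        try:
            params = original.copy()
            params[names.index("x:C(f, Sum)[S.a]")] = 0.0
            fit.params = params
            sl = fit.simple_slopes("x", "x", [-1.0, 1.0], by_factor="f")
            by_level = sl.groupby("factor_level")["slope"].nunique()
        finally:
            fit.params = original
        # with the interaction zeroed the slope no longer depends on f
        pivot = sl.pivot(index="moderator_level", columns="factor_level", values="slope")
        np.testing.assert_allclose(pivot["a"], pivot["b"], atol=1e-12)

    def test_unknown_variable_rejected(self, fit):
        with pytest.raises(ModelError):
            fit.simple_slopes("nope", "x", [0.0])
        with pytest.raises(ModelError):
            fit.emmeans_over_range("f", "a", "b", covariate="nope")


class TestModelSuite:
    def test_suite_structure_and_recovery(self, study_qc, study):
        report = run_model_suite(study_qc.kept, study.participants)
        assert set(report.fits) == {"M1", "M1b", "M2", "M3_control", "M3_mdd", "M4"}
        # M1: the planted overall emotional bias shows as an emotion main effect
        an = report.fits["M1"].anova().set_index("term")
        assert an.loc["C(image_emotion, Sum)", "p"] < 0.001
        # M2 follow-up: contrasts computed over both BDI ranges
        assert set(report.bias_contrasts) == {"control", "mdd"}
        # M3 control: slopes reported at every requested level and condition
        slopes = report.age_slopes["control"]
        assert len(slopes) == 5 * 2
        assert {"positive-neutral", "negative-neutral"} == set(slopes["factor_level"])
        # report serialises
        frame = report.to_frame()
        assert {"model", "kind", "term"}.issubset(frame.columns)
        assert len(report.summary()) > 100

    def test_bias_dv_switch(self, study_qc, study):
        report = run_model_suite(study_qc.kept, study.participants, dv="bias")
        assert report.fits["M4"].n_obs > 0
        with pytest.raises(ModelError):
            run_model_suite(study_qc.kept, study.participants, dv="nope")

    def test_single_condition_subset_errors(self, study_qc, study):
        kept = study_qc.kept.loc[study_qc.kept["condition"] == "positive-neutral"]
        with pytest.raises(ModelError):
            run_model_suite(kept, study.participants)
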