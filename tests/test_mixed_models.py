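import numpy as np
import pandas as pd
import pytest

from broilerfeed import (
    ModelSpec,
    backward_select,
    build_model_table,
    default_candidate_terms,
    fit_lmm,
    r2_nakagawa,
    simulate_model_table,
)
from broilerfeed.mixed_models import build_design, contrast_matrix


class TestDesign:
    def test_contrast_columns_sum_to_zero(self):
        assert contrast_matrix(("female", "male")).sum() == 0

    def test_factor_coding(self):
        df = pd.DataFrame({"sex": ["female", "male"], "age_days": [20, 21]})
        X, names = build_design(df, ("sex", "age_days"))
        assert names == ["Intercept", "sex", "age_days"]
        np.testing.assert_array_equal(X[:, 1], [1.0, -1.0])

    def test_interaction_column_is_product(self):
        df = pd.DataFrame({"sex": ["female", "male"], "age_days": [20.0, 21.0]})
        X, _ = build_design(df, ("sex", "age_days", "sex:age_days"))
        np.testing.assert_array_equal(X[:, 3], X[:, 1] * X[:, 2])

    def test_unknown_level_raises(self):
        df = pd.DataFrame({"sex": ["unknown"], "age_days": [20]})
        with pytest.raises(ValueError, match="unknown"):
            build_design(df, ("sex",))

    def test_marginality_enforced_in_spec(self):
        with pytest.raises(ValueError, match="marginality"):
            ModelSpec("nfv", ("age_days", "age_days:sex"))

    def test_default_candidates(self):
        terms = default_candidate_terms()
        assert len(terms) == 15  # 5 mains + 10 two-way interactions
        assert "age_days:sex" in terms


def _toy_balanced():
    # 2 birds x 2 obs; sum-to-zero coded factor balanced across birds
    return pd.DataFrame({
        "bird_id": ["a", "a", "b", "b"],
        "sex": ["female", "female", "male", "male"],
        "nfv": [10.0, 12.0, 20.0, 26.0],
    })


class TestFitLmm:
    def test_balanced_intercept_is_mean_of_group_means(self):
        fit = fit_lmm(_toy_balanced(), ModelSpec("nfv", ("sex",)))
        # group means 11 and 23 -> grand intercept 17 under sum-to-zero coding
        assert fit.terms.loc["Intercept", "estimate"] == pytest.approx(17.0)
        assert fit.terms.loc["sex", "estimate"] == pytest.approx(-6.0)

    def test_matches_statsmodels_mixedlm(self):
        smf = pytest.importorskip("statsmodels.formula.api")
        df = simulate_model_table(
            "mfbd", {"age_days": 2.192, "start_bw_g": 0.130, "bw_gain_g_d": -0.390},
            6.198, 223.5, 900.0, rng=42)
        fit = fit_lmm(df, ModelSpec("mfbd", ("age_days", "start_bw_g", "bw_gain_g_d")))
        ref = smf.mixedlm("mfbd_s ~ age_days + start_bw_g + bw_gain_g_d",
                          df, groups=df["bird_id"]).fit(reml=True)
        np.testing.assert_allclose(fit.terms["estimate"], ref.fe_params, rtol=1e-5)
        np.testing.assert_allclose(fit.terms["se"], ref.bse_fe, rtol=1e-3)
        assert fit.var_id == pytest.approx(float(ref.cov_re.iloc[0, 0]), rel=1e-3)
        assert fit.var_resid == pytest.approx(float(ref.scale), rel=1e-3)

    def test_recovers_generating_coefficients(self):
        df = simulate_model_table("nfv", {"age_days": -2.212}, 111.4, 232.4, 368.3, rng=1)
        fit = fit_lmm(df, ModelSpec("nfv", ("age_days",)))
        est = fit.terms.loc["age_days"]
        assert abs(est["estimate"] - (-2.212)) < 3 * est["se"]
        assert 50 < fit.var_id < 600
        assert 200 < fit.var_resid < 600

    def test_zero_var_id_degenerate(self):
        df = simulate_model_table("nfv", {"age_days": -2.0}, 100.0, 0.0, 100.0, rng=2)
        fit = fit_lmm(df, ModelSpec("nfv", ("age_days",)))
        assert fit.var_id < 5.0
        assert fit.r2_conditional - fit.r2_marginal < 0.05

    def test_variance_component_invariants(self):
        df = simulate_model_table("ndf", {"age_days": -0.4}, 20.0, 1.2, 4.6, rng=3)
        fit = fit_lmm(df, ModelSpec("ndf", ("age_days",)))
        assert fit.var_id >= 0
        assert fit.var_resid > 0
        assert fit.r2_marginal <= fit.r2_conditional <= 1

    def test_flipping_factor_labels_flips_sign_only(self):
        df = simulate_model_table("nfv", {"age_days": -2.0, "sex": 4.0},
                                  100.0, 50.0, 100.0, rng=4)
        fit = fit_lmm(df, ModelSpec("nfv", ("age_days", "sex")))
        flipped = df.assign(sex=df["sex"].map({"male": "female", "female": "male"}))
        fit2 = fit_lmm(flipped, ModelSpec("nfv", ("age_days", "sex")))
        assert fit2.terms.loc["sex", "estimate"] == pytest.approx(
            -fit.terms.loc["sex", "estimate"])
        assert fit2.terms.loc["age_days", "estimate"] == pytest.approx(
            fit.terms.loc["age_days", "estimate"])
        assert fit2.terms.loc["Intercept", "estimate"] == pytest.approx(
            fit.terms.loc["Intercept", "estimate"])
        assert fit2.var_id == pytest.approx(fit.var_id, rel=1e-6)

    def test_missing_response_rows_dropped(self):
        df = simulate_model_table("nfv", {"age_days": -2.0}, 100.0, 50.0, 100.0, rng=5)
        df.loc[df.index[:10], "nfv"] = np.nan
        fit = fit_lmm(df, ModelSpec("nfv", ("age_days",)))
        assert fit.n_obs == len(df) - 10

    def test_missing_covariate_errors(self):
        df = simulate_model_table("nfv", {"age_days": -2.0}, 100.0, 50.0, 100.0, rng=5)
        df.loc[df.index[0], "age_days"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            fit_lmm(df, ModelSpec("nfv", ("age_days",)))

    def test_too_few_birds_errors(self):
        df = _toy_balanced().iloc[:2]
        with pytest.raises(ValueError, match="2 birds"):
            fit_lmm(df, ModelSpec("nfv", ("sex",)))

    def test_singular_design_names_terms(self):
        df = simulate_model_table("nfv", {"age_days": -2.0}, 100.0, 50.0, 100.0, rng=6)
        df["bw_gain_g_d"] = 2.0 * df["start_bw_g"] + 1.0
        with pytest.raises(np.linalg.LinAlgError, match="bw_gain_g_d|start_bw_g"):
            fit_lmm(df, ModelSpec("nfv", ("age_days", "start_bw_g", "bw_gain_g_d")))


class TestR2:
    def test_closed_form(self):
        assert r2_nakagawa(1.0, 1.0, 2.0) == (0.25, 0.50)

    def test_all_null_betas_marginal_near_zero(self):
        df = simulate_model_table("nfv", {}, 100.0, 50.0, 100.0, rng=7)
        fit = fit_lmm(df, ModelSpec("nfv", ("age_days",)))
        assert fit.r2_marginal < 0.02

    def test_degenerate_components(self):
        assert r2_nakagawa(0.0, 0.0, 0.0) == (0.0, 0.0)

    def test_affine_rescaling_invariance(self):
        df = simulate_model_table("mfbd", {"age_days": 2.0, "start_bw_g": 0.1},
                                  10.0, 200.0, 900.0, rng=8)
        fit = fit_lmm(df, ModelSpec("mfbd", ("age_days", "start_bw_g")))
        scaled = df.assign(start_bw_g=df["start_bw_g"] * 10 - 500)
        fit2 = fit_lmm(scaled, ModelSpec("mfbd", ("age_days", "start_bw_g")))
        assert fit2.r2_marginal == pytest.approx(fit.r2_marginal, rel=1e-6)
        assert fit2.r2_conditional == pytest.approx(fit.r2_conditional, rel=1e-6)

    def test_simulation_close_to_plugin_truth(self):
        # var_fixed from the age spread, components known
        betas = {"age_days": -2.212}
        df = simulate_model_table("nfv", betas, 111.4, 232.4, 368.3, rng=9)
        fit = fit_lmm(df, ModelSpec("nfv", ("age_days",)))
        var_fixed_truth = np.var(betas["age_days"] * df["age_days"].to_numpy(), ddof=1)
        truth = r2_nakagawa(var_fixed_truth, 232.4, 368.3)
        assert fit.r2_marginal == pytest.approx(truth[0], abs=0.05)
        assert fit.r2_conditional == pytest.approx(truth[1], abs=0.12)


class TestBackwardSelect:
    def test_alpha_one_keeps_full_model(self):
        df = simulate_model_table("nfv", {"age_days": -2.0}, 100.0, 50.0, 100.0, rng=10)
        spec = ModelSpec("nfv", alpha=1.0)
        final, fit, log = backward_select(df, spec)
        assert final.fixed_terms == spec.fixed_terms
        assert log.empty

    def test_strong_age_only_signal(self):
        df = simulate_model_table("nfv", {"age_days": -2.212}, 111.4, 232.4, 368.3, rng=11)
        final, fit, log = backward_select(df, ModelSpec("nfv"))
        assert final.fixed_terms == ("age_days",)

    def test_elimination_log_is_valid_derivation(self):
        df = simulate_model_table("nfv", {"age_days": -2.212}, 111.4, 232.4, 368.3, rng=12)
        spec = ModelSpec("nfv")
        final, _, log = backward_select(df, spec)
        assert (log["p"] > spec.alpha).all()
        assert list(log["step"]) == list(range(1, len(log) + 1))
        removed = set(log["term"])
        assert removed | set(final.fixed_terms) == set(spec.fixed_terms)

    def test_mains_removed_only_after_their_interactions(self):
        df = simulate_model_table("nfv", {}, 100.0, 50.0, 100.0, rng=13)
        _, _, log = backward_select(df, ModelSpec("nfv"))
        seen_removal = {}
        for _, row in log.iterrows():
            term = row["term"]
            if ":" not in term:
                # every interaction containing this main must already be gone
                for other in default_candidate_terms():
                    if ":" in other and term in other.split(":"):
                        assert other in seen_removal or other not in log["term"].values
            seen_removal[term] = row["step"]

    def test_result_fit_matches_direct_fit(self):
        df = simulate_model_table("ndf", {"age_days": -0.396, "start_bw_g": -0.033,
                                          "bw_gain_g_d": 0.084}, 51.0, 1.155, 4.586, rng=14)
        final, fit, _ = backward_select(df, ModelSpec("ndf"))
        direct = fit_lmm(df, final)
        pd.testing.assert_frame_equal(fit.terms, direct.terms)


def test_build_model_table_joins_on_bird():
    desc = pd.DataFrame({"bird_id": ["a", "b"], "age_days": [20, 20],
                         "nfv": [5, 6], "mfbd_s": [10.0, 12.0], "ndf": [2, 3]})
    covs = pd.DataFrame({"bird_id": ["a"], "sex": ["male"], "gait_class": ["GG"],
                         "start_bw_g": [600.0], "bw_gain_g_d": [90.0]})
    data = build_model_table(desc, covs)
    assert len(data) == 1
    assert data.iloc[0]["bird_id"] == "a"
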