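import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import t as t_dist

from quercinus.lmm import (
    DesignError,
    GroupingError,
    ModelSpec,
    estimated_marginal_means,
    fit_lmm,
    tukey_contrasts,
)


def _two_group_frame():
    """Balanced two-group data, one record per individual."""
    rng = np.random.default_rng(3)
    y = np.concatenate([rng.normal(10, 1, 8), rng.normal(13, 1, 8)])
    return pd.DataFrame(
        {
            "y": y,
            "g": ["A"] * 8 + ["B"] * 8,
            "id": [f"i{k}" for k in range(16)],
        }
    )


SPEC_G = ModelSpec(response="y", group="id", factors={"g": ["A", "B"]})


class TestREMLCore:
    def test_one_record_per_individual_reduces_to_ols_group_means(self):
        df = _two_group_frame()
        fit = fit_lmm(df, SPEC_G)
        assert fit.sigma2_group == 0.0
        mean_a = df.loc[df.g == "A", "y"].mean()
        mean_b = df.loc[df.g == "B", "y"].mean()
        assert fit.params["(Intercept)"] == pytest.approx(mean_a, abs=1e-9)
        assert fit.params["(Intercept)"] + fit.params["g[B]"] == pytest.approx(
            mean_b, abs=1e-9
        )

    def test_reml_optimum_beats_1000_point_variance_ratio_grid(self):
        # 6 observations on 3 individuals
        df = pd.DataFrame(
            {
                "y": [1.0, 1.4, 3.1, 3.3, 5.2, 4.8],
                "x": [0.1, 0.3, 0.2, 0.5, 0.4, 0.6],
                "id": ["a", "a", "b", "b", "c", "c"],
            }
        )
        spec = ModelSpec(response="y", group="id", numeric=["x"])
        fit = fit_lmm(df, spec)

        # independent grid-search oracle over the variance ratio
        from quercinus.lmm import _reml_criterion

        X = np.column_stack([np.ones(6), df["x"]])
        y = df["y"].to_numpy()
        gi = [np.array([0, 1]), np.array([2, 3]), np.array([4, 5])]
        gs = [2, 2, 2]
        grid = np.concatenate([[0.0], np.logspace(-6, 6, 999)])
        grid_best = min(_reml_criterion(X, y, gi, gs, lam) for lam in grid)
        ours = _reml_criterion(X, y, gi, gs, fit.lam)
        assert ours <= grid_best + 1e-6

    def test_matches_statsmodels_mixedlm_oracle(self):
        """Independent cross-check: REML estimates agree with MixedLM."""
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(11)
        n_ind, per = 20, 3
        b = np.repeat(rng.normal(0, 1.5, n_ind), per)
        x = rng.normal(0, 1, n_ind * per)
        y = 2.0 + 0.7 * x + b + rng.normal(0, 1, n_ind * per)
        df = pd.DataFrame(
            {"y": y, "x": x, "id": np.repeat([f"i{k}" for k in range(n_ind)], per)}
        )
        fit = fit_lmm(df, ModelSpec(response="y", group="id", numeric=["x"]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            oracle = smf.mixedlm("y ~ x", df, groups=df["id"]).fit(reml=True)
        assert fit.params["(Intercept)"] == pytest.approx(
            oracle.fe_params["Intercept"], abs=1e-5
        )
        assert fit.params["x"] == pytest.approx(oracle.fe_params["x"], abs=1e-5)
        assert fit.sigma2 == pytest.approx(oracle.scale, rel=1e-4)
        assert fit.sigma2_group == pytest.approx(
            float(oracle.cov_re.iloc[0, 0]), rel=1e-3, abs=1e-6
        )

    def test_response_shift_moves_only_the_intercept(self):
        df = _two_group_frame()
        base = fit_lmm(df, SPEC_G)
        shifted = df.assign(y=df["y"] + 7.5)
        fit = fit_lmm(shifted, SPEC_G)
        assert fit.params["(Intercept)"] == pytest.approx(
            base.params["(Intercept)"] + 7.5, abs=1e-9
        )
        assert fit.params["g[B]"] == pytest.approx(base.params["g[B]"], abs=1e-9)

    def test_row_permutation_invariance(self):
        df = _two_group_frame()
        base = fit_lmm(df, SPEC_G)
        perm = df.sample(frac=1.0, random_state=9)
        fit = fit_lmm(perm, SPEC_G)
        assert np.allclose(fit.params, base.params, atol=1e-9)
        assert fit.sigma2 == pytest.approx(base.sigma2, abs=1e-9)

    def test_single_individual_is_a_grouping_error(self):
        df = pd.DataFrame({"y": [1.0, 2.0], "id": ["a", "a"]})
        with pytest.raises(GroupingError):
            fit_lmm(df, ModelSpec(response="y", group="id"))

    def test_rank_deficient_design_names_aliased_terms(self):
        df = _two_group_frame()
        df["x"] = (df["g"] == "B").astype(float)  # aliased with the factor
        spec = ModelSpec(response="y", group="id", numeric=["x"], factors={"g": None})
        with pytest.raises(DesignError, match="aliased"):
            fit_lmm(df, spec)

    def test_zero_variance_predictions_equal_ols(self):
        df = _two_group_frame()
        fit = fit_lmm(df, SPEC_G)
        assert fit.lam == 0.0
        X = fit.X
        beta_ols, *_ = np.linalg.lstsq(X, fit.y, rcond=None)
        assert np.allclose(fit.fitted(), X @ beta_ols, atol=1e-9)


class TestEMMs:
    def test_balanced_one_factor_emms_equal_cell_means(self):
        df = _two_group_frame()
        fit = fit_lmm(df, SPEC_G)
        emm = estimated_marginal_means(fit, ["g"]).table
        for level in ("A", "B"):
            raw = df.loc[df.g == level, "y"].mean()
            assert emm.loc[emm.g == level, "emmean"].iloc[0] == pytest.approx(
                raw, abs=1e-9
            )

    def test_emms_invariant_to_covariate_centring(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            {
                "y": rng.normal(10, 1, 12),
                "x": rng.normal(50, 5, 12),
                "g": ["A", "B"] * 6,
                "id": [f"i{k}" for k in range(12)],
            }
        )
        spec = ModelSpec(response="y", group="id", numeric=["x"], factors={"g": None})
        emm1 = estimated_marginal_means(fit_lmm(df, spec), ["g"]).table
        centred = df.assign(x=df["x"] - df["x"].mean())
        emm2 = estimated_marginal_means(fit_lmm(centred, spec), ["g"]).table
        assert np.allclose(emm1["emmean"], emm2["emmean"], atol=1e-9)

    def test_unbalanced_two_factor_grid_average_matches_hand_oracle(self):
        # cell counts 3/1/1/3; hand oracle: OLS fit, then uniform average of
        # the four cell predictions over the non-requested factor
        y = [1.0, 1.2, 1.1, 2.0, 3.0, 4.1, 4.0, 3.9]
        f1 = ["A", "A", "A", "A", "B", "B", "B", "B"]
        f2 = ["u", "u", "u", "v", "u", "v", "v", "v"]
        df = pd.DataFrame(
            {"y": y, "f1": f1, "f2": f2, "id": [f"i{k}" for k in range(8)]}
        )
        spec = ModelSpec(
            response="y", group="id", factors={"f1": None, "f2": None}
        )
        fit = fit_lmm(df, spec)
        emm = estimated_marginal_means(fit, ["f1"]).table

        X = np.column_stack(
            [
                np.ones(8),
                (np.array(f1) == "B").astype(float),
                (np.array(f2) == "v").astype(float),
            ]
        )
        beta, *_ = np.linalg.lstsq(X, np.array(y), rcond=None)
        oracle_a = beta[0] + 0.5 * beta[2]
        oracle_b = beta[0] + beta[1] + 0.5 * beta[2]
        assert emm.loc[emm.f1 == "A", "emmean"].iloc[0] == pytest.approx(
            oracle_a, abs=1e-9
        )
        assert emm.loc[emm.f1 == "B", "emmean"].iloc[0] == pytest.approx(
            oracle_b, abs=1e-9
        )

    def test_unknown_factor_rejected(self):
        fit = fit_lmm(_two_group_frame(), SPEC_G)
        with pytest.raises(ValueError, match="not in model"):
            estimated_marginal_means(fit, ["nope"])


class TestTukey:
    def test_k2_adjusted_p_equals_unadjusted_t_test_p(self):
        df = _two_group_frame()
        fit = fit_lmm(df, SPEC_G)
        emm = estimated_marginal_means(fit, ["g"])
        (con,) = tukey_contrasts(emm)
        expected = 2 * t_dist.sf(abs(con.t), con.df)
        assert con.p_tukey == pytest.approx(expected, abs=1e-8)
        assert con.p_tukey == pytest.approx(con.p_unadjusted, abs=1e-8)

    def test_k3_adjusted_p_never_below_unadjusted(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(
            {
                "y": rng.normal(10, 1, 18) + np.repeat([0.0, 0.6, 1.2], 6),
                "g": np.repeat(["A", "B", "C"], 6),
                "id": [f"i{k}" for k in range(18)],
            }
        )
        fit = fit_lmm(df, ModelSpec(response="y", group="id", factors={"g": None}))
        for con in tukey_contrasts(estimated_marginal_means(fit, ["g"])):
            assert con.p_tukey >= con.p_unadjusted - 1e-12
            assert 0.0 <= con.p_tukey <= 1.0

    def test_identical_level_means_give_p_of_one(self):
        df = pd.DataFrame(
            {
                "y": [5.0, 6.0, 5.0, 6.0, 5.0, 6.0],
                "g": np.repeat(["A", "B", "C"], 2),
                "id": [f"i{k}" for k in range(6)],
            }
        )
        fit = fit_lmm(df, ModelSpec(response="y", group="id", factors={"g": None}))
        for con in tukey_contrasts(estimated_marginal_means(fit, ["g"])):
            assert con.p_tukey == pytest.approx(1.0, abs=1e-6)

    def test_factor_level_reordering_only_relabels(self):
        df = _two_group_frame()
        fit1 = fit_lmm(df, ModelSpec(response="y", group="id", factors={"g": ["A", "B"]}))
        fit2 = fit_lmm(df, ModelSpec(response="y", group="id", factors={"g": ["B", "A"]}))
        e1 = estimated_marginal_means(fit1, ["g"]).table.set_index("g")["emmean"]
        e2 = estimated_marginal_means(fit2, ["g"]).table.set_index("g")["emmean"]
        assert e1["A"] == pytest.approx(e2["A"], abs=1e-9)
        assert e1["B"] == pytest.approx(e2["B"], abs=1e-9)
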