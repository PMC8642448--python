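"""Weight estimation and model comparison, cross-checked against
independent oracles (normal equations; statsmodels MixedLM)."""

import numpy as np
import pandas as pd
import pytest

from infoseek import choice_models as cm
from infoseek import utility_construction as uc
from infoseek.choice_models import (
    ModelSpec,
    compare_models,
    enumerate_model_space,
    fit_mixed_model,
    fit_subject_weights,
)


def _util_frame(pid, U, y, timepoint="T1"):
    n = len(y)
    return pd.DataFrame({
        "participant_id": pid, "timepoint": timepoint,
        "item_id": [f"i{k}" for k in range(n)],
        "choice": y,
        "instrumental": U[:, 0], "hedonic": U[:, 1], "cognitive": U[:, 2],
    })


class TestSubjectWeights:
    def test_noiseless_linear_data_interpolated(self):
        rng = np.random.default_rng(0)
        U = rng.normal(size=(20, 3))
        y = 1.0 + 0.5 * U[:, 0] + 0.2 * U[:, 1] + 0.1 * U[:, 2]
        w, flagged = fit_subject_weights(_util_frame("s", U, y))
        assert not flagged
        row = w.iloc[0]
        np.testing.assert_allclose(
            [row["intercept"], row["beta_instrumental"], row["beta_hedonic"],
             row["beta_cognitive"]], [1.0, 0.5, 0.2, 0.1], atol=1e-12)
        assert row["r_squared"] == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = rng.integers(6, 40)
            U = rng.normal(size=(n, 3))
            y = rng.normal(size=n)
            w, _ = fit_subject_weights(_util_frame("s", U, y))
            X = np.column_stack([np.ones(n), U])
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            np.testing.assert_allclose(
                w[["intercept", "beta_instrumental", "beta_hedonic",
                   "beta_cognitive"]].to_numpy()[0], beta, atol=1e-10)

    def test_constant_column_flagged(self):
        rng = np.random.default_rng(1)
        U = rng.normal(size=(12, 3))
        U[:, 2] = 1.3
        w, flagged = fit_subject_weights(
            _util_frame("s", U, rng.normal(size=12)))
        assert flagged == [("s", "T1")]
        assert len(w) == 0

    def test_slopes_invariant_to_centering(self):
        rng = np.random.default_rng(2)
        U = rng.normal(size=(15, 3))
        y = rng.normal(size=15)
        raw = _util_frame("s", U, y)
        centred = uc.center_within_participant(raw).drop(
            columns=["instrumental", "hedonic", "cognitive"]).rename(
            columns={"instrumental_c": "instrumental",
                     "hedonic_c": "hedonic", "cognitive_c": "cognitive"})
        w_raw, _ = fit_subject_weights(raw)
        w_c, _ = fit_subject_weights(centred)
        for col in ("beta_instrumental", "beta_hedonic", "beta_cognitive"):
            assert w_raw[col].iloc[0] == pytest.approx(w_c[col].iloc[0],
                                                       abs=1e-10)


class TestModelSpace:
    def test_utility_only_count(self):
        specs = enumerate_model_space(include_confidence=False)
        assert len(specs) == 7

    def test_with_confidence_count(self):
        specs = enumerate_model_space(include_confidence=True)
        assert len(specs) == 15
        with_conf = [s for s in specs if "confidence" in s.fixed_terms]
        assert len(with_conf) == 8

    def test_full_model_unique_and_labels_stable(self):
        specs = enumerate_model_space(True)
        labels = [s.label for s in specs]
        assert len(set(labels)) == 15
        assert sum(s.is_full_utility for s in specs) == 1

    def test_empty_spec_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(())


class TestCompare:
    @staticmethod
    def _fit(label_terms, ll, k, n_obs=100, converged=True):
        fit = cm.ModelFit(
            spec=ModelSpec(label_terms),
            fixed_effects=pd.DataFrame(), random_variances={},
            log_likelihood=ll, n_obs=n_obs, k_params=k,
            converged=converged, reml=False, cov_structure="diagonal",
            df_method="normal")
        return fit

    def test_bic_closed_form(self):
        fit = self._fit(("instrumental",), -100.0, 5, 100)
        assert fit.bic == pytest.approx(5 * np.log(100) + 200, abs=1e-9)
        assert fit.aic == pytest.approx(210.0)
        assert fit.self_check()

    def test_equal_loglik_ties_resolve_to_smaller_k(self):
        f4 = self._fit(("instrumental",), -100.0, 4)
        f5 = self._fit(("hedonic",), -100.0, 5)
        table = compare_models([f5, f4])
        assert table.iloc[0]["label"] == "I"
        assert table.iloc[0]["rank_aic"] == 1

    def test_differing_nobs_refused(self):
        with pytest.raises(ValueError, match="refusing"):
            compare_models([self._fit(("instrumental",), -10, 4, 100),
                            self._fit(("hedonic",), -10, 4, 90)])

    def test_nonconverged_listed_apart(self):
        good = self._fit(("instrumental",), -10, 4)
        bad = self._fit(("hedonic",), -500, 4, converged=False)
        table = compare_models([good, bad])
        assert table.iloc[-1]["label"] == "H"
        assert not table.iloc[-1]["converged"]
        assert np.isnan(table.iloc[-1]["delta_bic"])


def _centered(util):
    return uc.center_within_participant(util)


class TestMixedModel:
    def test_matches_statsmodels_oracle(self, small_utilities):
        import statsmodels.formula.api as smf

        fit = fit_mixed_model(small_utilities, compute_df=False)
        df = small_utilities.rename(columns={
            "instrumental_c": "ic", "hedonic_c": "hc", "cognitive_c": "cc"})
        df["one"] = 1
        vc = {"pid_int": "0 + C(participant_id)",
              "pid_i": "0 + C(participant_id):ic",
              "pid_h": "0 + C(participant_id):hc",
              "pid_c": "0 + C(participant_id):cc",
              "item": "0 + C(item_id)"}
        sm_fit = smf.mixedlm("choice ~ ic + hc + cc", data=df, groups="one",
                             vc_formula=vc).fit(reml=False, method="lbfgs",
                                                maxiter=500)
        ours = fit.fixed_effects["estimate"].to_numpy()
        np.testing.assert_allclose(ours, sm_fit.fe_params.values, atol=5e-3)
        # our profiled optimum should be at least as good
        assert fit.log_likelihood >= sm_fit.llf - 1e-3

    def test_aic_bic_self_check_and_fields(self, small_utilities):
        fit = fit_mixed_model(small_utilities, compute_df=True)
        assert fit.self_check()
        assert fit.n_obs == len(small_utilities)
        # 4 fixed + 5 variance components + residual
        assert fit.k_params == 4 + 6
        assert np.isfinite(fit.fixed_effects["df"]).all()
        assert (fit.fixed_effects["df"] > 1).all()

    def test_single_item_rejected(self):
        rng = np.random.default_rng(3)
        U = rng.normal(size=(24, 3))
        util = _util_frame("s1", U, rng.normal(size=24))
        util["item_id"] = "only_item"
        util2 = util.copy()
        util2["participant_id"] = "s2"
        both = _centered(pd.concat([util, util2], ignore_index=True))
        with pytest.raises(ValueError, match="single item"):
            fit_mixed_model(both)

    def test_single_participant_rejected(self, small_utilities):
        one = small_utilities[small_utilities["participant_id"]
                              == small_utilities["participant_id"].iloc[0]]
        with pytest.raises(ValueError, match="participants"):
            fit_mixed_model(one)

    def test_mean_subject_betas_near_fixed_effects(self):
        # with vanishing random-slope variance the mixed fixed effects and
        # the mean of the per-subject OLS betas coincide
        from infoseek.synthetic_data import GeneratorConfig, generate_dataset

        cfg = GeneratorConfig(n_subjects=60, n_trials=30, seed=21,
                              population_cov_weights=np.diag([1e-6] * 3),
                              longitudinal=False)
        b = generate_dataset(cfg)
        util = _centered(uc.build_utilities(b.trials_t1))
        fit = fit_mixed_model(util, compute_df=False)
        w, _ = fit_subject_weights(util)
        mixed = fit.fixed_effects.set_index("term")["estimate"]
        for term, col in (("instrumental", "beta_instrumental"),
                          ("hedonic", "beta_hedonic"),
                          ("cognitive", "beta_cognitive")):
            assert mixed[term] == pytest.approx(w[col].mean(), abs=0.02)

    def test_reml_flag_and_unstructured_covariance(self, small_utilities):
        fit = fit_mixed_model(small_utilities, reml=True, compute_df=False)
        assert fit.reml
        fit_u = fit_mixed_model(small_utilities, cov_structure="unstructured",
                                compute_df=False)
        # the unstructured fit nests the diagonal one
        fit_d = fit_mixed_model(small_utilities, compute_df=False)
        assert fit_u.log_likelihood >= fit_d.log_likelihood - 1e-6
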