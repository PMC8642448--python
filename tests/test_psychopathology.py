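"""Dimension scoring and association analyses, with residualisation and
normal-equations oracles."""

import numpy as np
import pandas as pd
import pytest

from infoseek.psychopathology import (
    ancova_dimensions,
    average_score_regression,
    partial_correlations,
    questionnaire_associations,
    score_dimensions,
)


def _fw(items, weights):
    rows = []
    for item, (ad, sw, cit) in zip(items, weights):
        rows.append({"item_id": item, "instrument": "Q1",
                     "dim_AD": ad, "dim_SW": sw, "dim_CIT": cit})
    return pd.DataFrame(rows)


def _quest(ratings):
    """ratings: dict item_id -> list of per-participant values."""
    rows = []
    for item, vals in ratings.items():
        for i, v in enumerate(vals):
            rows.append({"participant_id": f"p{i}", "instrument": "Q1",
                         "item_id": item, "rating": v})
    return pd.DataFrame(rows)


class TestScoring:
    def test_two_participant_hand_example(self):
        scores = score_dimensions(_quest({"q1": [1, 3]}),
                                  _fw(["q1"], [(0.5, 0.0, 0.0)]))
        # z with sample SD sqrt(2): (-0.7071, +0.7071); weighted by 0.5
        np.testing.assert_allclose(scores["score_AD"],
                                   [-0.35355339, 0.35355339], atol=1e-6)
        np.testing.assert_allclose(scores["score_SW"], 0.0)

    def test_all_zero_weights(self):
        scores = score_dimensions(_quest({"q1": [1, 3]}),
                                  _fw(["q1"], [(0, 0, 0)]))
        assert (scores[["score_AD", "score_SW", "score_CIT"]] == 0).all().all()

    def test_linearity_in_weights(self):
        q = _quest({"q1": [1, 3, 2], "q2": [2, 2, 5]})
        fw1 = _fw(["q1", "q2"], [(0.5, 0.2, 0.0), (0.1, 0.0, 0.9)])
        fw2 = fw1.copy()
        fw2[["dim_AD", "dim_SW", "dim_CIT"]] *= 2
        s1 = score_dimensions(q, fw1)
        s2 = score_dimensions(q, fw2)
        cols = ["score_AD", "score_SW", "score_CIT", "average_score"]
        np.testing.assert_allclose(2 * s1[cols], s2[cols], atol=1e-12)

    def test_average_is_mean_of_dimensions(self):
        q = _quest({"q1": [1, 3, 2], "q2": [2, 1, 5]})
        s = score_dimensions(q, _fw(["q1", "q2"],
                                    [(0.5, 0.2, 0.1), (0.3, 0.6, 0.2)]))
        np.testing.assert_allclose(
            s["average_score"],
            s[["score_AD", "score_SW", "score_CIT"]].mean(axis=1))

    def test_zscored_items_standardised(self, small_bundle):
        scores = score_dimensions(small_bundle.questionnaire,
                                  small_bundle.factor_weights)
        assert scores["complete"].all()
        # re-derive one item's z column and check mean/sd
        q = small_bundle.questionnaire
        one = q[q["item_id"] == "q000"].sort_values("participant_id")
        z = (one["rating"] - one["rating"].mean()) / one["rating"].std(ddof=1)
        assert z.mean() == pytest.approx(0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1, abs=1e-12)

    def test_zero_variance_item_warns_and_scores_zero(self):
        q = _quest({"q1": [2, 2, 2], "q2": [1, 5, 3]})
        with pytest.warns(UserWarning, match="zero variance"):
            s = score_dimensions(q, _fw(["q1", "q2"],
                                        [(1.0, 0, 0), (0, 1.0, 0)]))
        np.testing.assert_allclose(s["score_AD"], 0.0)

    def test_unmapped_item_raises(self):
        with pytest.raises(KeyError, match="q2"):
            score_dimensions(_quest({"q2": [1, 2]}),
                             _fw(["q1"], [(1, 0, 0)]))

    def test_incomplete_participant_flagged(self):
        q = _quest({"q1": [1, 3, 2], "q2": [2, 1, 5]})
        q = q[~((q["participant_id"] == "p2") & (q["item_id"] == "q2"))]
        s = score_dimensions(q, _fw(["q1", "q2"],
                                    [(1, 0, 0), (0, 1, 0)]))
        assert s.set_index("participant_id")["complete"].to_dict() == {
            "p0": True, "p1": True, "p2": False}


def _cohort(rng, n=60, gamma=0.0, binary_gender=True):
    betas = rng.normal(0.1, 0.2, size=(n, 3))
    age = rng.integers(20, 60, n)
    genders = ("female", "male") if binary_gender else ("female", "male",
                                                        "other")
    gender = rng.choice(genders, n)
    noise = rng.normal(0, 0.5, n)
    avg = gamma * betas[:, 2] + 0.01 * age + noise
    scores = pd.DataFrame({
        "participant_id": [f"p{i}" for i in range(n)],
        "score_AD": avg + rng.normal(0, 0.3, n),
        "score_SW": avg + rng.normal(0, 0.3, n),
        "score_CIT": avg + rng.normal(0, 0.3, n),
        "complete": True,
    })
    scores["average_score"] = scores[
        ["score_AD", "score_SW", "score_CIT"]].mean(axis=1)
    weights = pd.DataFrame({
        "participant_id": scores["participant_id"],
        "beta_instrumental": betas[:, 0],
        "beta_hedonic": betas[:, 1],
        "beta_cognitive": betas[:, 2],
    })
    demo = pd.DataFrame({"participant_id": scores["participant_id"],
                         "age": age, "gender": gender,
                         "attention_failures": 0})
    return scores, weights, demo


class TestRegression:
    def test_planted_linear_relation_recovered_exactly(self, rng):
        scores, weights, demo = _cohort(rng, n=40)
        demo["gender"] = "female"  # collapse gender out of the design
        y = (0.5 + 2.0 * weights["beta_instrumental"]
             - 1.0 * weights["beta_cognitive"] + 0.02 * demo["age"])
        for c in ("score_AD", "score_SW", "score_CIT", "average_score"):
            scores[c] = y
        with pytest.warns(UserWarning, match="gender"):
            res = average_score_regression(scores, weights, demo)
        coef = res.regression.set_index("term")["estimate"]
        assert coef["beta_instrumental"] == pytest.approx(2.0, abs=1e-9)
        assert coef["beta_hedonic"] == pytest.approx(0.0, abs=1e-9)
        assert coef["beta_cognitive"] == pytest.approx(-1.0, abs=1e-9)
        assert coef["age"] == pytest.approx(0.02, abs=1e-9)

    def test_matches_normal_equations_oracle(self, rng):
        scores, weights, demo = _cohort(rng, gamma=-0.8)
        res = average_score_regression(scores, weights, demo)
        df = (scores.merge(weights, on="participant_id")
              .merge(demo, on="participant_id"))
        ref = df["gender"].value_counts().idxmax()
        other = [g for g in df["gender"].unique() if g != ref]
        X = np.column_stack(
            [np.ones(len(df)), df["beta_instrumental"], df["beta_hedonic"],
             df["beta_cognitive"], df["age"]]
            + [(df["gender"] == g).astype(float) for g in sorted(other)])
        beta = np.linalg.solve(X.T @ X, X.T @ df["average_score"])
        np.testing.assert_allclose(res.regression["estimate"], beta,
                                   atol=1e-9)


class TestAncova:
    def test_f_equals_t_squared(self, rng):
        scores, weights, demo = _cohort(rng, gamma=-0.6)
        res = ancova_dimensions(scores, weights, demo)
        reg = res.regression.set_index("term")
        anc = res.ancova_between.set_index("term")
        for term in ("beta_instrumental", "beta_hedonic", "beta_cognitive",
                     "age"):
            assert anc.loc[term, "F"] == pytest.approx(
                reg.loc[term, "tvalue"] ** 2, rel=1e-10)
            assert anc.loc[term, "pvalue"] == pytest.approx(
                reg.loc[term, "pvalue"], rel=1e-10)

    def test_three_level_gender_uses_partial_f(self, rng):
        scores, weights, demo = _cohort(rng, binary_gender=False)
        res = ancova_dimensions(scores, weights, demo)
        gender = res.ancova_between.set_index("term").loc["gender"]
        assert gender["df1"] == 2.0

    def test_identical_dimension_scores_degenerate(self, rng):
        scores, weights, demo = _cohort(rng)
        for c in ("score_SW", "score_CIT"):
            scores[c] = scores["score_AD"]
        scores["average_score"] = scores["score_AD"]
        res = ancova_dimensions(scores, weights, demo)
        assert res.ancova_within is None
        assert any("within-subject" in n for n in res.notes)

    def test_within_stratum_reports_interactions(self, rng):
        scores, weights, demo = _cohort(rng, gamma=-0.5)
        res = ancova_dimensions(scores, weights, demo)
        terms = set(res.ancova_within["term"])
        assert "dimension" in terms
        assert "dimension:beta_cognitive" in terms
        assert (res.ancova_within["df2"] > 0).all()


class TestPartialCorrelations:
    def test_matches_residualisation_oracle(self, rng):
        scores, weights, demo = _cohort(rng, gamma=-0.7)
        res = partial_correlations(scores, weights, demo)
        df = (scores.merge(weights, on="participant_id")
              .merge(demo, on="participant_id"))
        ref = df["gender"].value_counts().idxmax()
        other = sorted(set(df["gender"].unique()) - {ref})
        C = np.column_stack([np.ones(len(df)), df["age"]]
                            + [(df["gender"] == g).astype(float)
                               for g in other])
        def residual(v):
            v = np.asarray(v, float)
            return v - C @ np.linalg.lstsq(C, v, rcond=None)[0]
        ry = residual(df["average_score"])
        for beta in ("beta_instrumental", "beta_hedonic", "beta_cognitive"):
            rx = residual(df[beta])
            expected = np.corrcoef(rx, ry)[0, 1]
            got = res.partial_corr.set_index("motive").loc[beta, "r"]
            assert got == pytest.approx(expected, abs=1e-9)
        assert (res.partial_corr["df"] == len(df) - 4).all()

    def test_matches_pingouin_oracle(self, rng):
        import pingouin as pg

        scores, weights, demo = _cohort(rng, gamma=-0.5)
        res = partial_correlations(scores, weights, demo)
        df = (scores.merge(weights, on="participant_id")
              .merge(demo, on="participant_id"))
        df["gender_num"] = (df["gender"] == "female").astype(float)
        for beta in ("beta_instrumental", "beta_hedonic", "beta_cognitive"):
            tab = pg.partial_corr(data=df, x=beta, y="average_score",
                                  covar=["age", "gender_num"])
            got = res.partial_corr.set_index("motive").loc[beta]
            assert got["r"] == pytest.approx(float(tab["r"].iloc[0]),
                                             abs=1e-8)
            assert got["pvalue"] == pytest.approx(
                float(tab["p_val"].iloc[0]), abs=1e-8)

    def test_constant_controls_reduce_to_pearson(self, rng):
        scores, weights, demo = _cohort(rng, gamma=-0.7)
        demo["age"] = 30
        demo["gender"] = "female"
        from scipy import stats
        with pytest.warns(UserWarning, match="gender"):
            res = partial_correlations(scores, weights, demo)
        df = scores.merge(weights, on="participant_id")
        # age is constant, so residualising on it changes nothing
        for beta in ("beta_instrumental", "beta_cognitive"):
            expected = stats.pearsonr(df[beta], df["average_score"])[0]
            got = res.partial_corr.set_index("motive").loc[beta, "r"]
            assert got == pytest.approx(expected, abs=1e-9)

    def test_perfect_linear_association(self, rng):
        scores, weights, demo = _cohort(rng)
        scores["average_score"] = 3.0 * weights["beta_hedonic"] + 1.0
        res = partial_correlations(scores, weights, demo)
        r = res.partial_corr.set_index("motive").loc["beta_hedonic", "r"]
        assert r == pytest.approx(1.0, abs=1e-6)


class TestQuestionnaireAssociations:
    def _questionnaire(self, rng, n=40, n_inst=9):
        rows = []
        for i in range(n):
            for inst in range(n_inst):
                for item in range(3):
                    rows.append({
                        "participant_id": f"p{i}",
                        "instrument": f"Q{inst}",
                        "item_id": f"Q{inst}_it{item}",
                        "rating": int(rng.integers(1, 6)),
                    })
        return pd.DataFrame(rows)

    def test_bonferroni_arithmetic(self, rng):
        _, weights, _ = _cohort(rng)
        q = self._questionnaire(rng)
        table = questionnaire_associations(weights, q)
        m = q["instrument"].nunique()
        assert m == 9
        expected = np.minimum(1.0, m * table["pvalue"])
        np.testing.assert_allclose(table["pvalue_bonferroni"], expected)
        assert (table.loc[table["pvalue"] >= 0.2,
                          "pvalue_bonferroni"] == 1.0).all()

    def test_null_data_familywise_control(self):
        # across seeded replicates of null data the familywise error of the
        # Bonferroni-corrected battery stays near its nominal level
        hits = 0
        reps = 20
        for s in range(reps):
            rng = np.random.default_rng(1000 + s)
            _, weights, _ = _cohort(rng)
            q = self._questionnaire(rng)
            t = questionnaire_associations(weights, q)
            inst_sig = (t[t["motive"] == "beta_cognitive"]
                        ["significant"].any())
            hits += bool(inst_sig)
        assert hits / reps <= 0.1
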