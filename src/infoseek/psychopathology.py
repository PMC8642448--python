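"""Transdiagnostic psychopathology scores and their link to motive weights.

Questionnaire items are z-scored across participants, multiplied by
previously published factor weights, and summed per dimension to give each
participant scores on three transdiagnostic dimensions (anxious-depression,
social withdrawal, compulsive behaviour and intrusive thought).  The
association analyses relate these scores to the per-participant motive
weights: a repeated-measures ANCOVA with dimension as the within-subject
factor and the three betas plus age and gender as covariates, a simplified
regression of the average score on the same predictors, per-beta partial
correlations controlling age and gender, and per-questionnaire tests with
Bonferroni correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "AssociationResult",
    "score_dimensions",
    "average_score_regression",
    "ancova_dimensions",
    "partial_correlations",
    "questionnaire_associations",
]

DIMS = ("AD", "SW", "CIT")
BETA_COLUMNS = ("beta_instrumental", "beta_hedonic", "beta_cognitive")


def score_dimensions(questionnaire: pd.DataFrame,
                     factor_weights: pd.DataFrame, *,
                     zscore: bool = True) -> pd.DataFrame:
    """Weighted transdiagnostic dimension scores per participant.

    Each item is z-scored across participants (sample SD) and multiplied
    by its factor weight; per participant and dimension the weighted
    values are summed.  ``zscore=False`` scores the raw ratings (a
    sensitivity variant).  Items with zero variance across participants
    are scored as 0 with a warning; items missing from the weight table
    raise.  Participants missing any item are flagged incomplete (their
    scores use only the items they answered and they are excluded from
    association analyses downstream).
    """
    wide = questionnaire.pivot_table(index="participant_id",
                                     columns="item_id", values="rating",
                                     aggfunc="first")
    unmapped = set(wide.columns) - set(factor_weights["item_id"])
    if unmapped:
        raise KeyError(
            f"questionnaire items without factor weights: {sorted(unmapped)[:5]}")
    if len(wide) < 2:
        raise ValueError("z-scoring needs at least 2 participants")

    vals = wide.to_numpy(float)
    if zscore:
        mu = np.nanmean(vals, axis=0)
        sd = np.nanstd(vals, axis=0, ddof=1)
        flat = sd == 0
        if flat.any():
            warnings.warn(
                f"{int(flat.sum())} item(s) with zero variance z-scored to 0",
                stacklevel=2)
        sd_safe = np.where(flat, 1.0, sd)
        vals = (vals - mu) / sd_safe
        vals[:, flat] = 0.0

    W = (factor_weights.set_index("item_id")
         .loc[wide.columns, [f"dim_{d}" for d in DIMS]].to_numpy(float))
    complete = ~np.isnan(vals).any(axis=1)
    scores = np.nan_to_num(vals) @ W

    out = pd.DataFrame({
        "participant_id": wide.index,
        "score_AD": scores[:, 0],
        "score_SW": scores[:, 1],
        "score_CIT": scores[:, 2],
        "complete": complete,
    })
    out["average_score"] = out[[f"score_{d}" for d in DIMS]].mean(axis=1)
    return out.reset_index(drop=True)


@dataclass
class AssociationResult:
    """Association analyses between motive weights and psychopathology."""

    regression: pd.DataFrame | None = None        # term, estimate, se, t, p
    ancova_between: pd.DataFrame | None = None    # term, F, df1, df2, p, pes
    ancova_within: pd.DataFrame | None = None
    partial_corr: pd.DataFrame | None = None      # motive, r, df, p
    notes: list = field(default_factory=list)


def _most_frequent(series):
    return series.value_counts().idxmax()


def _design(scores, weights, demographics):
    """Merge scores, weights and demographics into one analysis frame.

    Incomplete scorers are dropped; gender is dummy-coded with the most
    frequent level as reference.
    """
    df = (scores[scores["complete"]]
          .merge(weights, on="participant_id")
          .merge(demographics[["participant_id", "age", "gender"]],
                 on="participant_id"))
    levels = df["gender"].unique()
    gender_cols = []
    if len(levels) < 2:
        warnings.warn("only one gender level present; gender collapses "
                      "to the intercept", stacklevel=3)
    else:
        ref = _most_frequent(df["gender"])
        for lv in sorted(set(levels) - {ref}):
            col = f"gender[{lv}]"
            df[col] = (df["gender"] == lv).astype(float)
            gender_cols.append(col)
    predictors = list(BETA_COLUMNS) + ["age"] + gender_cols
    return df, predictors, gender_cols


def average_score_regression(scores, weights, demographics) -> AssociationResult:
    """OLS of the average psychopathology score on the five predictors.

    Predictors are the three motive weights, age and gender; p-values are
    two sided.
    """
    df, predictors, gender_cols = _design(scores, weights, demographics)
    X = sm.add_constant(df[predictors].to_numpy(float))
    model = sm.OLS(df["average_score"].to_numpy(float), X)
    res = model.fit()
    table = pd.DataFrame({
        "term": ["intercept"] + predictors,
        "estimate": res.params,
        "se": res.bse,
        "tvalue": res.tvalues,
        "pvalue": res.pvalues,
    })
    out = AssociationResult(regression=table)
    out._ols = res          # reused by the ANCOVA between stratum
    out._frame = df
    out._predictors = predictors
    out._gender_cols = gender_cols
    return out


def ancova_dimensions(scores, weights, demographics) -> AssociationResult:
    """Repeated-measures ANCOVA of the three dimension scores.

    Dimension (3 levels) is the within-subject factor; the three motive
    weights, age and gender enter as covariates.  The between-subject
    stratum is algebraically the regression of participant-mean scores on
    the covariates, so each single-df covariate main effect satisfies
    F = t^2 with the average-score regression.  The within-subject stratum
    tests the dimension main effect and dimension x covariate
    interactions on the per-participant deviations from the mean score.
    """
    base = average_score_regression(scores, weights, demographics)
    df, predictors = base._frame, base._predictors
    res = base._ols
    n = len(df)
    df_den = res.df_resid

    rows = []
    # single-df covariates: F = t^2; multi-df (gender with >2 levels):
    # partial F over the dummy block
    gender_cols = base._gender_cols
    for term in list(BETA_COLUMNS) + ["age"]:
        j = 1 + predictors.index(term)
        t = res.tvalues[j]
        F = t * t
        pes = F / (F + df_den)
        rows.append({"term": term, "F": float(F), "df1": 1.0,
                     "df2": float(df_den),
                     "pvalue": float(stats.f.sf(F, 1, df_den)),
                     "partial_eta_sq": float(pes)})
    if gender_cols:
        R = np.zeros((len(gender_cols), len(res.params)))
        for i, col in enumerate(gender_cols):
            R[i, 1 + predictors.index(col)] = 1.0
        ft = res.f_test(R)
        F = float(np.squeeze(ft.fvalue))
        df1 = float(ft.df_num)
        pes = (F * df1) / (F * df1 + df_den)
        rows.append({"term": "gender", "F": F, "df1": df1,
                     "df2": float(df_den), "pvalue": float(ft.pvalue),
                     "partial_eta_sq": float(pes)})
    between = pd.DataFrame(rows)

    # within-subject stratum on deviations from the participant mean
    notes = []
    score_cols = [f"score_{d}" for d in DIMS]
    S = df[score_cols].to_numpy(float)
    dev = S - S.mean(axis=1, keepdims=True)
    if np.allclose(dev, 0):
        notes.append("zero within-subject variance; dimension effects "
                     "and interactions undefined")
        within = None
    else:
        long = pd.DataFrame({
            "dev": dev.ravel(),
            "dim": np.tile(DIMS, n),
        })
        for p_ in predictors:
            long[p_] = np.repeat(df[p_].to_numpy(float), 3)
        d1 = (long["dim"] == "SW").astype(float)
        d2 = (long["dim"] == "CIT").astype(float)
        cols = {"dim_SW": d1, "dim_CIT": d2}
        for p_ in predictors:
            cols[f"dim_SW:{p_}"] = d1 * long[p_]
            cols[f"dim_CIT:{p_}"] = d2 * long[p_]
        Xw = pd.DataFrame(cols)
        # no intercept: deviations sum to zero within participant
        resw = sm.OLS(long["dev"].to_numpy(), Xw.to_numpy()).fit()
        # each participant's deviations sum to zero, so the stratum carries
        # 2n free df; subtract the model's parameters
        df_err = 2 * n - Xw.shape[1]
        ss_err = resw.ssr
        wrows = []
        terms = ["dimension"] + [f"dimension:{p_}" for p_ in predictors]
        blocks = [["dim_SW", "dim_CIT"]] + [
            [f"dim_SW:{p_}", f"dim_CIT:{p_}"] for p_ in predictors]
        for term, block in zip(terms, blocks):
            idx = [Xw.columns.get_loc(b) for b in block]
            R = np.zeros((len(idx), Xw.shape[1]))
            for i, j in enumerate(idx):
                R[i, j] = 1.0
            # partial F with the corrected error df
            ss_h = _hypothesis_ss(resw, R)
            F = (ss_h / len(idx)) / (ss_err / df_err)
            wrows.append({"term": term, "F": float(F), "df1": float(len(idx)),
                          "df2": float(df_err),
                          "pvalue": float(stats.f.sf(F, len(idx), df_err)),
                          "partial_eta_sq": float(ss_h / (ss_h + ss_err))})
        within = pd.DataFrame(wrows)

    return AssociationResult(regression=base.regression,
                             ancova_between=between, ancova_within=within,
                             notes=notes)


def _hypothesis_ss(res, R):
    """Sum of squares for the linear hypothesis R beta = 0."""
    Rb = R @ res.params
    mid = R @ res.normalized_cov_params @ R.T
    return float(Rb @ np.linalg.solve(mid, Rb))


def partial_correlations(scores, weights, demographics) -> AssociationResult:
    """Partial correlation of each beta with the average score.

    Age and gender are partialled out by residual-on-residual
    correlation; df = n - 2 - (number of control columns).
    """
    df, _, gender_cols = _design(scores, weights, demographics)
    covars = ["age"] + gender_cols
    n = len(df)
    C = np.column_stack([np.ones(n)]
                        + [df[c].to_numpy(float) for c in covars])

    def residual(v):
        v = np.asarray(v, float)
        coef, *_ = np.linalg.lstsq(C, v, rcond=None)
        return v - C @ coef

    ry = residual(df["average_score"])
    rows = []
    dof = n - 2 - len(covars)
    for beta in BETA_COLUMNS:
        rx = residual(df[beta])
        r = float(np.corrcoef(rx, ry)[0, 1])
        r = float(np.clip(r, -1.0, 1.0))
        if abs(r) == 1.0 or dof <= 0:
            pval = 0.0 if dof > 0 else np.nan
        else:
            t = r * np.sqrt(dof / (1.0 - r * r))
            pval = float(2.0 * stats.t.sf(abs(t), dof))
        rows.append({"motive": beta, "r": r, "df": dof, "pvalue": pval})
    return AssociationResult(partial_corr=pd.DataFrame(rows))


def questionnaire_associations(weights, questionnaire, demographics=None, *,
                               alpha: float = 0.05) -> pd.DataFrame:
    """Per-instrument association of each beta with the instrument total.

    Instrument totals are summed raw ratings.  Each beta is regressed on
    each total (simple linear regression, two-sided p); p-values are
    Bonferroni-adjusted across the instruments (p_adj = min(1, m*p)) and
    flagged significant at the adjusted ``alpha``.
    """
    totals = (questionnaire.groupby(["participant_id", "instrument"],
                                    observed=True)["rating"].sum()
              .unstack("instrument"))
    merged = weights.merge(totals, on="participant_id")
    instruments = list(totals.columns)
    m = len(instruments)
    rows = []
    for beta in BETA_COLUMNS:
        for inst in instruments:
            sub = merged[[beta, inst]].dropna()
            lr = stats.linregress(sub[inst], sub[beta])
            p_adj = min(1.0, m * lr.pvalue)
            rows.append({
                "motive": beta, "instrument": inst,
                "slope": float(lr.slope), "r": float(lr.rvalue),
                "pvalue": float(lr.pvalue), "pvalue_bonferroni": p_adj,
                "significant": p_adj < alpha, "n": len(sub),
            })
    return pd.DataFrame(rows)
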