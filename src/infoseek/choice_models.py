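"""Motive-weight estimation and candidate-model comparison.

Two estimation routes mirror the two questions the analysis asks.  At the
population level, a linear mixed-effects model regresses the (numeric)
choice rating on the within-participant-centred utilities, with
by-participant random intercept and slopes and a by-item random intercept;
candidate models spanning subsets of the utilities (optionally plus the
confidence rating) are compared on BIC and AIC after maximum-likelihood
fits.  At the individual level, an ordinary least-squares regression per
participant yields the weight triple (beta_1, beta_2, beta_3) that all
profiling, stability and psychopathology analyses consume.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._lmm import CrossedLMM

__all__ = [
    "ModelSpec",
    "ModelFit",
    "UTILITY_TERMS",
    "fit_subject_weights",
    "fit_mixed_model",
    "enumerate_model_space",
    "compare_models",
]

UTILITY_TERMS = ("instrumental", "hedonic", "cognitive")

_SHORT = {"instrumental": "I", "hedonic": "H", "cognitive": "C",
          "confidence": "conf"}


@dataclass(frozen=True)
class ModelSpec:
    """One candidate fixed/random structure.

    Every fixed term also receives a by-participant random slope; the
    by-participant and by-item random intercepts are always present.
    """

    fixed_terms: tuple

    def __post_init__(self):
        if not self.fixed_terms:
            raise ValueError("fixed_terms must be nonempty")
        unknown = set(self.fixed_terms) - set(UTILITY_TERMS) - {"confidence"}
        if unknown:
            raise ValueError(f"unknown terms {sorted(unknown)}")

    @property
    def label(self) -> str:
        return "+".join(_SHORT[t] for t in self.fixed_terms)

    @property
    def is_full_utility(self) -> bool:
        return set(self.fixed_terms) == set(UTILITY_TERMS)


FULL_MODEL = ModelSpec(UTILITY_TERMS)


def enumerate_model_space(include_confidence: bool = True):
    """All candidate specs: the 7 nonempty utility subsets and, when
    ``include_confidence``, the 8 specs containing the confidence rating
    (confidence alone, plus each utility subset)."""
    specs = []
    for r in (3, 2, 1):
        for combo in itertools.combinations(UTILITY_TERMS, r):
            specs.append(ModelSpec(combo))
    if include_confidence:
        specs.append(ModelSpec(("confidence",)))
        for r in (1, 2, 3):
            for combo in itertools.combinations(UTILITY_TERMS, r):
                specs.append(ModelSpec(combo + ("confidence",)))
    return specs


@dataclass
class ModelFit:
    """Result of one mixed-model fit, with recomputable AIC/BIC."""

    spec: ModelSpec
    fixed_effects: pd.DataFrame   # term, estimate, se, tvalue, df, pvalue
    random_variances: dict
    log_likelihood: float
    n_obs: int
    k_params: int
    converged: bool
    reml: bool
    cov_structure: str
    df_method: str
    reduction_applied: str | None = None

    @property
    def aic(self) -> float:
        return 2.0 * self.k_params - 2.0 * self.log_likelihood

    @property
    def bic(self) -> float:
        return self.k_params * np.log(self.n_obs) - 2.0 * self.log_likelihood

    def self_check(self, atol=1e-8):
        """AIC/BIC must be recomputable from (logLik, k, n_obs)."""
        aic = 2 * self.k_params - 2 * self.log_likelihood
        bic = self.k_params * np.log(self.n_obs) - 2 * self.log_likelihood
        if not (abs(aic - self.aic) < atol and abs(bic - self.bic) < atol):
            raise AssertionError("stored AIC/BIC inconsistent with parts")
        return True


def _prepare(utilities: pd.DataFrame, terms):
    """Centred design matrix + integer codes for subject and item."""
    missing = [t for t in terms if f"{t}_c" not in utilities.columns
               and t not in utilities.columns]
    if missing:
        raise ValueError(f"utility table lacks columns for terms {missing}")
    cols = [f"{t}_c" if f"{t}_c" in utilities.columns else t for t in terms]
    X = np.column_stack([np.ones(len(utilities)),
                         utilities[cols].to_numpy(float)])
    subj, _ = pd.factorize(utilities["participant_id"])
    item, _ = pd.factorize(utilities["item_id"])
    y = utilities["choice"].to_numpy(float)
    return y, X, subj, item


def fit_mixed_model(utilities: pd.DataFrame, spec: ModelSpec = FULL_MODEL, *,
                    reml: bool = False, cov_structure: str = "diagonal",
                    compute_df: bool = True) -> ModelFit:
    """Fit one candidate linear mixed model.

    ``utilities`` is a centred utility table (see
    :func:`infoseek.utility_construction.center_within_participant`) that
    also carries the ``choice`` column.  Estimation is by maximum
    likelihood by default so that fits can enter
    :func:`compare_models`; set ``reml=True`` for reporting final
    estimates.  Fixed-effect t tests use Satterthwaite-type approximate
    degrees of freedom unless ``compute_df`` is off (then a normal
    reference is used and df is reported as inf).
    """
    if utilities["participant_id"].nunique() < 2:
        raise ValueError("mixed model needs at least 2 participants")
    if utilities["item_id"].nunique() < 2:
        raise ValueError(
            "item random intercept inestimable with a single item")
    y, X, subj, item = _prepare(utilities, spec.fixed_terms)
    names = ["intercept"] + list(spec.fixed_terms)
    model = CrossedLMM(y, X, subj, item,
                       slope_cols=range(1, X.shape[1]),
                       cov_structure=cov_structure, fe_names=names)
    res = model.fit(reml=reml, compute_df=compute_df)

    fe = pd.DataFrame({
        "term": names,
        "estimate": res.fe_params,
        "se": res.fe_se,
        "tvalue": res.tvalues,
        "df": res.df,
        "pvalue": res.pvalues,
    })
    rv = {k: v for k, v in res.vc.items() if not isinstance(v, np.ndarray)
          or v.ndim == 0}
    fit = ModelFit(
        spec=spec, fixed_effects=fe, random_variances=rv,
        log_likelihood=res.loglike, n_obs=res.n_obs, k_params=res.k_params,
        converged=res.converged, reml=reml, cov_structure=cov_structure,
        df_method="satterthwaite" if compute_df else "normal")
    fit.self_check()
    return fit


def fit_subject_weights(utilities: pd.DataFrame):
    """Per-participant OLS of choice on the three utilities.

    Returns ``(weights, flagged)``: a DataFrame with one row per
    participant x timepoint (intercept, the three betas, R^2, trial count)
    and a list of (participant, timepoint) pairs whose design was rank
    deficient (e.g. a constant utility column) and for whom no weights are
    emitted.
    """
    weights = []
    flagged = []
    for (pid, tp), block in utilities.groupby(
            ["participant_id", "timepoint"], observed=True):
        U = block[list(UTILITY_TERMS)].to_numpy(float)
        y = block["choice"].to_numpy(float)
        X = np.column_stack([np.ones(len(y)), U])
        if len(y) < 4 or np.linalg.matrix_rank(X) < 4:
            flagged.append((pid, tp))
            continue
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        tss = ((y - y.mean()) ** 2).sum()
        r2 = 1.0 - (resid @ resid) / tss if tss > 0 else np.nan
        weights.append({
            "participant_id": pid, "timepoint": tp,
            "intercept": beta[0],
            "beta_instrumental": beta[1],
            "beta_hedonic": beta[2],
            "beta_cognitive": beta[3],
            "r_squared": r2,
            "n_trials_used": len(y),
        })
    return pd.DataFrame(weights), flagged


def compare_models(fits) -> pd.DataFrame:
    """Rank converged fits by BIC (and AIC) ascending.

    All fits must share the same observation count; otherwise the
    criteria are not comparable and the call refuses to rank.  Ties in
    log-likelihood resolve to the smaller parameter count by the criteria
    themselves.  Non-converged fits are listed after the ranked ones with
    ``converged=False``.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to compare")
    n_obs = {f.n_obs for f in fits}
    if len(n_obs) > 1:
        raise ValueError(
            f"fits cover different observation sets (n_obs={sorted(n_obs)}); "
            "refusing to rank")
    rows = []
    for f in fits:
        f.self_check()
        rows.append({
            "label": f.spec.label,
            "k": f.k_params,
            "log_likelihood": f.log_likelihood,
            "aic": f.aic,
            "bic": f.bic,
            "converged": f.converged,
        })
    table = pd.DataFrame(rows)
    conv = table[table["converged"]].copy()
    conv = conv.sort_values(["bic", "k"], kind="mergesort")
    conv["delta_bic"] = conv["bic"] - conv["bic"].min()
    conv["delta_aic"] = conv["aic"] - conv["aic"].min()
    conv["rank_bic"] = np.arange(1, len(conv) + 1)
    conv["rank_aic"] = conv["aic"].rank(method="first").astype(int)
    bad = table[~table["converged"]].copy()
    if len(bad):
        for c in ("delta_bic", "delta_aic", "rank_bic", "rank_aic"):
            bad[c] = np.nan
    return pd.concat([conv, bad], ignore_index=True)
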