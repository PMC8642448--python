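"""Synthetic information-seeking datasets with known generative structure.

The generator draws, for every simulated participant, a latent weight triple
(instrumental, hedonic, cognitive) from a population distribution, simulates
correlated latent utility ratings per trial, discretises them to the task's
Likert scales, and forms the choice rating as a noisy linear combination of
the (discretised) utilities plus participant intercept and item effect.  A
second timepoint, a questionnaire battery whose latent composite is coupled
to the cognitive weight, and a demographics table complete the bundle, so
every downstream analysis stage can be exercised against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SCALE_7",
    "SCALE_6_NO_ZERO",
    "GeneratorConfig",
    "SyntheticBundle",
    "ConfigurationError",
    "discretize_likert",
    "generate_dataset",
    "simulate_trials",
]

SCALE_7 = "7-point"
SCALE_6_NO_ZERO = "6-point-no-zero"

#: Names of the nine questionnaire instruments the battery emulates.
INSTRUMENTS = (
    "OCI-R", "SDS", "STAI", "AUDIT", "AES", "EAT-26", "BIS-11",
    "Schizotypy", "LSAS",
)

GENDER_LEVELS = ("female", "male", "other")


class ConfigurationError(ValueError):
    """Raised when a generator configuration violates its invariants."""


def _check_psd(mat, name):
    mat = np.asarray(mat, float)
    if mat.shape != (3, 3):
        raise ConfigurationError(f"{name} must be 3x3, got {mat.shape}")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ConfigurationError(f"{name} must be symmetric")
    if np.linalg.eigvalsh(mat).min() < -1e-10:
        raise ConfigurationError(f"{name} must be positive semi-definite")
    return mat


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror the self-trait task: 40 trials per participant, 80
    participants, population mean weights near the reported fixed effects
    (0.114, 0.123, 0.091) and a between-participant mean desire of 0.43
    with an SD of 1.30.
    """

    n_subjects: int = 80
    n_trials: int = 40
    population_mean_weights: tuple = (0.114, 0.123, 0.091)
    population_cov_weights: np.ndarray = field(
        default_factory=lambda: np.diag([0.15 ** 2] * 3))
    intercept_mean: float = 0.43
    intercept_sd: float = 1.2
    item_effect_sd: float = 0.3
    noise_sd: float = 1.0
    rating_corr: np.ndarray = field(
        default_factory=lambda: np.array([[1.0, 0.3, 0.3],
                                          [0.3, 1.0, 0.3],
                                          [0.3, 0.3, 1.0]]))
    rating_sd: float = 1.5
    stability_rho: float = 0.6
    psych_coupling: float = -2.5
    psych_noise_sd: float = 1.0
    psych_gender_effect: float = 0.0
    psych_age_slope: float = 0.0
    n_items_per_dim: int = 15
    longitudinal: bool = True
    discretize: bool = True
    domain: str = "self-traits"
    frac_attention_fail: float = 0.0
    frac_zero_variance: float = 0.0
    seed: int = 0

    def validate(self):
        if self.n_subjects < 2:
            raise ConfigurationError("n_subjects must be at least 2")
        if self.n_trials < 4:
            raise ConfigurationError(
                "n_trials must be at least 4 (a per-subject fit estimates "
                "an intercept and three slopes)")
        _check_psd(self.population_cov_weights, "population_cov_weights")
        corr = _check_psd(self.rating_corr, "rating_corr")
        if not np.allclose(np.diag(corr), 1.0):
            raise ConfigurationError("rating_corr must have unit diagonal")
        if not -1.0 <= self.stability_rho <= 1.0:
            raise ConfigurationError("stability_rho must lie in [-1, 1]")
        for nm in ("intercept_sd", "item_effect_sd", "noise_sd", "rating_sd",
                   "psych_noise_sd"):
            if getattr(self, nm) < 0:
                raise ConfigurationError(f"{nm} must be nonnegative")
        return self

    def replace(self, **kw) -> "GeneratorConfig":
        return replace(self, **kw)


@dataclass
class SyntheticBundle:
    """Everything one synthetic study produces.

    True weights are the latent per-subject values drawn before any
    discretisation noise enters the trials.
    """

    trials_t1: pd.DataFrame
    true_weights_t1: pd.DataFrame
    demographics: pd.DataFrame
    questionnaire: pd.DataFrame
    factor_weights: pd.DataFrame
    true_psych: pd.DataFrame
    config: GeneratorConfig
    trials_t2: pd.DataFrame | None = None
    true_weights_t2: pd.DataFrame | None = None

    def write_csvs(self, outdir):
        """Write the bundle in the schemas data_io reads."""
        import json
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        trials = ([self.trials_t1] if self.trials_t2 is None
                  else [self.trials_t1, self.trials_t2])
        pd.concat(trials, ignore_index=True).to_csv(
            outdir / "trials.csv", index=False)
        self.demographics.to_csv(outdir / "participants.csv", index=False)
        self.questionnaire.to_csv(outdir / "questionnaire.csv", index=False)
        self.factor_weights.to_csv(outdir / "factor_weights.csv", index=False)
        meta = {"seed": self.config.seed,
                "n_subjects": self.config.n_subjects,
                "n_trials": self.config.n_trials}
        (outdir / "generator_meta.json").write_text(json.dumps(meta, indent=2))


def discretize_likert(latent, scale):
    """Map latent continuous values to the nearest admissible Likert level.

    ``scale`` is :data:`SCALE_7` (integers -3..3) or :data:`SCALE_6_NO_ZERO`
    (integers -3..3 with 0 excluded).  On the no-zero scale, latents in
    (-0.5, 0.5) map to -1 or +1 by sign and an exactly-zero latent maps to
    +1 (tie-break toward seeking).  Halves round away from the midpoint.
    """
    x = np.asarray(latent, float)
    if scale == SCALE_7:
        out = np.clip(np.floor(x + 0.5), -3, 3)
    elif scale == SCALE_6_NO_ZERO:
        pos = np.clip(np.floor(x + 0.5), 1, 3)
        neg = np.clip(np.ceil(x - 0.5), -3, -1)
        out = np.where(x >= 0.5, pos, np.where(x <= -0.5, neg,
                       np.where(x < 0, -1.0, 1.0)))
    else:
        raise ValueError(f"unknown scale descriptor {scale!r}")
    if np.isscalar(latent):
        return int(out)
    return out.astype(int)


def _draw_weights(rng, config):
    mu = np.asarray(config.population_mean_weights, float)
    w = rng.multivariate_normal(mu, config.population_cov_weights,
                                size=config.n_subjects)
    alpha = rng.normal(config.intercept_mean, config.intercept_sd,
                       config.n_subjects)
    return w, alpha


def _perturb_t2(rng, config, w1, a1):
    """AR(1)-style shrink toward the population mean plus orthogonal noise."""
    rho = config.stability_rho
    mu = np.asarray(config.population_mean_weights, float)
    eta = rng.multivariate_normal(np.zeros(3), config.population_cov_weights,
                                  size=config.n_subjects)
    w2 = mu + rho * (w1 - mu) + np.sqrt(max(0.0, 1 - rho ** 2)) * eta
    eps = rng.normal(0.0, config.intercept_sd, config.n_subjects)
    a2 = (config.intercept_mean + rho * (a1 - config.intercept_mean)
          + np.sqrt(max(0.0, 1 - rho ** 2)) * eps)
    return w2, a2


def simulate_trials(true_weights, intercepts, config, rng, *,
                    timepoint="T1", item_prefix=None):
    """Simulate one timepoint of trials for given per-subject parameters.

    ``true_weights`` is (n_subjects, 3); ``intercepts`` is (n_subjects,).
    Returns a long-format DataFrame with one row per participant x item.
    """
    nS = true_weights.shape[0]
    nT = config.n_trials
    prefix = item_prefix or f"{timepoint}_item"
    item_ids = [f"{prefix}{j:03d}" for j in range(nT)]
    item_eff = rng.normal(0.0, config.item_effect_sd, nT)
    valence = np.where(np.arange(nT) % 2 == 0, "positive", "negative")

    L = np.linalg.cholesky(config.rating_corr + 1e-12 * np.eye(3))
    lat = rng.standard_normal((nS, nT, 3)) @ L.T * config.rating_sd
    base_feel = rng.standard_normal((nS, nT))
    feel_know_lat = base_feel + lat[:, :, 1] / 2.0
    feel_not_lat = base_feel - lat[:, :, 1] / 2.0
    expect_lat = rng.standard_normal((nS, nT)) * config.rating_sd
    conf_lat = rng.standard_normal((nS, nT)) * config.rating_sd

    if config.discretize:
        usefulness = discretize_likert(lat[:, :, 0], SCALE_7)
        feel_know = discretize_likert(feel_know_lat, SCALE_7)
        feel_not = discretize_likert(feel_not_lat, SCALE_7)
        think = discretize_likert(lat[:, :, 2], SCALE_7)
        expect = discretize_likert(expect_lat, SCALE_7)
        conf = discretize_likert(conf_lat, SCALE_7)
    else:
        usefulness = lat[:, :, 0]
        feel_know = feel_know_lat
        feel_not = feel_not_lat
        think = lat[:, :, 2]
        expect = expect_lat
        conf = conf_lat

    U = np.stack([usefulness, feel_know - feel_not, think], axis=-1)
    c_lat = (intercepts[:, None]
             + np.einsum("stk,sk->st", U.astype(float), true_weights)
             + item_eff[None, :]
             + rng.normal(0.0, config.noise_sd, (nS, nT)))
    choice = (discretize_likert(c_lat, SCALE_6_NO_ZERO)
              if config.discretize else c_lat)

    pid = np.repeat([f"p{s:04d}" for s in range(nS)], nT)
    df = pd.DataFrame({
        "participant_id": pid,
        "timepoint": timepoint,
        "domain": config.domain,
        "item_id": np.tile(item_ids, nS),
        "valence": np.tile(valence, nS),
        "choice": choice.ravel(),
        "usefulness": usefulness.ravel(),
        "feel_know": feel_know.ravel(),
        "feel_not_know": feel_not.ravel(),
        "think_freq": think.ravel(),
        "expectation": expect.ravel(),
        "confidence": conf.ravel(),
    })
    return df


def _factor_weight_matrix(rng, n_items_per_dim):
    """Random sparse positive item loadings on the three dimensions."""
    dims = ("AD", "SW", "CIT")
    rows = []
    n_items = 3 * n_items_per_dim
    for i in range(n_items):
        d = i % 3
        w = np.zeros(3)
        w[d] = rng.uniform(0.3, 0.9)
        for other in range(3):
            if other != d and rng.uniform() < 0.25:
                w[other] = rng.uniform(0.03, 0.15)
        rows.append({
            "item_id": f"q{i:03d}",
            "instrument": INSTRUMENTS[i % len(INSTRUMENTS)],
            "primary_dim": dims[d],
            "dim_AD": w[0], "dim_SW": w[1], "dim_CIT": w[2],
        })
    return pd.DataFrame(rows)


def _simulate_questionnaire(rng, config, w_cog, demographics):
    """Item responses whose latent composite tracks the cognitive weight.

    The per-subject latent composite is
    gamma * (w_cog - mean) + age/gender covariate terms + noise; each of the
    three dimensions adds its own disturbance and items load on their
    primary dimension, so the measured weighted scores recover the planted
    coupling up to attenuation.
    """
    fw = _factor_weight_matrix(rng, config.n_items_per_dim)
    nS = len(w_cog)
    age = demographics["age"].to_numpy(float)
    is_female = (demographics["gender"] == "female").to_numpy(float)
    composite = (config.psych_coupling * (w_cog - np.mean(
                    config.population_mean_weights[2:3]))
                 + config.psych_age_slope * (age - age.mean())
                 + config.psych_gender_effect * is_female
                 + rng.normal(0.0, config.psych_noise_sd, nS))
    dim_latent = composite[:, None] + rng.normal(0.0, 0.5, (nS, 3))
    dim_idx = {"AD": 0, "SW": 1, "CIT": 2}
    records = []
    pids = demographics["participant_id"].to_numpy()
    for _, item in fw.iterrows():
        d = dim_idx[item["primary_dim"]]
        lat = (item[f"dim_{item['primary_dim']}"] * dim_latent[:, d]
               + rng.normal(0.0, 1.0, nS))
        rating = np.clip(np.floor(3.0 + lat + 0.5), 1, 5).astype(int)
        records.append(pd.DataFrame({
            "participant_id": pids,
            "instrument": item["instrument"],
            "item_id": item["item_id"],
            "rating": rating,
        }))
    questionnaire = pd.concat(records, ignore_index=True)
    true_psych = pd.DataFrame({"participant_id": pids,
                               "latent_composite": composite})
    return questionnaire, fw, true_psych


def _demographics(rng, config):
    nS = config.n_subjects
    age = np.clip(np.round(rng.normal(37.7, 9.2, nS)), 18, 75).astype(int)
    gender = rng.choice(GENDER_LEVELS, size=nS, p=(0.47, 0.50, 0.03))
    failures = np.zeros(nS, dtype=int)
    n_fail = int(round(config.frac_attention_fail * nS))
    if n_fail:
        failures[rng.choice(nS, n_fail, replace=False)] = 2
    return pd.DataFrame({
        "participant_id": [f"p{s:04d}" for s in range(nS)],
        "age": age,
        "gender": gender,
        "attention_failures": failures,
    })


def generate_dataset(config: GeneratorConfig) -> SyntheticBundle:
    """Generate a full synthetic study, reproducible from ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    w1, a1 = _draw_weights(rng, config)
    demographics = _demographics(rng, config)
    trials_t1 = simulate_trials(w1, a1, config, rng, timepoint="T1")

    trials_t2 = true_w2 = None
    if config.longitudinal:
        w2, a2 = _perturb_t2(rng, config, w1, a1)
        trials_t2 = simulate_trials(w2, a2, config, rng, timepoint="T2")
        true_w2 = _weights_frame(w2, a2, demographics, "T2")

    questionnaire, fw, true_psych = _simulate_questionnaire(
        rng, config, w1[:, 2], demographics)

    if config.frac_zero_variance > 0:
        n_flat = int(round(config.frac_zero_variance * config.n_subjects))
        flat_ids = rng.choice(demographics["participant_id"], n_flat,
                              replace=False)
        mask = trials_t1["participant_id"].isin(flat_ids)
        trials_t1.loc[mask, "usefulness"] = 3

    return SyntheticBundle(
        trials_t1=trials_t1,
        trials_t2=trials_t2,
        true_weights_t1=_weights_frame(w1, a1, demographics, "T1"),
        true_weights_t2=true_w2,
        demographics=demographics,
        questionnaire=questionnaire,
        factor_weights=fw,
        true_psych=true_psych,
        config=config,
    )


def _weights_frame(w, alpha, demographics, timepoint):
    return pd.DataFrame({
        "participant_id": demographics["participant_id"],
        "timepoint": timepoint,
        "beta_instrumental": w[:, 0],
        "beta_hedonic": w[:, 1],
        "beta_cognitive": w[:, 2],
        "intercept": alpha,
    })
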