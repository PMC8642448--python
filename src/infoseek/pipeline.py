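"""One-call pipeline over the module APIs, with machine-first reports.

The pipeline takes either real-data CSV paths or a synthetic-generator
configuration, runs validation and exclusions, utility construction,
per-subject and mixed-model estimation, model comparison, dominance
profiling, the stability block (when two timepoints are present) and the
psychopathology block (when questionnaires are present), and writes each
result as CSV/JSON.  The reporting layer never re-derives numbers: every
figure it emits is computed by the module APIs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, choice_models, data_io, motive_profiles
from . import psychopathology, stability, synthetic_data, utility_construction

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs, toggles and seeds for one pipeline run.

    Exactly one of (``trials_path``, ``generator``) must be provided.
    """

    trials_path: str | None = None
    participants_path: str | None = None
    questionnaire_path: str | None = None
    factor_weights_path: str | None = None
    generator: synthetic_data.GeneratorConfig | None = None
    out_dir: str | None = None
    seed: int = 0
    n_permutations: int = 10_000
    include_confidence_models: bool = True
    run_model_comparison: bool = True
    compute_df: bool = True
    exclude_constant_choice: bool = True
    min_trials: int = 20
    dominance_comparison: str = "magnitude"
    icc_centering: str = "profile"
    icc_form: str = "ICC2"
    zscore_items: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen = raw.pop("generator", None)
        cfg = cls(**raw)
        if gen is not None:
            cfg.generator = synthetic_data.GeneratorConfig(**gen)
        return cfg

    def validate(self):
        if (self.trials_path is None) == (self.generator is None):
            raise ValueError(
                "provide either real-data paths or a generator config")
        return self


@dataclass
class ReportBundle:
    exclusions: dict
    descriptives: pd.DataFrame
    rating_correlations: pd.DataFrame
    fixed_effects: pd.DataFrame
    model_comparison: pd.DataFrame | None
    subject_weights: pd.DataFrame
    dominance_labels: pd.DataFrame
    dominance_summary: dict
    midpoint: dict
    stability_block: dict | None
    association_block: dict | None
    run_log: dict
    tables: dict = field(default_factory=dict)


def _descriptives(utilities: pd.DataFrame):
    cols = [c for c in ("choice", "instrumental", "hedonic", "cognitive",
                        "confidence") if c in utilities.columns]
    desc = utilities[cols].agg(["mean", "std", "min", "max"]).T
    desc.index.name = "rating"
    corr = utilities[cols].corr()
    return desc.reset_index(), corr


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute every applicable stage and (optionally) persist reports."""
    config.validate()
    toggles = {k: v for k, v in vars(config).items()
               if k not in ("generator",) and not k.endswith("_path")}
    run_log = {"infoseek_version": __version__, "seed": config.seed,
               "toggles": {k: repr(v) for k, v in toggles.items()}}

    # ------------------------------------------------------------- inputs
    if config.generator is not None:
        bundle = synthetic_data.generate_dataset(config.generator)
        trials = pd.concat(
            [t for t in (bundle.trials_t1, bundle.trials_t2) if t is not None],
            ignore_index=True)
        trials = data_io.validate_trials(trials)
        participants = bundle.demographics
        questionnaire = bundle.questionnaire
        factor_weights = bundle.factor_weights
        run_log["input"] = f"synthetic(seed={config.generator.seed})"
    else:
        trials = data_io.load_trials(config.trials_path)
        participants = data_io.load_participants(config.participants_path)
        questionnaire = factor_weights = None
        if config.questionnaire_path:
            questionnaire = data_io.load_questionnaire(config.questionnaire_path)
            factor_weights = data_io.load_factor_weights(
                config.factor_weights_path)
        run_log["input"] = str(config.trials_path)

    # -------------------------------------------------------- exclusions
    effective_min = config.min_trials
    if config.generator is not None:
        effective_min = min(effective_min, config.generator.n_trials)
    report = data_io.apply_exclusions(
        trials, participants,
        exclude_constant_choice=config.exclude_constant_choice,
        min_trials=effective_min)
    trials = trials[trials["participant_id"].isin(report.retained)]

    # --------------------------------------------------------- utilities
    utilities = utility_construction.build_utilities(trials)
    utilities = utility_construction.center_within_participant(utilities)
    desc, corr = _descriptives(utilities)

    timepoints = sorted(utilities["timepoint"].unique())
    first_tp = utilities[utilities["timepoint"] == timepoints[0]]

    # ------------------------------------------------------ choice models
    full_fit = choice_models.fit_mixed_model(
        first_tp, choice_models.FULL_MODEL, compute_df=config.compute_df)
    comparison = None
    if config.run_model_comparison:
        has_conf = ("confidence" in utilities.columns
                    and config.include_confidence_models)
        fits = [full_fit]
        for spec in choice_models.enumerate_model_space(has_conf):
            if spec.is_full_utility:
                continue
            fits.append(choice_models.fit_mixed_model(
                first_tp, spec, compute_df=False))
        comparison = choice_models.compare_models(fits)

    weights, flagged = choice_models.fit_subject_weights(utilities)
    if flagged:
        logger.warning("rank-deficient per-subject designs flagged: %s",
                       flagged)
        run_log["flagged_subjects"] = [list(map(str, f)) for f in flagged]

    # ---------------------------------------------------------- profiling
    w_first = weights[weights["timepoint"] == timepoints[0]]
    labels = motive_profiles.classify_dominance_table(
        w_first, comparison=config.dominance_comparison)
    summary = motive_profiles.profile_summary(labels)
    mean_choice = first_tp.groupby("participant_id")["choice"].mean()
    midpoint = motive_profiles.midpoint_test(mean_choice.to_numpy())

    # ----------------------------------------------------------- stability
    stability_block = None
    if len(timepoints) >= 2:
        w1 = weights[weights["timepoint"] == timepoints[0]]
        w2 = weights[weights["timepoint"] == timepoints[1]]
        perm = stability.permutation_stability_test(
            w1, w2, n_iter=config.n_permutations, seed=config.seed)
        icc = stability.icc_per_motive(
            w1, w2, centering=config.icc_centering, form=config.icc_form)
        stability_block = {"permutation": perm.to_dict(),
                           "icc": icc.to_dict("records")}
    else:
        logger.info("single timepoint: stability block skipped")
        run_log["stability"] = "skipped (single timepoint)"

    # ------------------------------------------------------ psychopathology
    association_block = None
    if questionnaire is not None:
        scores = psychopathology.score_dimensions(
            questionnaire, factor_weights, zscore=config.zscore_items)
        w_mean = (weights.groupby("participant_id", as_index=False)
                  [list(motive_profiles.BETA_COLUMNS)].mean())
        ancova = psychopathology.ancova_dimensions(
            scores, w_mean, participants)
        pcorr = psychopathology.partial_correlations(
            scores, w_mean, participants)
        qassoc = psychopathology.questionnaire_associations(
            w_mean, questionnaire)
        association_block = {
            "regression": ancova.regression.to_dict("records"),
            "ancova_between": ancova.ancova_between.to_dict("records"),
            "ancova_within": (ancova.ancova_within.to_dict("records")
                              if ancova.ancova_within is not None else None),
            "partial_correlations": pcorr.partial_corr.to_dict("records"),
            "questionnaire_associations": qassoc.to_dict("records"),
        }

    out = ReportBundle(
        exclusions=report.to_dict(),
        descriptives=desc,
        rating_correlations=corr,
        fixed_effects=full_fit.fixed_effects,
        model_comparison=comparison,
        subject_weights=weights,
        dominance_labels=labels,
        dominance_summary=summary,
        midpoint=midpoint,
        stability_block=stability_block,
        association_block=association_block,
        run_log=run_log,
    )
    if config.out_dir:
        _write_reports(out, Path(config.out_dir))
    return out


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _write_reports(out: ReportBundle, outdir: Path):
    outdir.mkdir(parents=True, exist_ok=True)

    def dump(name, payload):
        (outdir / name).write_text(
            json.dumps(payload, indent=2, default=_jsonable) + "\n")

    dump("exclusions.json", out.exclusions)
    out.descriptives.to_csv(outdir / "descriptives.csv", index=False)
    out.rating_correlations.to_csv(outdir / "rating_correlations.csv")
    out.fixed_effects.to_csv(outdir / "fixed_effects.csv", index=False)
    if out.model_comparison is not None:
        out.model_comparison.to_csv(outdir / "model_comparison.csv",
                                    index=False)
    out.subject_weights.to_csv(outdir / "subject_weights.csv", index=False)
    out.dominance_labels.to_csv(outdir / "dominance_labels.csv", index=False)
    dump("dominance_summary.json", out.dominance_summary)
    dump("midpoint_test.json", out.midpoint)
    if out.stability_block is not None:
        dump("stability.json", out.stability_block)
    if out.association_block is not None:
        dump("associations.json", out.association_block)
    dump("run_log.json", out.run_log)

    lines = ["infoseek pipeline summary", "=" * 25, ""]
    fe = out.fixed_effects
    for _, r in fe.iterrows():
        lines.append(f"fixed effect {r['term']:<14} beta={r['estimate']:+.3f} "
                     f"SE={r['se']:.3f} p={r['pvalue']:.4g}")
    ds = out.dominance_summary
    lines.append("")
    lines.append(f"twofold dominance: {ds['pct_any_dominant_2x']:.2f}% ; "
                 f">=1.25x dominance: {ds['pct_any_dominant_1_25x']:.2f}%")
    if out.stability_block:
        p = out.stability_block["permutation"]
        lines.append(
            f"stability: actual mean distance {p['actual_mean_distance']:.3f}; "
            f"{100 * p['proportion_actual_smaller']:.2f}% of "
            f"{p['n_iter']} mismatched pairings were larger")
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
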