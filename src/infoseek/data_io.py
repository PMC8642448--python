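"""Reading, validation and exclusion rules for rating-task tables.

The long-format trials table holds one row per participant x stimulus with
the choice rating (six-point scale, zero excluded) and the auxiliary
ratings; participants, questionnaire responses and factor weights each have
their own flat CSV schema.  Exclusions follow the task's two rules: more
than one failed attention check (of five), and zero variance on any of the
utility inputs across a participant's trials at a timepoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ExclusionReport",
    "TRIAL_COLUMNS",
    "load_trials",
    "validate_trials",
    "load_participants",
    "load_questionnaire",
    "load_factor_weights",
    "apply_exclusions",
]

logger = logging.getLogger(__name__)

#: canonical trial columns -> (required, valid range or None)
TRIAL_COLUMNS = {
    "participant_id": (True, None),
    "timepoint": (False, None),
    "domain": (False, None),
    "item_id": (True, None),
    "valence": (False, None),
    "choice": (True, {-3, -2, -1, 1, 2, 3}),
    "usefulness": (True, set(range(-3, 4))),
    "feel_know": (True, set(range(-3, 4))),
    "feel_not_know": (True, set(range(-3, 4))),
    "think_freq": (True, set(range(-3, 4))),
    "expectation": (False, set(range(-3, 4))),
    "confidence": (False, set(range(-3, 4))),
}

_KEY = ["participant_id", "timepoint", "item_id"]


class ValidationError(ValueError):
    """A table violated its schema; the message carries row-level detail."""


def validate_trials(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a trials table against the canonical schema.

    Rows with missing mandatory fields are dropped (with a logged count);
    any out-of-range rating or duplicate (participant, timepoint, item) key
    raises :class:`ValidationError` naming the offending rows and rule.
    """
    df = df.copy()
    missing_cols = [c for c, (req, _) in TRIAL_COLUMNS.items()
                    if req and c not in df.columns]
    if missing_cols:
        raise ValidationError(f"missing mandatory columns: {missing_cols}")
    if "timepoint" not in df.columns:
        df["timepoint"] = "T1"
    if "domain" not in df.columns:
        df["domain"] = "unspecified"
    if "valence" not in df.columns:
        df["valence"] = "none"

    mandatory = [c for c, (req, _) in TRIAL_COLUMNS.items() if req]
    na_mask = df[mandatory].isna().any(axis=1)
    if na_mask.any():
        logger.warning("dropping %d rows with missing mandatory fields",
                       int(na_mask.sum()))
        df = df.loc[~na_mask]

    problems = []
    for col, (req, rng) in TRIAL_COLUMNS.items():
        if rng is None or col not in df.columns:
            continue
        vals = df[col]
        present = vals.notna()
        bad = present & ~vals.isin(list(rng))
        if bad.any():
            rows = df.index[bad][:10].tolist()
            rule = ("choice is on the six-point scale with 0 not included"
                    if col == "choice"
                    else f"{col} must lie on the 7-point scale -3..3")
            problems.append(f"rows {rows}: {rule} "
                            f"(saw {sorted(vals[bad].unique().tolist())})")
    if problems:
        raise ValidationError("; ".join(problems))

    dup = df.duplicated(subset=_KEY, keep=False)
    if dup.any():
        keys = df.loc[dup, _KEY].drop_duplicates().head(5).to_dict("records")
        raise ValidationError(
            f"duplicate (participant, timepoint, item) keys: {keys}")

    for col in ("choice", "usefulness", "feel_know", "feel_not_know",
                "think_freq"):
        df[col] = df[col].astype(int)
    return df.reset_index(drop=True)


def load_trials(path, schema: dict | None = None) -> pd.DataFrame:
    """Read and validate a long-format trials CSV.

    ``schema`` optionally maps canonical column names to the names used in
    the file (e.g. ``{"choice": "want_to_know"}``).
    """
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    return validate_trials(df)


def load_participants(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"participant_id", "age", "gender", "attention_failures"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"participants table missing columns {missing}")
    bad = ~df["attention_failures"].between(0, 5)
    if bad.any():
        raise ValidationError(
            f"attention_failures outside 0..5 at rows {df.index[bad].tolist()}")
    return df


def load_questionnaire(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"participant_id", "instrument", "item_id", "rating"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"questionnaire table missing columns {missing}")
    return df


def load_factor_weights(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"item_id", "dim_AD", "dim_SW", "dim_CIT"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"factor-weight table missing columns {missing}")
    if not np.isfinite(df[["dim_AD", "dim_SW", "dim_CIT"]].to_numpy()).all():
        raise ValidationError("factor weights must be finite")
    return df


@dataclass
class ExclusionReport:
    """Partition of participants into excluded and retained sets."""

    excluded_attention: list
    excluded_zero_variance: list
    retained: list
    reasons: dict = field(default_factory=dict)
    variance_flags: pd.DataFrame | None = None

    def to_dict(self):
        return {
            "excluded_attention": list(self.excluded_attention),
            "excluded_zero_variance": list(self.excluded_zero_variance),
            "retained": list(self.retained),
            "reasons": self.reasons,
        }


def apply_exclusions(trials: pd.DataFrame, participants: pd.DataFrame, *,
                     max_attention_failures: int = 1,
                     exclude_constant_choice: bool = True,
                     min_trials: int = 20) -> ExclusionReport:
    """Apply the attention-check and zero-variance exclusion rules.

    A participant is excluded if they failed more than
    ``max_attention_failures`` of the embedded attention checks, or if any
    one of the three utility inputs (usefulness, the feel-if-know minus
    feel-if-not-know difference, think-frequency) — or, when
    ``exclude_constant_choice``, the choice itself — is constant across all
    of their trials at any timepoint, or if they contributed fewer than
    ``min_trials`` trials at a timepoint.  The rules are per-participant,
    so the report is idempotent and one participant's exclusion never
    affects another's.
    """
    trial_ids = set(trials["participant_id"].unique())
    demo_ids = set(participants["participant_id"])
    orphans = trial_ids - demo_ids
    if orphans:
        raise ValidationError(
            f"participants with trials but no demographic row: {sorted(orphans)[:5]}")

    failures = participants.set_index("participant_id")["attention_failures"]
    excluded_attention = sorted(
        pid for pid in trial_ids if failures[pid] > max_attention_failures)

    work = trials.copy()
    work["hedonic_input"] = work["feel_know"] - work["feel_not_know"]
    scales = ["usefulness", "hedonic_input", "think_freq"]
    if exclude_constant_choice:
        scales.append("choice")

    grp = work.groupby(["participant_id", "timepoint"])
    nun = grp[scales].nunique()
    counts = grp.size()
    flags = (nun <= 1)
    flags["too_few_trials"] = counts < min_trials
    bad_any = flags.any(axis=1)
    reasons: dict = {}
    excluded_zero_variance = []
    for (pid, tp), row in flags[bad_any].iterrows():
        if pid in excluded_attention:
            continue
        if pid not in excluded_zero_variance:
            excluded_zero_variance.append(pid)
        why = [f"{c}@{tp}" for c in flags.columns if row[c]]
        reasons.setdefault(pid, []).extend(why)
    excluded_zero_variance = sorted(excluded_zero_variance)

    for pid in excluded_attention:
        reasons[pid] = ["attention_checks"]

    retained = sorted(trial_ids - set(excluded_attention)
                      - set(excluded_zero_variance))
    return ExclusionReport(
        excluded_attention=excluded_attention,
        excluded_zero_variance=excluded_zero_variance,
        retained=retained,
        reasons=reasons,
        variance_flags=flags.reset_index(),
    )
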