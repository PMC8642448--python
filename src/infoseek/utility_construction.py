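"""Construct the three utility regressors from raw ratings.

Instrumental utility is the usefulness rating, hedonic utility is the
difference between the expected feeling if the information were known and
if it were never known, and cognitive utility is the think-frequency
rating.  Each regressor is subsequently centred within participant (per
timepoint) before entering any model; the raw columns are retained side by
side with their centred counterparts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "UTILITY_COLUMNS",
    "build_utilities",
    "center_within_participant",
    "reverse_valence",
]

UTILITY_COLUMNS = ("instrumental", "hedonic", "cognitive")


def reverse_valence(expectation, valence):
    """Reverse expectation ratings for negative-valence stimuli.

    On the symmetric -3..+3 scale the reversal is a sign flip, so that
    after reversal a high value always means "expects good news".
    Vectorised over equally-shaped inputs.
    """
    exp = np.asarray(expectation, float)
    val = np.asarray(valence)
    known = np.isin(val, ("positive", "negative", "none"))
    if not known.all():
        bad = np.unique(val[~known]).tolist()
        raise ValueError(f"unknown valence label(s): {bad}")
    out = np.where(val == "negative", -exp, exp)
    if np.isscalar(expectation) or (out.ndim == 0):
        return float(out)
    return out


def build_utilities(trials: pd.DataFrame) -> pd.DataFrame:
    """Turn validated trials into a utility table (uncentred).

    Returns one row per (participant, timepoint, item) with the three
    utilities, the choice, and the optional confidence and valenced
    expectation covariates.
    """
    out = pd.DataFrame({
        "participant_id": trials["participant_id"],
        "timepoint": trials["timepoint"],
        "item_id": trials["item_id"],
        "choice": trials["choice"].astype(float),
        "instrumental": trials["usefulness"].astype(float),
        "hedonic": (trials["feel_know"] - trials["feel_not_know"]).astype(float),
        "cognitive": trials["think_freq"].astype(float),
    })
    if "confidence" in trials.columns:
        out["confidence"] = trials["confidence"].astype(float)
    if "expectation" in trials.columns and "valence" in trials.columns:
        out["expectation_valenced"] = reverse_valence(
            trials["expectation"].to_numpy(float),
            trials["valence"].to_numpy())
    return out.reset_index(drop=True)


def center_within_participant(table: pd.DataFrame,
                              columns=None) -> pd.DataFrame:
    """Append within-(participant, timepoint) mean-centred columns.

    For each listed column ``c`` a ``c_c`` column is added holding the
    value minus its participant-by-timepoint block mean.  Centring is
    idempotent: re-centring a centred column reproduces it.
    """
    if columns is None:
        columns = [c for c in
                   list(UTILITY_COLUMNS) + ["confidence"]
                   if c in table.columns]
    if table.empty:
        raise ValueError("cannot centre an empty utility table")
    out = table.copy()
    grp = out.groupby(["participant_id", "timepoint"], observed=True)
    for col in columns:
        out[f"{col}_c"] = out[col] - grp[col].transform("mean")
    return out
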