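"""Dominant-motive classification and descriptive profile statistics.

A participant's dominant motive is the utility whose weight magnitude
exceeds both others by a ratio threshold: "twofold" dominance when the
largest magnitude is at least twice both others, a weaker "one_25" tier at
the 1.25x threshold, and "none" otherwise.  Magnitudes are compared by
default because negative weights (avoidance-driving motives) are as
meaningful as positive ones; a signed comparison mode is available for
sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DominanceLabel",
    "classify_dominance",
    "classify_dominance_table",
    "profile_summary",
    "midpoint_test",
    "ZeroVarianceError",
]

MOTIVE_NAMES = ("action", "affect", "cognition")
BETA_COLUMNS = ("beta_instrumental", "beta_hedonic", "beta_cognitive")


class ZeroVarianceError(ValueError):
    """A test statistic is undefined because its denominator variance is 0."""


@dataclass(frozen=True)
class DominanceLabel:
    participant_id: object
    timepoint: object
    dominant: str          # action / affect / cognition / none
    tier: str              # twofold / one_25 / none
    weight_ratio_1: float  # largest / second-largest magnitude
    weight_ratio_2: float  # largest / smallest magnitude


def _classify(values):
    """Tier and winner for one weight triple (already magnitude or signed)."""
    order = np.argsort(values)[::-1]
    m1, m2, m3 = values[order]
    r1 = m1 / m2 if m2 > 0 else np.inf
    r2 = m1 / m3 if m3 > 0 else np.inf
    if m1 <= 0 or m1 == m2:
        return "none", "none", r1, r2
    if m1 >= 2.0 * m2:
        tier = "twofold"
    elif m1 >= 1.25 * m2:
        tier = "one_25"
    else:
        return "none", "none", r1, r2
    return MOTIVE_NAMES[order[0]], tier, r1, r2


def classify_dominance(weights, comparison: str = "magnitude",
                       participant_id=None, timepoint=None) -> DominanceLabel:
    """Classify one weight triple (instrumental, hedonic, cognitive).

    ``weights`` is a length-3 sequence or a Series/row with the
    ``beta_*`` columns.  ``comparison='magnitude'`` (default) compares
    absolute weights; ``'signed'`` compares raw values, in which a
    non-positive largest weight yields no dominant motive.  Exact ties at
    the threshold count as meeting it ("at least 1.25/2 times"); ties for
    the largest weight yield ``dominant='none'``.
    """
    if isinstance(weights, (pd.Series, dict)):
        pid = participant_id if participant_id is not None else weights.get(
            "participant_id")
        tp = timepoint if timepoint is not None else weights.get("timepoint")
        vals = np.array([weights[c] for c in BETA_COLUMNS], float)
    else:
        pid, tp = participant_id, timepoint
        vals = np.asarray(weights, float)
    if vals.shape != (3,) or not np.isfinite(vals).all():
        raise ValueError("need three finite motive weights")
    if comparison == "magnitude":
        vals = np.abs(vals)
    elif comparison != "signed":
        raise ValueError(f"unknown comparison mode {comparison!r}")
    dominant, tier, r1, r2 = _classify(vals)
    return DominanceLabel(pid, tp, dominant, tier, r1, r2)


def classify_dominance_table(weights: pd.DataFrame,
                             comparison: str = "magnitude") -> pd.DataFrame:
    """Vectorised :func:`classify_dominance` over a per-subject weights table."""
    labels = [
        classify_dominance(row, comparison=comparison)
        for _, row in weights.iterrows()
    ]
    return pd.DataFrame([l.__dict__ for l in labels])


def profile_summary(labels: pd.DataFrame) -> dict:
    """Percentages of participants per dominant motive and per tier.

    Each partition sums to 100 (up to rounding of the stored floats).
    """
    if len(labels) == 0:
        raise ValueError("no dominance labels to summarise")
    n = len(labels)
    by_motive = {m: 100.0 * (labels["dominant"] == m).sum() / n
                 for m in MOTIVE_NAMES + ("none",)}
    by_tier = {t: 100.0 * (labels["tier"] == t).sum() / n
               for t in ("twofold", "one_25", "none")}
    return {
        "n": n,
        "pct_dominant": by_motive,
        "pct_tier": by_tier,
        "pct_any_dominant_2x": by_tier["twofold"],
        "pct_any_dominant_1_25x": by_tier["twofold"] + by_tier["one_25"],
    }


def midpoint_test(mean_choices) -> dict:
    """One-sample t test of per-participant mean choice against 0.

    Zero is the midpoint of the six-point no-zero choice scale.  With at
    least two participants and nonzero spread, returns mean, SD, t, df and
    the two-sided p; an all-equal nonzero input raises
    :class:`ZeroVarianceError` (the statistic is unbounded).
    """
    x = np.asarray(mean_choices, float)
    if x.size < 2:
        raise ValueError("need at least 2 participants")
    sd = x.std(ddof=1)
    if sd == 0:
        if x[0] == 0:
            return {"mean": 0.0, "sd": 0.0, "t": 0.0,
                    "df": x.size - 1, "p": 1.0}
        raise ZeroVarianceError(
            "all participant means identical and nonzero; t is unbounded")
    t, p = stats.ttest_1samp(x, 0.0)
    return {"mean": float(x.mean()), "sd": float(sd), "t": float(t),
            "df": x.size - 1, "p": float(p)}
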