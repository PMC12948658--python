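"""Point-light-face emotion-recognition accuracy scoring.

Per trial the participant rates how angry, happy and sad the displayed
person looked (0-10 each). Accuracy is the correct-emotion rating minus
the mean of the two incorrect ratings, so each trial scores in [-10, 10];
the participant's headline score is the grand mean over the 108 trials,
with optional cell means by emotion, spatial level and kinematic level.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .design import EMOTIONS

logger = logging.getLogger(__name__)

N_TRIALS = 108
RATING_COLS = [f"rating_{e}" for e in EMOTIONS]


def trial_accuracy(true_emotion: str, ratings: dict) -> float:
    """Correct-emotion rating minus the mean of the two incorrect ratings."""
    missing = [e for e in EMOTIONS if e not in ratings or ratings[e] is None
               or (isinstance(ratings[e], float) and np.isnan(ratings[e]))]
    if missing:
        raise ValueError(f"missing ratings for: {missing}")
    if true_emotion not in EMOTIONS:
        raise ValueError(f"unknown emotion {true_emotion!r}")
    vals = {e: float(ratings[e]) for e in EMOTIONS}
    if any(not (0 <= v <= 10) for v in vals.values()):
        raise ValueError("ratings must lie in [0, 10]")
    others = [vals[e] for e in EMOTIONS if e != true_emotion]
    return vals[true_emotion] - float(np.mean(others))


def _accuracies(trials: pd.DataFrame) -> pd.Series:
    for col in RATING_COLS + ["emotion"]:
        if col not in trials.columns:
            raise ValueError(f"missing column {col!r}")
    R = trials[RATING_COLS].to_numpy(dtype=float)
    if np.isnan(R).any():
        raise ValueError("missing ratings in trial table")
    if ((R < 0) | (R > 10)).any():
        raise ValueError("ratings must lie in [0, 10]")
    true_idx = trials["emotion"].map({e: i for i, e in enumerate(EMOTIONS)})
    if true_idx.isna().any():
        raise ValueError("unknown emotion label in trial table")
    ti = true_idx.to_numpy()
    correct = R[np.arange(len(R)), ti]
    incorrect_mean = (R.sum(axis=1) - correct) / 2.0
    return pd.Series(correct - incorrect_mean, index=trials.index,
                     name="accuracy")


def mean_accuracy(trials: pd.DataFrame, by=None):
    """Grand-mean accuracy, or cell means over the given grouping columns.

    A set smaller than the full 108-trial design is scored over the
    available trials with a logged warning.
    """
    if len(trials) == 0:
        raise ValueError("empty trial set")
    if len(trials) != N_TRIALS:
        logger.warning("expected %d trials, scoring %d", N_TRIALS, len(trials))
    acc = _accuracies(trials)
    if by is None:
        return float(acc.mean())
    grouped = trials.assign(accuracy=acc).groupby(list(by), sort=True)
    means = grouped["accuracy"].mean()
    if (grouped.size() == 0).any():
        raise ValueError("empty cell in grouped accuracy")
    return means


def score_recognition(plf: pd.DataFrame) -> pd.DataFrame:
    """Per-participant grand mean + per-emotion/spatial/kinematic means."""
    rows = []
    for pid, grp in plf.groupby("participant", sort=True):
        row = dict(participant=pid, accuracy_mean=mean_accuracy(grp))
        for e, v in mean_accuracy(grp, by=["emotion"]).items():
            row[f"accuracy_{e}"] = v
        for s, v in mean_accuracy(grp, by=["spatial"]).items():
            row[f"accuracy_spatial_{s}"] = v
        for k, v in mean_accuracy(grp, by=["kinematic"]).items():
            row[f"accuracy_kinematic_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
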