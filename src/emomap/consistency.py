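"""Emotional-consistency scoring for the forced-choice tournament task.

Each condition is a complete round robin over 11 target images (55 trials).
An image's *rank score* is the number of trials in which it was chosen
(0-10). Per trial, the *item difference* is rank(chosen) - rank(unchosen);
the condition's *total consistency* is the sum of the 55 item differences.
A perfectly transitive chooser yields rank scores 10, 9, ..., 0 and a total
of 220; an item difference <= 0 marks an inconsistent decision.

For a complete round robin on 11 images the total obeys the closed-form
identity ``total = 2 * sum(w_i^2) - 550``, since each image i is chosen
w_i times and unchosen (10 - w_i) times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class IncompleteDataError(ValueError):
    """A planned trial has no valid final choice event."""


def filter_final_choices(raw: pd.DataFrame) -> pd.DataFrame:
    """Keep exactly one valid (non-redo) choice per planned trial.

    Redo-flagged events (trap selections, too-fast responses) are dropped;
    the surviving event is the final non-redo row of each trial. A trial
    with only redo events raises :class:`IncompleteDataError`.
    """
    keys = [k for k in ("participant", "condition", "trial_index")
            if k in raw.columns]
    if "trial_index" not in keys:
        raise ValueError("choice table needs a trial_index column")
    valid = raw[~raw["redo"].astype(bool)]
    out = valid.groupby(keys, sort=False, as_index=False).tail(1)
    planned = raw[keys].drop_duplicates()
    got = out[keys].drop_duplicates()
    missing = planned.merge(got, on=keys, how="left", indicator=True)
    missing = missing[missing["_merge"] == "left_only"]
    if len(missing):
        lost = missing[keys].to_dict("records")
        raise IncompleteDataError(f"trials with no valid final choice: {lost}")
    return out.reset_index(drop=True)


def _check_round_robin(choices: pd.DataFrame) -> tuple[list, int]:
    images = sorted(set(choices["stimulus_a"]) | set(choices["stimulus_b"]))
    n = len(images)
    pairs = set(map(frozenset, zip(choices["stimulus_a"],
                                   choices["stimulus_b"])))
    if len(choices) != n * (n - 1) // 2 or len(pairs) != len(choices):
        raise ValueError(
            f"incomplete round robin: {len(choices)} trials over {n} images")
    return images, n


def rank_scores(choices: pd.DataFrame) -> pd.Series:
    """Times-chosen count per image for one participant-condition table.

    Images never chosen get 0. Requires a complete filtered round robin.
    """
    images, _ = _check_round_robin(choices)
    bad = ~(choices["chosen"].eq(choices["stimulus_a"])
            | choices["chosen"].eq(choices["stimulus_b"]))
    if bad.any():
        raise ValueError("chosen image not among the shown targets")
    counts = choices["chosen"].value_counts()
    return pd.Series({img: int(counts.get(img, 0)) for img in images},
                     name="rank_score")


@dataclass
class ConsistencyResult:
    total: int
    item_differences: np.ndarray
    n_inconsistent: int


def consistency_total(choices: pd.DataFrame,
                      ranks: pd.Series | None = None) -> ConsistencyResult:
    """Sum of per-trial rank differences (max 220 for an 11-image round robin)."""
    if ranks is None:
        ranks = rank_scores(choices)
    images, _ = _check_round_robin(choices)
    if set(ranks.index) != set(images):
        raise ValueError("rank scores do not match the choice table's images")
    chosen = choices["chosen"].map(ranks)
    unchosen_id = np.where(choices["chosen"].eq(choices["stimulus_a"]),
                           choices["stimulus_b"], choices["stimulus_a"])
    unchosen = pd.Series(unchosen_id, index=choices.index).map(ranks)
    diffs = (chosen - unchosen).to_numpy()
    return ConsistencyResult(total=int(diffs.sum()),
                             item_differences=diffs,
                             n_inconsistent=int((diffs <= 0).sum()))


def score_consistency(raw: pd.DataFrame) -> pd.DataFrame:
    """Per-participant, per-condition consistency totals from a raw table."""
    filtered = filter_final_choices(raw)
    rows = []
    for (pid, cond), grp in filtered.groupby(["participant", "condition"],
                                             sort=True):
        res = consistency_total(grp)
        rows.append(dict(participant=pid, condition=cond,
                         consistency=res.total,
                         n_inconsistent=res.n_inconsistent))
    return pd.DataFrame(rows)
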