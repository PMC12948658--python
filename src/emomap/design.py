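"""Deterministic construction of the four task designs.

The study battery comprises:

* an affect-similarity task: all unordered pairs of 15 affect-inducing
  images (5 per emotion category: angry, happy, sad), rated 0-10;
* a forced-choice "tournament" task: per condition, the 11 target images
  shown pairwise in all 55 unique combinations together with a trap image
  inducing a non-target emotion (attention check);
* a point-light-face (PLF) recognition task: the full crossing of
  3 emotions x 4 actors x 3 spatial levels x 3 kinematic levels = 108
  trials, 12 per spatial x kinematic condition;
* an emotional vocabulary test over 20 emotion words (10 positive,
  10 negative valence).

All plans are plain tidy DataFrames wrapped in :class:`TrialPlan`;
randomisation (trial order, trap assignment) is fully seeded.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

EMOTIONS = ("angry", "happy", "sad")

#: The 20 emotion words of the vocabulary test with fixed valence tags.
#: The 10/10 split is forced by the task's 45/45/100 pair-group sizes.
VOCAB_ITEMS: tuple[tuple[str, str], ...] = (
    ("affection", "positive"),
    ("amusement", "positive"),
    ("anger", "negative"),
    ("anxiety", "negative"),
    ("awe", "positive"),
    ("contentment", "positive"),
    ("depression", "negative"),
    ("desire", "positive"),
    ("disgust", "negative"),
    ("embarrassment", "negative"),
    ("excitement", "positive"),
    ("fear", "negative"),
    ("guilt", "negative"),
    ("happiness", "positive"),
    ("interest", "positive"),
    ("irritation", "negative"),
    ("loneliness", "negative"),
    ("peaceful", "positive"),
    ("sadness", "negative"),
    ("surprise", "positive"),
)

PLAN_COLUMNS = [
    "task",
    "trial_index",
    "stimulus_a",
    "stimulus_b",
    "stimulus_c",
    "emotion",
    "emotion_pair",
    "spatial",
    "kinematic",
    "actor",
    "trap_id",
]


class DesignError(ValueError):
    """A task design precondition is violated."""


@dataclass(frozen=True)
class ImageSet:
    """A labelled set of stimulus images.

    Parameters
    ----------
    images : image identifiers, unique.
    emotions : emotion label per image (parallel to ``images``).
    roles : ``"target"`` or ``"trap"`` per image.
    """

    images: tuple[str, ...]
    emotions: tuple[str, ...]
    roles: tuple[str, ...] = field(default=())

    def __post_init__(self):
        roles = self.roles or tuple("target" for _ in self.images)
        object.__setattr__(self, "roles", roles)
        if len(set(self.images)) != len(self.images):
            raise DesignError("image identifiers must be unique")
        if not (len(self.images) == len(self.emotions) == len(self.roles)):
            raise DesignError("images, emotions and roles must be parallel")

    @property
    def targets(self) -> tuple[str, ...]:
        return tuple(i for i, r in zip(self.images, self.roles) if r == "target")

    def emotion_of(self, image: str) -> str:
        return self.emotions[self.images.index(image)]

    @classmethod
    def similarity_default(cls, n_per_emotion: int = 5) -> "ImageSet":
        """The 15-image similarity set: ``n_per_emotion`` per category."""
        images, emotions = [], []
        for emo in EMOTIONS:
            for i in range(1, n_per_emotion + 1):
                images.append(f"{emo}_{i:02d}")
                emotions.append(emo)
        return cls(tuple(images), tuple(emotions))

    @classmethod
    def choice_default(cls, condition: str, n_targets: int = 11,
                       n_traps: int = 5) -> "ImageSet":
        """Target + trap images for one forced-choice condition.

        For emotional conditions the traps induce a different emotion;
        for the ``"control"`` (colourfulness) condition they are grayscale
        stand-ins. Identifiers are abstract.
        """
        if condition == "control":
            target_emo, trap_emo = "neutral", "grayscale"
        else:
            if condition not in EMOTIONS:
                raise DesignError(f"unknown condition {condition!r}")
            target_emo = condition
            trap_emo = EMOTIONS[(EMOTIONS.index(condition) + 1) % 3]
        images = [f"{condition}_t{i:02d}" for i in range(1, n_targets + 1)]
        emotions = [target_emo] * n_targets
        roles = ["target"] * n_targets
        for i in range(1, n_traps + 1):
            images.append(f"{condition}_trap{i:02d}")
            emotions.append(trap_emo)
            roles.append("trap")
        return cls(tuple(images), tuple(emotions), tuple(roles))


@dataclass(frozen=True)
class TrialPlan:
    """An ordered trial list for one task (tidy frame, one row per trial)."""

    task: str
    trials: pd.DataFrame

    def __len__(self) -> int:
        return len(self.trials)

    def to_csv(self, path) -> None:
        self.trials.to_csv(path, index=False)


def _finish(task: str, rows: list[dict]) -> TrialPlan:
    df = pd.DataFrame(rows)
    for col in PLAN_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    df = df[PLAN_COLUMNS]
    df["trial_index"] = np.arange(len(df))
    return TrialPlan(task, df)


def build_similarity_pairs(image_set: ImageSet | None = None) -> TrialPlan:
    """All unordered image pairs of the similarity task.

    With the default 15-image set (5 per emotion) this yields 105 trials:
    30 within-emotion pairs (10 per emotion) and 75 between-emotion pairs
    (25 per emotion pair).
    """
    image_set = image_set or ImageSet.similarity_default()
    counts = pd.Series(image_set.emotions).value_counts()
    if counts.nunique() > 1:
        raise DesignError(f"unbalanced emotion categories: {counts.to_dict()}")
    if set(image_set.roles) != {"target"}:
        raise DesignError("similarity task uses target images only")
    rows = []
    for a, b in itertools.combinations(image_set.images, 2):
        ea, eb = image_set.emotion_of(a), image_set.emotion_of(b)
        if ea == eb:
            rows.append(dict(task="similarity", stimulus_a=a, stimulus_b=b,
                             emotion=ea, emotion_pair="within"))
        else:
            pair = "-".join(sorted([ea, eb]))
            rows.append(dict(task="similarity", stimulus_a=a, stimulus_b=b,
                             emotion=pd.NA, emotion_pair=pair))
    return _finish("similarity", rows)


def build_choice_trials(image_set: ImageSet, seed: int,
                        condition: str | None = None) -> TrialPlan:
    """The 55-trial pairwise tournament over 11 targets, plus a trap per trial.

    Every unordered pair of targets appears exactly once; the trap shown on
    each trial is drawn uniformly (with replacement) from the trap pool and
    the trial order is a seeded uniform permutation.
    """
    targets = image_set.targets
    traps = tuple(i for i, r in zip(image_set.images, image_set.roles)
                  if r == "trap")
    if len(set(targets)) != len(targets):
        raise DesignError("duplicate target images")
    if not traps:
        raise DesignError("trap pool is empty")
    rng = np.random.default_rng(seed)
    pairs = list(itertools.combinations(targets, 2))
    trap_ids = rng.choice(traps, size=len(pairs))
    order = rng.permutation(len(pairs))
    condition = condition or image_set.emotion_of(targets[0])
    rows = [
        dict(task="choice", stimulus_a=pairs[i][0], stimulus_b=pairs[i][1],
             stimulus_c=trap_ids[i], emotion=condition, trap_id=trap_ids[i])
        for i in order
    ]
    return _finish("choice", rows)


def build_plf_trials(
    emotions: Sequence[str] = EMOTIONS,
    actors: Sequence[str] = ("a1", "a2", "a3", "a4"),
    spatial_levels: Sequence[int] = (50, 100, 150),
    kinematic_levels: Sequence[int] = (50, 100, 150),
    seed: int = 0,
) -> TrialPlan:
    """The full emotion x actor x spatial x kinematic crossing, one trial
    each, in a seeded random order (108 trials, 12 per spatial x kinematic
    condition, under the default levels)."""
    cells = list(itertools.product(emotions, actors, spatial_levels,
                                   kinematic_levels))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cells))
    rows = [
        dict(task="plf", emotion=cells[i][0], actor=cells[i][1],
             spatial=cells[i][2], kinematic=cells[i][3],
             stimulus_a=f"plf_{cells[i][0]}_{cells[i][1]}_s{cells[i][2]}_k{cells[i][3]}")
        for i in order
    ]
    return _finish("plf", rows)


def build_vocab_items() -> list[tuple[str, str]]:
    """The 20 vocabulary-test emotion words with their valence tags."""
    return list(VOCAB_ITEMS)


def valence_map() -> dict[str, str]:
    return dict(VOCAB_ITEMS)
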