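"""Emotion differentiation: similarity ratings -> MDS -> cluster distances.

Pairwise similarity ratings (0 = not at all similar, 10 = very similar) are
inverted to dissimilarities (delta = 10 - rating), embedded with metric MDS
(SMACOF majorisation of raw stress), and summarised as the mean embedded
Euclidean distance within each emotion cluster (10 same-label pairs each)
and between each pair of clusters (25 cross-label pairs each). Larger
between-cluster distances index differentiation of distinct emotional
states; larger within-cluster distances index differentiation of similar
states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator
from sklearn.utils import check_random_state

from .design import EMOTIONS, ImageSet


def similarity_to_dissimilarity(ratings: pd.DataFrame,
                                images: tuple[str, ...] | None = None
                                ) -> tuple[np.ndarray, tuple[str, ...]]:
    """One-rating-per-pair table -> symmetric 15x15 dissimilarity matrix.

    delta_ij = 10 - rating_ij, zero diagonal. Errors list missing or
    duplicated pairs.
    """
    if images is None:
        images = tuple(sorted(set(ratings["stimulus_a"])
                              | set(ratings["stimulus_b"])))
    idx = {img: i for i, img in enumerate(images)}
    n = len(images)
    seen: dict[frozenset, float] = {}
    dup = []
    for t in ratings.itertuples():
        key = frozenset((t.stimulus_a, t.stimulus_b))
        if key in seen:
            dup.append(sorted(key))
        seen[key] = t.rating
    expected = {frozenset((a, b)) for i, a in enumerate(images)
                for b in images[i + 1:]}
    missing = expected - set(seen)
    if dup or missing:
        raise ValueError(
            f"duplicate pairs: {dup}; missing pairs: "
            f"{[sorted(m) for m in missing]}")
    D = np.zeros((n, n))
    for key, rating in seen.items():
        a, b = tuple(key)
        D[idx[a], idx[b]] = D[idx[b], idx[a]] = 10.0 - rating
    return D, images


def _raw_stress(D: np.ndarray, X: np.ndarray) -> float:
    d = squareform(pdist(X))
    iu = np.triu_indices_from(D, k=1)
    return float(((D[iu] - d[iu]) ** 2).sum())


def _smacof_single(D: np.ndarray, X: np.ndarray, max_iter: int, tol: float
                   ) -> tuple[np.ndarray, list[float]]:
    """One SMACOF run from a given start; returns (X, stress history)."""
    n = D.shape[0]
    history = [_raw_stress(D, X)]
    for _ in range(max_iter):
        d = squareform(pdist(X))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d > 0, D / d, 0.0)
        B = -ratio
        np.fill_diagonal(B, 0.0)
        np.fill_diagonal(B, -B.sum(axis=1))
        X = B @ X / n                                   # Guttman transform
        history.append(_raw_stress(D, X))
        if history[-2] - history[-1] < tol:
            break
    return X, history


class StressMDS(BaseEstimator):
    """Metric MDS minimising raw stress by SMACOF majorisation.

    Raw stress sum_{i<j} (delta_ij - ||x_i - x_j||)^2 is minimised via the
    Guttman transform, which guarantees a non-increasing stress sequence;
    the best of ``n_init`` seeded random starts is kept.

    Parameters
    ----------
    n_components : embedding dimensionality (default 2).
    n_init : random restarts (default 8).
    max_iter, tol : per-run iteration cap and absolute stress-decrease
        convergence threshold.
    random_state : seed for the random starts.

    Attributes
    ----------
    embedding_ : (n, n_components) coordinates of the best run.
    stress_ : final raw stress of the best run.
    stress_history_ : per-iteration stress of the best run (non-increasing).
    n_iter_ : iterations used by the best run.
    """

    def __init__(self, n_components: int = 2, n_init: int = 8,
                 max_iter: int = 300, tol: float = 1e-6,
                 random_state: int | None = 0):
        self.n_components = n_components
        self.n_init = n_init
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        self.fit_transform(X, y)
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        """Embed a precomputed square dissimilarity matrix."""
        D = np.asarray(X, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("expected a square dissimilarity matrix")
        if not np.allclose(D, D.T, atol=1e-8):
            raise ValueError("dissimilarity matrix must be symmetric")
        if (D < 0).any():
            raise ValueError("dissimilarities must be non-negative")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        rng = check_random_state(self.random_state)
        n = D.shape[0]
        scale = D.max() if D.max() > 0 else 1.0
        best = None
        for _ in range(self.n_init):
            X0 = rng.uniform(-scale / 2, scale / 2,
                             size=(n, self.n_components))
            Xf, hist = _smacof_single(D, X0, self.max_iter, self.tol)
            if best is None or hist[-1] < best[1][-1]:
                best = (Xf, hist)
        self.embedding_, self.stress_history_ = best
        self.stress_ = self.stress_history_[-1]
        self.n_iter_ = len(self.stress_history_) - 1
        return self.embedding_


@dataclass
class ClusterDistances:
    """Mean embedded distances between and within emotion clusters."""

    between: dict      # e.g. {"angry-happy": float, ...}
    within: dict       # e.g. {"angry": float, ...}
    between_mean: float
    within_mean: float


def cluster_distances(coords: np.ndarray, labels) -> ClusterDistances:
    """Average pairwise Euclidean distances by emotion-cluster membership.

    Each within-emotion mean covers the 10 same-label pairs; each
    between-pair mean covers the 25 cross-label pairs (for 5 images per
    emotion). The grand means average the three component means.
    """
    labels = np.asarray(labels)
    counts = pd.Series(labels).value_counts()
    if counts.nunique() > 1:
        raise ValueError(f"unbalanced cluster labels: {counts.to_dict()}")
    m = counts.iloc[0]
    d = squareform(pdist(np.asarray(coords, dtype=float)))
    emotions = sorted(counts.index)
    within, between = {}, {}
    for e in emotions:
        mask = labels == e
        sub = d[np.ix_(mask, mask)]
        iu = np.triu_indices(mask.sum(), k=1)
        assert len(iu[0]) == m * (m - 1) // 2
        within[e] = float(sub[iu].mean())
    for i, a in enumerate(emotions):
        for b in emotions[i + 1:]:
            block = d[np.ix_(labels == a, labels == b)]
            assert block.size == m * m
            between[f"{a}-{b}"] = float(block.mean())
    return ClusterDistances(
        between=between, within=within,
        between_mean=float(np.mean(list(between.values()))),
        within_mean=float(np.mean(list(within.values()))),
    )


def score_differentiation(similarity: pd.DataFrame,
                          n_components: int = 2, n_init: int = 8,
                          max_iter: int = 300, tol: float = 1e-6,
                          random_state: int = 0) -> pd.DataFrame:
    """Per-participant MDS + cluster-distance scores from a raw table.

    Output columns follow ``dist_between_*`` / ``dist_within_*`` naming with
    the final stress, dimensionality and seed recorded per row.
    """
    image_set = ImageSet.similarity_default()
    labels = np.asarray(image_set.emotions)
    rows = []
    for pid, grp in similarity.groupby("participant", sort=True):
        D, _ = similarity_to_dissimilarity(grp, image_set.images)
        mds = StressMDS(n_components=n_components, n_init=n_init,
                        max_iter=max_iter, tol=tol, random_state=random_state)
        coords = mds.fit_transform(D)
        cd = cluster_distances(coords, labels)
        rows.append(dict(
            participant=pid,
            dist_between_AH=cd.between["angry-happy"],
            dist_between_AS=cd.between["angry-sad"],
            dist_between_HS=cd.between["happy-sad"],
            dist_between_mean=cd.between_mean,
            dist_within_A=cd.within["angry"],
            dist_within_H=cd.within["happy"],
            dist_within_S=cd.within["sad"],
            dist_within_mean=cd.within_mean,
            stress=mds.stress_, k=n_components, seed=random_state,
        ))
    return pd.DataFrame(rows)
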