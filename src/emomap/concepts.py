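"""Emotion-concept measures from scored definitions and their embeddings.

Four per-participant quantities:

* vocabulary total — sum of the 20 human item scores (0/1/2 each; 0-40);
* mean definition word count — control covariate for definition length;
* pairwise conceptual distance — negative cosine similarity between the
  embedding vectors of two definitions (nominally in [-1, 0]);
* valence aggregates — within-valence distance is the unweighted mean of
  the 45 positive-positive pair mean and the 45 negative-negative pair
  mean; between-valence distance is the mean of the 100 cross-valence
  pairs. Higher (less negative) values mean more differentiated concepts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .design import valence_map

logger = logging.getLogger(__name__)

N_ITEMS = 20


def vocab_total(scores) -> int:
    """Sum the 20 item scores (each 0, 1 or 2) into a 0-40 total."""
    s = np.asarray(scores)
    if len(s) != N_ITEMS:
        raise ValueError(f"expected {N_ITEMS} item scores, got {len(s)}")
    if not np.isin(s, (0, 1, 2)).all():
        raise ValueError("item scores must be 0, 1 or 2")
    return int(s.sum())


def mean_word_count(word_counts) -> float:
    w = np.asarray(word_counts, dtype=float)
    if (w < 0).any():
        raise ValueError("word counts must be >= 0")
    return float(w.mean())


def count_words(text: str) -> int:
    """Whitespace tokenization, dropping punctuation-only tokens."""
    tokens = [t for t in text.split() if any(c.isalnum() for c in t)]
    return len(tokens)


@dataclass
class ConceptDistanceTable:
    """All 190 pairwise conceptual distances, keyed by word pair."""

    distances: dict          # frozenset({w1, w2}) -> -cos
    words: tuple[str, ...]

    def as_frame(self) -> pd.DataFrame:
        rows = [dict(word_a=min(k), word_b=max(k), distance=v)
                for k, v in self.distances.items()]
        return pd.DataFrame(rows).sort_values(["word_a", "word_b"],
                                              ignore_index=True)


def pairwise_conceptual_distance(words, vectors) -> ConceptDistanceTable:
    """Negative cosine similarity for every unordered pair of definitions.

    Vectors are expected unit-normalised; they are renormalised defensively
    and a zero vector is an error. Values outside [-1, 0] are legal but
    logged, since in practice definition embeddings correlate positively.
    """
    words = tuple(words)
    V = np.asarray(vectors, dtype=float)
    if V.shape[0] != len(words):
        raise ValueError("one vector per word required")
    norms = np.linalg.norm(V, axis=1)
    if (norms == 0).any():
        bad = [w for w, n in zip(words, norms) if n == 0]
        raise ValueError(f"zero embedding vector for: {bad}")
    U = V / norms[:, None]
    cos = U @ U.T
    table = {}
    for i, j in combinations(range(len(words)), 2):
        d = -float(cos[i, j])
        if d > 0:
            logger.info("conceptual distance above 0 for %s-%s: %.4f",
                        words[i], words[j], d)
        table[frozenset((words[i], words[j]))] = d
    return ConceptDistanceTable(distances=table, words=words)


def valence_aggregates(table: ConceptDistanceTable,
                       valences: dict | None = None) -> tuple[float, float]:
    """(within, between) valence aggregates of the 190 pair distances.

    Requires a 10/10 valence partition, giving 45 + 45 same-valence and
    100 cross-valence pairs. The within aggregate is the unweighted mean of
    the two same-valence means (not the pooled mean of 90 pairs).
    """
    valences = valences or valence_map()
    tags = [valences[w] for w in table.words]
    n_pos = tags.count("positive")
    if n_pos != 10 or len(tags) - n_pos != 10:
        raise ValueError(
            f"valence partition must be 10/10, got {n_pos} positive")
    groups = {"positive": [], "negative": [], "cross": []}
    for key, d in table.distances.items():
        a, b = tuple(key)
        va, vb = valences[a], valences[b]
        groups[va if va == vb else "cross"].append(d)
    assert (len(groups["positive"]), len(groups["negative"]),
            len(groups["cross"])) == (45, 45, 100)
    within = float(np.mean([np.mean(groups["positive"]),
                            np.mean(groups["negative"])]))
    between = float(np.mean(groups["cross"]))
    return within, between


def score_concepts(definitions: pd.DataFrame,
                   embeddings: pd.DataFrame) -> pd.DataFrame:
    """Per-participant concept measures from long-format cohort tables."""
    ecols = [c for c in embeddings.columns if c.startswith("e")]
    rows = []
    for pid, defs in definitions.groupby("participant", sort=True):
        emb = embeddings[embeddings["participant"] == pid]
        emb = emb.set_index("word").loc[list(defs["word"])]
        table = pairwise_conceptual_distance(defs["word"],
                                             emb[ecols].to_numpy())
        vmap = dict(zip(defs["word"], defs["valence"]))
        within, between = valence_aggregates(table, vmap)
        rows.append(dict(
            participant=pid,
            vocab_total=vocab_total(defs["score"]),
            mean_word_count=mean_word_count(defs["word_count"]),
            within_valence_distance=within,
            between_valence_distance=between,
        ))
    return pd.DataFrame(rows)
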