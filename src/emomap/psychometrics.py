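"""Instrument reliability: split-half (Spearman-Brown) and Cronbach's alpha."""

from __future__ import annotations

import numpy as np
from scipy import stats


def split_half_spearman_brown(matrix, split: str = "odd_even",
                              seed: int | None = None) -> float:
    """Split-half reliability with the Spearman-Brown length correction.

    Items are split into two halves (odd/even indices by default, or a
    seeded random half-split), half-scores are summed per participant, and
    the Pearson correlation r between half-scores is corrected to
    ``2 r / (1 + r)``.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2 or X.shape[0] < 3:
        raise ValueError("need a participants x items matrix, >=3 x >=2")
    idx = np.arange(X.shape[1])
    if split == "odd_even":
        first, second = idx[::2], idx[1::2]
    elif split == "random":
        rng = np.random.default_rng(seed)
        perm = rng.permutation(idx)
        half = X.shape[1] // 2
        first, second = perm[:half], perm[half:]
    else:
        raise ValueError(f"unknown split rule {split!r}")
    h1, h2 = X[:, first].sum(axis=1), X[:, second].sum(axis=1)
    if np.std(h1) == 0 or np.std(h2) == 0:
        raise ValueError("zero-variance half-score")
    r = float(stats.pearsonr(h1, h2).statistic)
    return 2 * r / (1 + r)


def cronbach_alpha(matrix) -> float:
    """Cronbach's alpha (unstandardised, sample variances).

    alpha = k/(k-1) * (1 - sum(item variances) / variance(total score)).
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2 or X.shape[0] < 3:
        raise ValueError("need a participants x items matrix, >=3 x >=2")
    item_var = X.var(axis=0, ddof=1)
    if (item_var == 0).any():
        raise ValueError("all-constant item column")
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero-variance total score")
    k = X.shape[1]
    return float(k / (k - 1) * (1 - item_var.sum() / total_var))
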