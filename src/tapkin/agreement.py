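"""Consensus labels and chance-corrected inter-rater agreement.

Multiple clinicians score each video on the ordinal 0-4 finger-tapping
scale; the per-video consensus is the modal rating (ties broken toward the
higher severity, favouring screening sensitivity) and the binary
bradykinesia flag is consensus >= 1. Agreement across raters is quantified
with Krippendorff's alpha, computed from the coincidence matrix with a
nominal or ordinal difference function and a percentile bootstrap CI over
items (videos) resampled with replacement.
"""

from __future__ import annotations

import warnings
from collections import Counter
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

Level = Literal["nominal", "ordinal"]


class UndefinedAlphaError(ValueError):
    """Alpha is undefined when expected disagreement is zero."""


def majority_label(ratings: Iterable[float]) -> int:
    """Modal rating of one item; ties resolve to the higher severity."""
    vals = [int(r) for r in ratings if not pd.isna(r)]
    if not vals:
        raise ValueError("item has no ratings")
    counts = Counter(vals)
    best = max(counts.values())
    return max(v for v, c in counts.items() if c == best)


def consensus_labels(table: pd.DataFrame, threshold: int = 1) -> pd.DataFrame:
    """Per-item consensus rating and binary bradykinesia flag.

    ``table`` is items x raters with NaN for missing ratings. The flag is
    consensus >= ``threshold`` (a finger-tapping score of at least 1).
    """
    cons = table.apply(majority_label, axis=1)
    return pd.DataFrame(
        {"consensus": cons.astype(int), "bradykinesia": (cons >= threshold).astype(int)}
    )


def _coincidence(table: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Coincidence matrix o_ck over rateable units and the category values.

    Each unit with m >= 2 ratings contributes every ordered pair of its
    ratings with weight 1/(m-1).
    """
    cats = np.unique(table[~np.isnan(table)])
    index = {c: i for i, c in enumerate(cats)}
    k = len(cats)
    o = np.zeros((k, k))
    for row in table:
        vals = row[~np.isnan(row)]
        m = len(vals)
        if m < 2:
            continue
        idx = [index[v] for v in vals]
        counts = np.bincount(idx, minlength=k)
        pair = np.outer(counts, counts) - np.diag(counts)
        o += pair / (m - 1)
    return o, cats


def _distance_sq(cats: np.ndarray, margins: np.ndarray, level: Level) -> np.ndarray:
    """Squared difference function delta^2 between category pairs."""
    k = len(cats)
    if level == "nominal":
        return 1.0 - np.eye(k)
    if level == "ordinal":
        # cumulative-margin distance: sum of margins between the two
        # categories minus half the endpoints' margins
        d = np.zeros((k, k))
        for c in range(k):
            for g in range(c + 1, k):
                d[c, g] = d[g, c] = (
                    margins[c : g + 1].sum() - (margins[c] + margins[g]) / 2.0
                ) ** 2
        return d
    raise ValueError(f"unknown metric level {level!r}")


def krippendorff_alpha(
    table: pd.DataFrame | np.ndarray, level: Level = "ordinal"
) -> float:
    """Krippendorff's alpha for an items x raters table with missing entries.

    alpha = 1 - D_o / D_e with observed and expected disagreement computed
    from the coincidence matrix and the level-appropriate squared
    difference function. Requires >= 2 units with >= 2 ratings.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("need an items x raters table with >= 2 raters")
    o, cats = _coincidence(arr)
    n_c = o.sum(axis=1)
    n = n_c.sum()
    if n < 2 or (n_c > 0).sum() == 0:
        raise UndefinedAlphaError("too few pairable ratings")
    d2 = _distance_sq(cats, n_c, level)
    d_e = (np.outer(n_c, n_c) - np.diag(n_c)) * d2
    expected = d_e.sum() / (n * (n - 1))
    if expected == 0:
        raise UndefinedAlphaError(
            "expected disagreement is zero (a single category in use)"
        )
    observed = (o * d2).sum() / n
    return float(1.0 - observed / expected)


def alpha_bootstrap_ci(
    table: pd.DataFrame | np.ndarray,
    level: Level = "ordinal",
    iterations: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile 95% bootstrap CI of alpha, resampling items with replacement.

    Replicates whose alpha is undefined (e.g. a resample using a single
    category) are skipped and counted; a warning is raised if more than 5%
    are skipped.
    """
    arr = np.asarray(table, dtype=float)
    rng = np.random.default_rng(seed)
    n_items = arr.shape[0]
    reps = []
    skipped = 0
    for _ in range(iterations):
        sample = arr[rng.integers(0, n_items, size=n_items)]
        try:
            reps.append(krippendorff_alpha(sample, level=level))
        except UndefinedAlphaError:
            skipped += 1
    if skipped > 0.05 * iterations:
        warnings.warn(
            f"{skipped}/{iterations} bootstrap replicates had undefined alpha",
            stacklevel=2,
        )
    if not reps:
        raise UndefinedAlphaError("all bootstrap replicates undefined")
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return float(lo), float(hi)


def ratings_from_csv(path) -> pd.DataFrame:
    """Read the long ratings CSV (item_id, rater_id, rating) into items x raters."""
    df = pd.read_csv(path)
    return df.pivot(index="item_id", columns="rater_id", values="rating")
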