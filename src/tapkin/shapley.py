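"""Sampling approximation of Shapley feature attributions.

Monte-Carlo permutation estimator: for a model score f, an instance x and a
background distribution B, the Shapley value of feature j is the expected
change in f when j's value is switched from a background draw to x_j,
averaged over random feature orderings. Each sampled permutation walks the
features in order, progressively replacing background values with the
instance's values; the marginal change attributed to each feature is an
unbiased draw of its Shapley contribution.
"""

from __future__ import annotations

from typing import Callable

import numpy as np


def sampling_shapley(
    score_fn: Callable[[np.ndarray], np.ndarray],
    background: np.ndarray,
    instances: np.ndarray,
    n_permutations: int = 30,
    rng: np.random.Generator | int = 0,
) -> np.ndarray:
    """Estimate per-instance Shapley attributions of ``score_fn``.

    Parameters
    ----------
    score_fn : maps an (m, p) array to m scalar scores (e.g. decision
        function or positive-class probability).
    background : (b, p) array the "feature absent" values are drawn from
        (typically the training set).
    instances : (n, p) array of instances to explain.
    n_permutations : sampled feature orderings per instance.
    rng : seed or Generator; fixed seed gives reproducible attributions.

    Returns
    -------
    (n, p) array of attributions; summing a row recovers
    score_fn(x) - score_fn(background draw) on average (local accuracy).
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    X = np.asarray(instances, dtype=float)
    B = np.asarray(background, dtype=float)
    n, p = X.shape
    contrib = np.zeros((n, p))
    for _ in range(n_permutations):
        order = rng.permutation(p)
        current = B[rng.integers(0, len(B), size=n)].copy()
        prev = np.asarray(score_fn(current), dtype=float)
        for j in order:
            current[:, j] = X[:, j]
            cur = np.asarray(score_fn(current), dtype=float)
            contrib[:, j] += cur - prev
            prev = cur
    return contrib / n_permutations


def mean_abs_attribution(attributions: np.ndarray) -> np.ndarray:
    """Global importance: mean absolute attribution per feature."""
    return np.abs(np.asarray(attributions)).mean(axis=0)
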