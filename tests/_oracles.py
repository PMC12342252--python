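"""Independent brute-force oracles used to validate the fast implementations.

These deliberately use naive O(n^2) enumeration straight from the
definitions and share no code with the package.
"""

from __future__ import annotations

import numpy as np


def brute_force_peaks(x, prominence: float):
    """All local maxima with topographic prominence >= threshold.

    A peak is an interior sample strictly greater than its left neighbour
    whose plateau (run of equal values) is followed by a strictly smaller
    sample; the leftmost plateau sample is reported. The prominence window
    extends on each side until the border or a sample strictly higher than
    the peak; the base on each side is the minimum over that stretch, and
    prominence is peak height minus the higher base.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    candidates = []
    i = 1
    while i < n - 1:
        if x[i] > x[i - 1]:
            j = i
            while j + 1 < n and x[j + 1] == x[i]:
                j += 1
            if j + 1 < n and x[j + 1] < x[i]:
                candidates.append(i)
            i = j + 1
        else:
            i += 1
    accepted = []
    proms = []
    for i in candidates:
        h = x[i]
        lmin = h
        j = i - 1
        while j >= 0 and x[j] <= h:
            lmin = min(lmin, x[j])
            j -= 1
        rmin = h
        j = i + 1
        while j < n and x[j] <= h:
            rmin = min(rmin, x[j])
            j += 1
        prom = h - max(lmin, rmin)
        if prom >= prominence:
            accepted.append(i)
            proms.append(prom)
    return np.array(accepted, dtype=int), np.array(proms, dtype=float)


def _odist_sq(values, counts_by_cat, cats):
    """Ordinal squared distance between two category values given margins."""
    c, k = sorted([cats.index(values[0]), cats.index(values[1])])
    margins = [counts_by_cat[cats[g]] for g in range(c, k + 1)]
    return (sum(margins) - (margins[0] + margins[-1]) / 2.0) ** 2


def alpha_bruteforce(table, level: str = "nominal") -> float:
    """Krippendorff's alpha by explicit pair enumeration over pairable values."""
    rows = []
    for row in np.asarray(table, dtype=float):
        vals = [v for v in row if not np.isnan(v)]
        if len(vals) >= 2:
            rows.append(vals)
    values = [v for vals in rows for v in vals]
    n = len(values)
    if n < 2:
        raise ValueError("too few pairable values")
    cats = sorted(set(values))
    counts = {c: values.count(c) for c in cats}

    def d2(a, b):
        if level == "nominal":
            return 0.0 if a == b else 1.0
        return _odist_sq((a, b), counts, cats) if a != b else 0.0

    d_obs = 0.0
    for vals in rows:
        m = len(vals)
        for i in range(m):
            for j in range(m):
                if i != j:
                    d_obs += d2(vals[i], vals[j]) / (m - 1)
    d_obs /= n

    d_exp = 0.0
    for i in range(n):
        for j in range(n):
            if i != j:
                d_exp += d2(values[i], values[j])
    d_exp /= n * (n - 1)
    if d_exp == 0:
        raise ValueError("expected disagreement is zero")
    return 1.0 - d_obs / d_exp
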