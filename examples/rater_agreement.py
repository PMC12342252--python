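"""Consensus labels and Krippendorff's alpha for multi-rater 0-4 scores.

Simulates four clinicians rating 100 videos on the ordinal finger-tapping
scale with imperfect reliability, builds majority-consensus labels, and
quantifies chance-corrected agreement with a bootstrap CI.
"""

import numpy as np
import pandas as pd

from tapkin import alpha_bootstrap_ci, consensus_labels, krippendorff_alpha

rng = np.random.default_rng(7)
latent = rng.integers(0, 5, size=100)          # true severity per video
ratings = pd.DataFrame(
    {
        rater: np.where(rng.random(100) < 0.75, latent, rng.integers(0, 5, 100))
        for rater in ["rater_a", "rater_b", "rater_c", "rater_d"]
    },
    index=[f"video_{i:03d}" for i in range(100)],
    dtype=float,
)

labels = consensus_labels(ratings)             # modal rating; flag = rating >= 1
alpha = krippendorff_alpha(ratings, level="ordinal")
lo, hi = alpha_bootstrap_ci(ratings, level="ordinal", iterations=1000, seed=7)

print(f"{labels['bradykinesia'].sum()} of {len(labels)} videos flagged bradykinetic "
      f"(consensus rating >= 1)")
print(f"ordinal Krippendorff's alpha = {alpha:.3f} "
      f"(95% bootstrap CI {lo:.3f}-{hi:.3f}, 1000 iterations)")
# Alpha is 1 under perfect agreement and ~0 for chance-level rating; values
# around 0.7 indicate the substantial-but-imperfect concordance typical of
# clinical bradykinesia scoring.
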