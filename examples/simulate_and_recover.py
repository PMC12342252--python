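"""Generate a synthetic tapping cohort and check parameter recovery.

Builds a small two-group cohort from the default clinical presets, runs the
full landmark-free pipeline (max-normalization -> prominence-0.3 peak
detection -> feature extraction), and compares group feature means against
the commanded preset values.
"""

import numpy as np

from tapkin import CohortSpec, build_feature_table, generate_cohort

cohort = generate_cohort(CohortSpec(n_control=40, n_pd=40, seed=7))
features = build_feature_table(cohort)

print(f"cohort: {len(cohort.subjects)} subjects, "
      f"{len(cohort.signals())} hand signals of "
      f"{len(cohort.subjects[0].right)} frames each\n")

commanded = {"control": (24.6, 85.4, 0.4), "bradykinesia": (17.9, 71.4, 2.8)}
for label, g in features.groupby("label"):
    ts, ta, td = commanded[label]
    print(f"{label:13s} extracted TS(right) {g['ts_right'].mean():5.1f} (commanded {ts})")
    print(f"{'':13s} extracted TA(right) {g['ta_right'].mean():5.1f} (commanded {ta})")
    print(f"{'':13s} extracted TD        {g['td'].mean():5.1f} (commanded {td})")

# Each line compares the pipeline's Monte-Carlo group mean with the preset
# value it was commanded to produce; agreement within a few tenths (TS, TD)
# or a couple of percent points (TA) shows the signal chain is unbiased.
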