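"""Nested cross-validated bradykinesia classification on a synthetic cohort.

Trains the SVM and logistic-regression families under the 5-fold outer /
3-fold inner stratified protocol and prints fold-aggregated metrics with
t-based 95% confidence intervals plus the Shapley feature ranking.
"""

from tapkin import CohortSpec, CVConfig, build_feature_table, generate_cohort, nested_cv
from tapkin.pipeline import feature_matrix

cohort = generate_cohort(CohortSpec(n_control=47, n_pd=53, seed=7))
X, y, names = feature_matrix(build_feature_table(cohort))
print(f"feature matrix: {X.shape[0]} subjects x {X.shape[1]} features\n")

for family in ("SVM", "LR"):
    rep = nested_cv(X, y, CVConfig(model_family=family, seed=7), feature_names=names)
    s = rep.summaries
    print(f"{family}:")
    for m in ("accuracy", "precision", "recall", "f1", "auc", "train_auc"):
        print(f"  {m:10s} {s[m].mean:.2f} ± {s[m].sd:.2f} "
              f"(95% CI {s[m].ci_low:.2f}-{s[m].ci_high:.2f})")
    top = ", ".join(n for n, _ in rep.feature_importances[:3])
    print(f"  top features by mean |Shapley attribution|: {top}\n")

# Test metrics are averaged over the 5 held-out outer folds; train_auc close
# to 1 with a lower test AUC flags overfitting. The top-ranked features are
# typically the inter-hand tap difference and right-hand tap count/amplitude,
# the kinematic signatures of asymmetric bradykinesia.
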