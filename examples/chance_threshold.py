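"""Estimate the chance-level cutoff for pattern accuracy.

Genuine scores (each response against its own environment's true layout)
are compared with null scores (the same responses against many foil
environments' layouts); the ROC-optimal cutoff separates the two, and
trials at or below it are classified as failed.
"""

from allomem import CohortConfig, simulate_cohort, classify_failed
from allomem.pipeline import (estimate_chance_threshold, make_foil_library,
                              score_response_table)

cohort = simulate_cohort(CohortConfig(n_subjects=6, seed=19))
truths = {e.env_id: e.truth for e in cohort.environments}
scores = score_response_table(cohort.responses, truths)

foils = make_foil_library(n_foils=60, n_objects=5, seed=19)
threshold = estimate_chance_threshold(
    scores, cohort.responses, foils,
    n_foils=50, n_null_subjects=3, n_null_trials=5, seed=19)

print(f"cutoff            {threshold.cutoff:.3f}")
print(f"youden index      {threshold.youden:.3f}")
print(f"balanced error    {threshold.misclassification:.3f}")
print(f"n genuine / null  {threshold.n_pos} / {threshold.n_neg}")

failed = scores["pattern_accuracy"].map(
    lambda s: classify_failed(s, threshold))
print(f"failed trials     {failed.sum()} of {len(failed)}")
# a score exactly at the cutoff counts as failed ("at or below chance")
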