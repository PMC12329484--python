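"""Stage functions binding scoring, thresholding, and association.

These are the library-level entry points the command line wraps: each takes
and returns in-memory tables, so they compose in scripts and notebooks
without touching the filesystem.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd

from ._rng import substream
from .association import AssociationConfig, aggregate_scores, association_pipeline
from .chance import (AlignConfig, ChanceThreshold, classify_failed,
                     estimate_threshold, null_scores)
from .errors import ValidationError
from .patterns import PositionalPattern
from .scoring import score_trial
from .simulate import CohortConfig, generate_environment, SHAPE_TEMPLATES

logger = logging.getLogger(__name__)


def score_response_table(responses: pd.DataFrame,
                         truths: dict[str, PositionalPattern],
                         config: AlignConfig | None = None) -> pd.DataFrame:
    """Score every trial in a response table against the true layouts.

    Returns the per-trial score table (failed=False throughout; chance
    classification is a separate stage).  A trial whose environment is
    missing from ``truths`` or whose object set does not match raises a
    validation error naming the trial.
    """
    config = config or AlignConfig()
    rows = []
    if responses.empty:
        raise ValidationError("empty response table: nothing to score")
    for (sid, tid, env_id), grp in responses.groupby(
            ["subject_id", "trial_id", "env_id"], sort=True):
        if env_id not in truths:
            raise ValidationError(
                f"trial ({sid}, {tid}): unknown environment {env_id!r}"
            )
        truth = truths[env_id]
        if sorted(grp["object_label"]) != sorted(truth.labels):
            raise ValidationError(
                f"trial ({sid}, {tid}): object labels {sorted(grp['object_label'])} "
                f"do not match environment {env_id!r} layout "
                f"{sorted(truth.labels)}"
            )
        response = PositionalPattern(grp[["x", "y"]].to_numpy(float),
                                     list(grp["object_label"]))
        s = score_trial(response, truth, config)
        rows.append({
            "subject_id": sid,
            "trial_id": tid,
            "env_id": env_id,
            "pattern_accuracy": s.pattern_accuracy,
            "raw_accuracy": s.raw_accuracy,
            "environmental_geometry": s.environmental_geometry,
            "object_identity": s.object_identity,
            "failed": False,
            "theta": s.transform.theta,
            "scale": s.transform.scale,
            "tx": float(s.transform.translation[0]),
            "ty": float(s.transform.translation[1]),
        })
    return pd.DataFrame(rows)


def make_foil_library(n_foils: int, n_objects: int, seed: int,
                      area_min: float = 50.0, area_max: float = 90.0
                      ) -> dict[str, PositionalPattern]:
    """Foil true layouts from freshly generated environments (the "extended
    set" the null distribution is built against)."""
    rng = substream(seed, "foil-library")
    families = list(SHAPE_TEMPLATES)
    out: dict[str, PositionalPattern] = {}
    for i in range(n_foils):
        family = families[int(rng.integers(len(families)))]
        area = rng.uniform(area_min, area_max)
        env = generate_environment(family, area, n_objects, rng,
                                   env_id=f"foil{i + 1:03d}")
        out[env.env_id] = env.truth
    return out


def estimate_chance_threshold(scores: pd.DataFrame,
                              responses: pd.DataFrame,
                              foil_truths: dict[str, PositionalPattern],
                              n_foils: int = 120,
                              n_null_subjects: int = 10,
                              n_null_trials: int = 10,
                              seed: int = 0,
                              method: str = "youden",
                              align_config: AlignConfig | None = None
                              ) -> ChanceThreshold:
    """Cohort-level chance cutoff for pattern accuracy.

    Positives are the cohort's own pattern-accuracy scores; negatives are
    foil comparisons from a seeded sub-group of subjects (each response
    scored against ``n_foils`` foil layouts, its own environment excluded).
    """
    rng = substream(seed, "chance-null")
    subjects = sorted(responses["subject_id"].unique())
    k = min(n_null_subjects, len(subjects))
    chosen = [subjects[int(i)]
              for i in rng.choice(len(subjects), size=k, replace=False)]
    null_pool: list[tuple[PositionalPattern, str]] = []
    for sid in chosen:
        sub = responses[responses["subject_id"] == sid]
        trials = sorted(sub["trial_id"].unique())[:n_null_trials]
        for tid in trials:
            grp = sub[sub["trial_id"] == tid]
            pattern = PositionalPattern(grp[["x", "y"]].to_numpy(float),
                                        list(grp["object_label"]))
            null_pool.append((pattern, str(grp["env_id"].iloc[0])))
    negatives = null_scores(null_pool, foil_truths, n_foils=n_foils,
                            rng=rng, config=align_config)
    positives = scores["pattern_accuracy"].to_numpy(float).tolist()
    return estimate_threshold(positives, negatives, method=method)


def apply_threshold(scores: pd.DataFrame,
                    threshold: ChanceThreshold) -> pd.DataFrame:
    """Flag failed trials (accuracy at or below the cutoff) and blank their
    environmental-geometry and object-identity entries."""
    out = scores.copy()
    failed = out["pattern_accuracy"].to_numpy(float) <= threshold.cutoff
    out["failed"] = failed
    out.loc[failed, "environmental_geometry"] = np.nan
    out.loc[failed, "object_identity"] = np.nan
    return out


def run_association(scores: pd.DataFrame, outcomes: Optional[pd.DataFrame],
                    tract_df: pd.DataFrame,
                    config: AssociationConfig | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate per-trial scores and fit the per-tract mixed models.

    Returns ``(summaries, results)``.
    """
    summaries = aggregate_scores(scores, outcomes)
    results = association_pipeline(summaries, tract_df, config)
    return summaries, results
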