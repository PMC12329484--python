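"""Self-contained evaluation routines for the package's headline properties.

Each function recomputes one quality-of-implementation quantity from
scratch at a configurable problem size: similarity invariance of pattern
accuracy, agreement of the alignment with brute-force oracles, behavior of
the chance threshold, and recovery of injected FA-behavior links by the
mixed-model pipeline.  They power both the acceptance script and the
acceptance test suite, with sizes scaled to the caller's time budget.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .association import association_pipeline, aggregate_scores
from .chance import estimate_threshold, null_scores, optimal_cutoff, roc_points
from .patterns import PositionalPattern
from .pipeline import (apply_threshold, estimate_chance_threshold,
                       make_foil_library, score_response_table)
from .scoring import (AlignConfig, Correspondence, SimilarityTransform,
                      exhaustive_align, align, nn_sse, optimal_rotation,
                      optimal_scale, paired_sse, pattern_accuracy)
from .simulate import (CohortConfig, DEFAULT_TRACTS, generate_environment,
                       make_profiles, simulate_cohort, simulate_response,
                       simulate_tract_measures, SHAPE_TEMPLATES)

TARGET_TRACTS = ("ILF", "MdLF", "fornix")

#: Reduced panel for Monte-Carlo work: the three tracts of interest plus
#: three bilateral control tracts.
MC_TRACTS = tuple(t for t in DEFAULT_TRACTS
                  if t[0] in TARGET_TRACTS
                  + ("frontal_aslant", "cingulum", "corticospinal"))


def _random_environment(rng, n_objects=5):
    family = list(SHAPE_TEMPLATES)[int(rng.integers(len(SHAPE_TEMPLATES)))]
    area = rng.uniform(50.0, 90.0)
    return generate_environment(family, area, n_objects, rng)


# ---------------------------------------------------------------------------
# scoring properties
# ---------------------------------------------------------------------------


def similarity_invariance(seed: int, n_instances: int = 500) -> dict:
    """Minimum pattern accuracy of similarity-transformed true layouts.

    Random environments, random in-bounds transforms (rotation uniform,
    scale log-uniform in [1/3, 3], arbitrary translation) and random label
    permutations; a correct implementation scores every instance at 1.
    """
    rng = substream(seed, "invariance")
    worst = np.inf
    for _ in range(n_instances):
        env = _random_environment(rng)
        truth = env.truth
        t = SimilarityTransform(
            rng.uniform(-np.pi, np.pi),
            float(np.exp(rng.uniform(np.log(1 / 3), np.log(3.0)))),
            rng.uniform(-30, 30, 2),
        )
        perm = rng.permutation(len(truth))
        response = PositionalPattern(t.apply(truth.points)[perm],
                                     [truth.labels[i] for i in perm])
        worst = min(worst, pattern_accuracy(response, truth))
    return {"value": float(worst), "n": n_instances}


def oracle_equivalence(seed: int, n_per_size: int = 200,
                       sizes: Sequence[int] = (4, 5, 6)) -> dict:
    """Largest gap between align's bijective SSE and the exhaustive n!
    correspondence search, over jittered transformed responses."""
    rng = substream(seed, "oracle")
    max_gap = 0.0
    total = 0
    for n in sizes:
        for _ in range(n_per_size):
            truth = PositionalPattern(
                rng.uniform(-4, 4, (n, 2)), [f"o{i}" for i in range(n)])
            t = SimilarityTransform(
                rng.uniform(-np.pi, np.pi),
                float(np.exp(rng.uniform(np.log(1 / 3), np.log(3.0)) / 2)),
                rng.uniform(-3, 3, 2),
            )
            pts = t.apply(truth.points) + rng.normal(0, 0.5, (n, 2))
            perm = rng.permutation(n)
            response = PositionalPattern(pts[perm],
                                         [truth.labels[i] for i in perm])
            transform, corr = align(response, truth)
            sse = paired_sse(response, truth, corr, transform)
            _, _, sse_oracle = exhaustive_align(response, truth)
            max_gap = max(max_gap, sse - sse_oracle)
            total += 1
    return {"value": float(max_gap), "n": total}


def rotation_grid_agreement(seed: int, n_instances: int = 100) -> dict:
    """Largest |closed-form rotation - 0.0005-rad grid search| (radians)."""
    rng = substream(seed, "rotation")
    grid = np.arange(-np.pi, np.pi, 0.0005)
    cos, sin = np.cos(grid), np.sin(grid)
    worst = 0.0
    for _ in range(n_instances):
        target = PositionalPattern(rng.uniform(-4, 4, (5, 2)),
                                   list("abcde")).centered()
        theta_true = rng.uniform(-np.pi, np.pi)
        source = SimilarityTransform(theta_true, 1.0, np.zeros(2)) \
            .apply_pattern(target)
        source = source.with_points(
            source.points + rng.normal(0, 0.3, (5, 2))).centered()
        theta = optimal_rotation(source, target,
                                 Correspondence(tuple(range(5))))
        x, y = source.points[:, 0], source.points[:, 1]
        rx = np.outer(cos, x) - np.outer(sin, y)
        ry = np.outer(sin, x) + np.outer(cos, y)
        sse = ((rx - target.points[:, 0]) ** 2
               + (ry - target.points[:, 1]) ** 2).sum(axis=1)
        theta_grid = grid[np.argmin(sse)]
        worst = max(worst, abs(math.remainder(theta - theta_grid,
                                              2 * math.pi)))
    return {"value": float(worst), "n": n_instances}


def scale_golden_agreement(seed: int, n_instances: int = 100) -> dict:
    """Largest |closed-form scale - golden-section line search|."""
    from scipy.optimize import minimize_scalar

    rng = substream(seed, "scale")
    worst = 0.0
    for _ in range(n_instances):
        target = PositionalPattern(rng.uniform(-4, 4, (5, 2)),
                                   list("abcde")).centered()
        s_true = float(np.exp(rng.uniform(-0.9, 0.9)))
        source = target.with_points(
            target.points * s_true + rng.normal(0, 0.2, (5, 2))).centered()
        s = optimal_scale(source, target, Correspondence(tuple(range(5))))

        def sse(scale):
            return float(((scale * source.points - target.points) ** 2).sum())

        g = np.linspace(0.01, 10.0, 400)
        k = int(np.argmin([sse(v) for v in g]))
        res = minimize_scalar(sse, bracket=(g[max(k - 1, 0)], g[k],
                                            g[min(k + 1, len(g) - 1)]),
                              method="golden", options={"xtol": 1e-12})
        worst = max(worst, abs(s - float(np.clip(res.x, 1 / 3, 3.0))))
    return {"value": float(worst), "n": n_instances}


def noise_monotonicity(seed: int, trials_per_level: int = 500,
                       sigmas: Sequence[float] = (0.0, 0.25, 0.5, 1.0, 2.0)
                       ) -> dict:
    """Number of adjacent jitter levels whose mean pattern accuracy fails
    to decrease strictly (0 for a correct implementation)."""
    rng = substream(seed, "monotonicity")
    envs = [_random_environment(rng) for _ in range(10)]
    means = []
    for sigma in sigmas:
        accs = []
        for k in range(trials_per_level):
            env = envs[k % len(envs)]
            pts = env.truth.points + rng.normal(0, sigma,
                                                (len(env.truth), 2))
            response = PositionalPattern(pts, env.truth.labels)
            accs.append(pattern_accuracy(response, env.truth))
        means.append(float(np.mean(accs)))
    violations = sum(1 for a, b in zip(means, means[1:]) if not b < a)
    return {"value": int(violations), "n": trials_per_level * len(sigmas),
            "means": means}


def decomposition_check(scores: pd.DataFrame) -> dict:
    """Violations of the score-decomposition contract on a scored table:
    pattern >= raw accuracy, environmental geometry in [-1, 0], object
    identity in {0..5}, and the latter two missing exactly when failed."""
    v = 0
    ok = ~scores["failed"].astype(bool)
    v += int((scores["pattern_accuracy"] < scores["raw_accuracy"] - 1e-9).sum())
    eg = scores.loc[ok, "environmental_geometry"]
    v += int(((eg < -1.0 - 1e-9) | (eg > 1e-9) | eg.isna()).sum())
    oi = scores.loc[ok, "object_identity"]
    v += int((~oi.isin(range(0, 6))).sum())
    v += int(scores.loc[~ok, "environmental_geometry"].notna().sum())
    v += int(scores.loc[~ok, "object_identity"].notna().sum())
    return {"value": int(v), "n": len(scores)}


# ---------------------------------------------------------------------------
# chance threshold
# ---------------------------------------------------------------------------


def chance_threshold_evaluation(seed: int, n_genuine: int = 160,
                                n_chance: int = 160, n_foil_responses: int = 40,
                                n_foils: int = 60) -> dict:
    """Held-out misclassification of the ROC cutoff, plus its gap to an
    exhaustive threshold scan.

    Genuine responses come from simulated recall where allocentric encoding
    took place (good-to-moderate ability, no outright-failure channel);
    chance responses are uniform placements.  The cutoff is trained on
    genuine scores vs foil comparisons and evaluated on held-out labeled
    scores of both kinds.
    """
    rng = substream(seed, "chance-eval")
    envs = [_random_environment(rng) for _ in range(12)]
    foils = make_foil_library(n_foils + 10, 5, seed)

    def genuine_scores(count):
        out = []
        for k in range(count):
            env = envs[k % len(envs)]
            profile_rng = rng
            from .simulate import SubjectProfile
            prof = SubjectProfile(subject_id="g",
                                  ability=float(rng.uniform(0.6, 0.95)),
                                  fail_prob_max=0.0)
            resp = simulate_response(env, prof, profile_rng)
            out.append(pattern_accuracy(resp, env.truth))
        return out

    def chance_scores(count):
        from .simulate import _sample_point_in
        out = []
        for k in range(count):
            env = envs[k % len(envs)]
            pts = np.vstack([_sample_point_in(env.polygon(), rng)
                             for _ in range(5)])
            resp = PositionalPattern(pts, env.truth.labels)
            out.append(pattern_accuracy(resp, env.truth))
        return out

    train_pos = genuine_scores(n_genuine)
    null_pool = []
    for k in range(n_foil_responses):
        env = envs[k % len(envs)]
        from .simulate import SubjectProfile
        prof = SubjectProfile(subject_id="g",
                              ability=float(rng.uniform(0.6, 0.95)),
                              fail_prob_max=0.0)
        null_pool.append((simulate_response(env, prof, rng), env.env_id))
    train_neg = null_scores(null_pool, foils, n_foils=n_foils, rng=rng)

    threshold = estimate_threshold(train_pos, train_neg)

    # exhaustive scan over every candidate threshold
    roc = roc_points(train_pos, train_neg)
    pos, neg = np.asarray(train_pos), np.asarray(train_neg)
    best = max(float(np.mean(pos > t) + np.mean(neg <= t))
               for t in roc.thresholds)
    achieved = float(np.mean(pos > threshold.cutoff)
                     + np.mean(neg <= threshold.cutoff))
    scan_gap = best - achieved

    test_pos = np.asarray(genuine_scores(n_genuine))
    test_neg = np.asarray(chance_scores(n_chance))
    err = (float((test_pos <= threshold.cutoff).mean())
           + float((test_neg > threshold.cutoff).mean())) / 2.0
    return {
        "misclassification_pct": 100.0 * err,
        "scan_gap": float(scan_gap),
        "cutoff": threshold.cutoff,
        "n": int(n_genuine + n_chance),
    }


# ---------------------------------------------------------------------------
# association recovery
# ---------------------------------------------------------------------------


def _behavior_tables(cfg: CohortConfig, cutoff: float):
    cohort = simulate_cohort(cfg)
    truths = {e.env_id: e.truth for e in cohort.environments}
    scores = score_response_table(cohort.responses, truths)
    from .chance import ChanceThreshold
    thr = ChanceThreshold(cutoff=cutoff, youden=np.nan, misclassification=np.nan)
    flagged = apply_threshold(scores, thr)
    summaries = aggregate_scores(flagged, cohort.outcomes)
    return cohort, summaries


def calibrate_cutoff(seed: int, n_foils: int = 60) -> float:
    """Chance cutoff estimated once from a calibration cohort; reused across
    Monte-Carlo replicates (the cutoff depends on the paradigm's geometry
    and noise, not on the tract model)."""
    cfg = CohortConfig(n_subjects=12, seed=int(
        substream(seed, "calibration").integers(2**31)))
    cohort = simulate_cohort(cfg)
    truths = {e.env_id: e.truth for e in cohort.environments}
    scores = score_response_table(cohort.responses, truths)
    foils = make_foil_library(n_foils + 10, cfg.n_objects, seed)
    thr = estimate_chance_threshold(
        scores, cohort.responses, foils, n_foils=n_foils,
        n_null_subjects=6, n_null_trials=6, seed=seed)
    return float(thr.cutoff)


def recovery_power(seed: int, n_replicates: int = 40, slope: float = 0.10,
                   cutoff: float | None = None) -> dict:
    """Fraction of replicates where the pattern-accuracy term is flagged
    (stepwise AIC + pooled BH-FDR) for all three target tracts' FA.

    Each replicate is an end-to-end n=83 session: simulate, score, classify
    failures, aggregate; FA for the target tracts carries a ``slope`` per
    unit mean pattern accuracy, everything else is null.  The fraction of
    replicates with no control-tract pattern-accuracy flag is reported
    alongside (``clean_pct``): post-selection inference on collinear
    behavioral candidates occasionally promotes a chance association on a
    null tract past the pooled correction.
    """
    if cutoff is None:
        cutoff = calibrate_cutoff(seed)
    successes = 0
    detected = 0
    clean = 0
    for rep in range(n_replicates):
        rep_seed = int(substream(seed, "power", rep).integers(2**31))
        # everything except the three target FA slopes is null: no nuisance
        # covariate effects, no hemisphere offsets, no MD links
        cfg = CohortConfig(n_subjects=83, seed=rep_seed, tracts=MC_TRACTS,
                           fa_slope={t: slope for t in TARGET_TRACTS},
                           md_slope={},
                           gamma_dropout_fa=0.0, gamma_pvf_fa=0.0,
                           gamma_dropout_md=0.0, gamma_pvf_md=0.0,
                           hemisphere_offset_fa=0.0,
                           hemisphere_offset_md=0.0)
        cohort, summaries = _behavior_tables(cfg, cutoff)
        trait = summaries.set_index("subject_id")["mean_pattern_accuracy"]
        trait = trait.fillna(trait.mean()).to_dict()
        tracts = simulate_tract_measures(
            cohort.profiles, cfg, substream(rep_seed, "tract-table"),
            trait=trait)
        results = association_pipeline(summaries, tracts)
        sig = results[results["fdr_significant"]
                      & (results["term"] == "mean_pattern_accuracy")]
        sig_models = set(sig["model_id"])
        got_all = all(f"{t}:FA" in sig_models for t in TARGET_TRACTS)
        controls = {m for m in sig_models
                    if m.split(":")[0] not in TARGET_TRACTS}
        detected += got_all
        clean += not controls
        successes += got_all and not controls
    return {
        "value": 100.0 * detected / n_replicates,
        "detection_pct": 100.0 * detected / n_replicates,
        "clean_pct": 100.0 * clean / n_replicates,
        "joint_pct": 100.0 * successes / n_replicates,
        "n": n_replicates,
    }


def null_false_positive_rate(seed: int, n_replicates: int = 80,
                             cutoff: float | None = None) -> dict:
    """Mean percentage of candidate terms flagged by the pooled FDR when
    every tract-behavior link (and every nuisance effect) is null.

    The behavioral summaries come from one scored session; each replicate
    draws a fresh all-null tract table (FA and MD independent of behavior),
    so the flagged fraction estimates the pipeline's false-positive rate.
    """
    if cutoff is None:
        cutoff = calibrate_cutoff(seed)
    null_cfg = CohortConfig(
        n_subjects=83,
        seed=int(substream(seed, "null-behavior").integers(2**31)),
        tracts=MC_TRACTS, fa_slope={}, md_slope={},
        gamma_dropout_fa=0.0, gamma_pvf_fa=0.0,
        gamma_dropout_md=0.0, gamma_pvf_md=0.0,
        hemisphere_offset_fa=0.0, hemisphere_offset_md=0.0,
    )
    _, summaries = _behavior_tables(null_cfg, cutoff)
    profiles = make_profiles(null_cfg)
    rates = []
    for rep in range(n_replicates):
        rng = substream(seed, "null-tracts", rep)
        tracts = simulate_tract_measures(profiles, null_cfg, rng)
        results = association_pipeline(summaries, tracts)
        rates.append(results["fdr_significant"].mean())
    return {"value": 100.0 * float(np.mean(rates)), "n": n_replicates}


# ---------------------------------------------------------------------------
# generator conformance
# ---------------------------------------------------------------------------


def generator_conformance(seed: int) -> dict:
    """Paradigm-facing facts of a default session, measured from a
    generated cohort."""
    cfg = CohortConfig(seed=seed)
    cohort = simulate_cohort(cfg)
    areas = [e.area for e in cohort.environments]
    schedule_lengths = {len(s) for s in cohort.schedules.values()}
    out_of_bounds = sum(1 for a in areas if not 50.0 <= a <= 90.0)
    return {
        "environments_per_session": len(cohort.environments),
        "objects_per_environment": int(np.mean(
            [len(e.truth) for e in cohort.environments])),
        "blocks_per_session": schedule_lengths.pop(),
        "shape_families_available": len(SHAPE_TEMPLATES),
        "area_bound_violations": out_of_bounds,
        "cohort_subjects": len(cohort.profiles),
    }
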