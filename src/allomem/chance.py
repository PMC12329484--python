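"""Chance-level estimation for pattern accuracy via ROC analysis.

Some trials carry no evidence that allocentric encoding took place; keeping
them would only add noise downstream.  A trial is "failed" when its pattern
accuracy is at or below chance level.  Chance level is estimated empirically:
the distribution of genuine scores (responses scored against their own
environment's true layout) is compared with a null distribution of the same
responses scored against the true layouts of many *foil* environments
(default 120, the correct one excluded).  An ROC curve over the two
distributions yields the optimal cutoff, by default the threshold maximizing
sensitivity + specificity (the Youden criterion).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import ConfigError, InvalidInputError
from .patterns import PositionalPattern
from .scoring import AlignConfig, pattern_accuracy

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RocCurve:
    """Sensitivity/specificity over candidate thresholds.

    Thresholds are midpoints between adjacent distinct pooled scores plus
    -inf/+inf sentinels.  Sensitivity is the fraction of positives strictly
    above a threshold; specificity the fraction of negatives at or below it.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray


@dataclass(frozen=True)
class ChanceThreshold:
    """An ROC-derived chance-level cutoff for pattern accuracy.

    ``youden`` is sensitivity + specificity - 1 at the cutoff;
    ``misclassification`` the balanced error 1 - (sens + spec) / 2.
    """

    cutoff: float
    youden: float
    misclassification: float
    n_pos: int = 0
    n_neg: int = 0


def null_scores(responses: Sequence[tuple[PositionalPattern, str]],
                foil_truths: dict[str, PositionalPattern],
                n_foils: int = 120,
                rng: Optional[np.random.Generator] = None,
                config: AlignConfig | None = None) -> list[float]:
    """Pattern accuracies of responses against foil environments' true layouts.

    Parameters
    ----------
    responses
        Pairs ``(recalled pattern, env_id of the correct environment)``; the
        correct environment is excluded from each response's foil draw.
    foil_truths
        Foil library: env_id -> true layout.
    n_foils
        Foils drawn (without replacement, seeded) per response.
    """
    config = config or AlignConfig()
    rng = rng if rng is not None else np.random.default_rng()
    scores: list[float] = []
    for response, true_env in responses:
        eligible = []
        for env_id, truth in foil_truths.items():
            if env_id == true_env:
                continue
            if len(truth) != len(response):
                logger.warning(
                    "foil %s skipped: %d objects vs response's %d",
                    env_id, len(truth), len(response),
                )
                continue
            eligible.append(env_id)
        if len(eligible) < n_foils:
            raise ConfigError(
                f"foil library has {len(eligible)} usable foils for env "
                f"{true_env}, need {n_foils}"
            )
        chosen = rng.choice(len(eligible), size=n_foils, replace=False)
        for idx in sorted(chosen):
            foil = foil_truths[eligible[int(idx)]]
            # foils have different labels; compare on geometry alone by
            # relabeling the foil truth with the response's label set
            relabeled = PositionalPattern(foil.points, response.labels)
            scores.append(pattern_accuracy(response, relabeled, config))
    return scores


def roc_points(positive_scores: Iterable[float],
               negative_scores: Iterable[float]) -> RocCurve:
    """ROC curve from exhaustive counting at every distinguishable threshold."""
    pos = np.asarray(list(positive_scores), dtype=float)
    neg = np.asarray(list(negative_scores), dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise InvalidInputError("both score classes must be non-empty")
    pooled = np.unique(np.concatenate([pos, neg]))
    mids = (pooled[:-1] + pooled[1:]) / 2.0 if pooled.size > 1 else np.empty(0)
    thresholds = np.concatenate([[-np.inf], mids, [np.inf]])
    sens = np.array([(pos > t).mean() for t in thresholds])
    spec = np.array([(neg <= t).mean() for t in thresholds])
    return RocCurve(thresholds=thresholds, sensitivity=sens, specificity=spec)


def optimal_cutoff(roc: RocCurve, method: str = "youden",
                   n_pos: int = 0, n_neg: int = 0) -> ChanceThreshold:
    """Pick the operating threshold from an ROC curve.

    ``method="youden"`` (default) maximizes sensitivity + specificity, ties
    broken toward higher specificity; ``method="closest_topleft"`` minimizes
    the squared distance to the perfect-classification corner.
    """
    sens, spec, thr = roc.sensitivity, roc.specificity, roc.thresholds
    if method == "youden":
        objective = sens + spec
        best = np.max(objective)
        tied = np.flatnonzero(objective >= best - 1e-12)
        best_spec = np.max(spec[tied])
        tied = tied[spec[tied] >= best_spec - 1e-12]
        i = int(tied[0])
    elif method == "closest_topleft":
        objective = (1.0 - sens) ** 2 + (1.0 - spec) ** 2
        i = int(np.argmin(objective))
    else:
        raise ConfigError(f"unknown cutoff method {method!r}")
    finite = thr[np.isfinite(thr)]
    cutoff = float(thr[i])
    if not np.isfinite(cutoff) and finite.size:
        cutoff = float(np.clip(cutoff, finite.min(), finite.max()))
    return ChanceThreshold(
        cutoff=cutoff,
        youden=float(sens[i] + spec[i] - 1.0),
        misclassification=float(1.0 - (sens[i] + spec[i]) / 2.0),
        n_pos=n_pos,
        n_neg=n_neg,
    )


def estimate_threshold(positive_scores: Iterable[float],
                       negative_scores: Iterable[float],
                       method: str = "youden") -> ChanceThreshold:
    """Convenience wrapper: ROC construction plus cutoff selection."""
    pos = list(positive_scores)
    neg = list(negative_scores)
    roc = roc_points(pos, neg)
    return optimal_cutoff(roc, method=method, n_pos=len(pos), n_neg=len(neg))


def classify_failed(score: float, threshold: ChanceThreshold) -> bool:
    """A trial fails when its accuracy is at or below the chance cutoff."""
    return bool(score <= threshold.cutoff)
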