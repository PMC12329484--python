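"""Synthetic cohort generation for the virtual-environment paradigm.

Emulates a study session in which participants freely explore small virtual
rooms and later reproduce each room's object layout by drag-and-drop on a 2D
overview: 15 environments presented over 7 runs of 5 blocks, each room one
of 10 perimeter shapes with an area between 50 and 90 virtual m^2 and five
uniquely identified objects.

Participant behavior is driven by a single latent spatial-memory ability in
[0, 1].  Every error channel scales linearly with (1 - ability):

* a random similarity transform of the whole pattern (rotation, log-scale,
  translation) — mis-anchoring to the room;
* independent per-object positional jitter;
* label transpositions — remembering the pattern but not which object
  went where;
* outright failures — the response is a uniform random placement.

Per-subject tract measures (FA/MD with dropout, partial-volume fraction and
demographic covariates) are generated at the table level with configurable
linear ability-FA slopes, so the downstream association models have a known
ground truth to recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point as ShapelyPoint
from shapely.geometry import Polygon

from ._rng import substream
from .errors import ConfigError, GenerationError
from .patterns import PositionalPattern
from .scoring import SimilarityTransform

# ---------------------------------------------------------------------------
# perimeter shape templates
# ---------------------------------------------------------------------------

_SQ3 = math.sqrt(3.0)


def _regular(n: int) -> list[tuple[float, float]]:
    return [
        (math.cos(2 * math.pi * k / n + math.pi / 2),
         math.sin(2 * math.pi * k / n + math.pi / 2))
        for k in range(n)
    ]


#: The 10 available perimeter families, as unit template polygons (CCW).
SHAPE_TEMPLATES: dict[str, list[tuple[float, float]]] = {
    "square": [(0, 0), (1, 0), (1, 1), (0, 1)],
    "rectangle": [(0, 0), (2, 0), (2, 1), (0, 1)],
    "triangle": [(0, 0), (1, 0), (0.5, _SQ3 / 2)],
    "trapezoid": [(0, 0), (3, 0), (2.2, 1), (0.8, 1)],
    "pentagon": _regular(5),
    "hexagon": _regular(6),
    "octagon": _regular(8),
    "l_shape": [(0, 0), (2, 0), (2, 1), (1, 1), (1, 2), (0, 2)],
    "t_shape": [(1, 0), (2, 0), (2, 2), (3, 2), (3, 3), (0, 3), (0, 2), (1, 2)],
    "cross": [(1, 0), (2, 0), (2, 1), (3, 1), (3, 2), (2, 2),
              (2, 3), (1, 3), (1, 2), (0, 2), (0, 1), (1, 1)],
}

#: Default white-matter tract panel: (tract, bilateral, FA baseline, MD baseline).
#: MD in 1e-3 mm^2/s.  The three tracts of interest come first; the rest act
#: as controls.  Baselines are typical adult tract means.
DEFAULT_TRACTS: tuple[tuple[str, bool, float, float], ...] = (
    ("ILF", True, 0.50, 0.78),
    ("MdLF", True, 0.48, 0.77),
    ("fornix", True, 0.40, 0.95),
    ("frontal_aslant", True, 0.45, 0.75),
    ("arcuate", True, 0.50, 0.74),
    ("cingulum", True, 0.55, 0.73),
    ("corticospinal", True, 0.60, 0.72),
    ("SLF", True, 0.46, 0.74),
    ("uncinate", True, 0.45, 0.76),
    ("anterior_thalamic", True, 0.42, 0.77),
    ("cc_genu", False, 0.65, 0.80),
    ("cc_splenium", False, 0.70, 0.78),
    ("anterior_commissure", False, 0.45, 0.85),
    ("mid_cerebellar_peduncle", False, 0.55, 0.72),
)


@dataclass(frozen=True)
class Environment:
    """A virtual room: perimeter polygon plus the true object layout."""

    env_id: str
    shape_family: str
    perimeter: np.ndarray  # (m, 2) vertices, virtual meters, centroid at origin
    truth: PositionalPattern
    area: float

    def polygon(self) -> Polygon:
        return Polygon(self.perimeter)


@dataclass(frozen=True)
class SubjectProfile:
    """Latent ability and noise ceilings for one simulated participant."""

    subject_id: str
    ability: float
    jitter_sigma_max: float = 1.0
    theta_sd_max: float = 0.4
    log_scale_sd_max: float = 0.2
    translation_sd_max: float = 1.2
    swap_prob_max: float = 0.3
    fail_prob_max: float = 0.3
    in_scanner: bool = True
    age: float = 24.0

    def __post_init__(self):
        if not 0.0 <= self.ability <= 1.0:
            raise ConfigError(f"ability must lie in [0, 1], got {self.ability}")
        for name in ("jitter_sigma_max", "theta_sd_max", "log_scale_sd_max",
                     "translation_sd_max"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("swap_prob_max", "fail_prob_max"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")


@dataclass
class CohortConfig:
    """Study-design and noise parameters for a synthetic cohort.

    Defaults reproduce the paradigm: 83 participants, 15 environments over
    7 runs x 5 blocks, rooms of 50-90 virtual m^2 drawn from 10 shape
    families, 5 objects each.  FA slopes of 0.10 FA-units per unit ability
    are injected for the ILF, MdLF, and fornix; all other tracts are null
    controls.
    """

    n_subjects: int = 83
    n_environments: int = 15
    runs: int = 7
    blocks_per_run: int = 5
    n_objects: int = 5
    area_min: float = 50.0
    area_max: float = 90.0
    wall_margin: float = 0.5
    min_separation: float = 1.0
    max_attempts: int = 10_000

    # behavioral noise ceilings (scaled by 1 - ability per subject)
    jitter_sigma_max: float = 1.0
    theta_sd_max: float = 0.4
    log_scale_sd_max: float = 0.2
    translation_sd_max: float = 1.2
    swap_prob_max: float = 0.3
    fail_prob_max: float = 0.3
    ability_beta: tuple[float, float] = (2.5, 1.5)

    # binary (non-allocentric) outcome model: P(correct) = logistic(b0 + b1*a)
    assoc_logit: tuple[float, float] = (-0.5, 2.5)
    room_logit: tuple[float, float] = (-0.3, 2.0)

    # tract-measure model
    tracts: tuple[tuple[str, bool, float, float], ...] = DEFAULT_TRACTS
    fa_slope: dict = field(
        default_factory=lambda: {"ILF": 0.10, "MdLF": 0.10, "fornix": 0.10}
    )
    md_slope: dict = field(default_factory=dict)
    fa_noise_sd: float = 0.02
    md_noise_sd: float = 0.02
    hemisphere_offset_fa: float = 0.005
    hemisphere_offset_md: float = 0.002
    gamma_dropout_fa: float = -0.005
    gamma_pvf_fa: float = 0.02
    gamma_dropout_md: float = 0.005
    gamma_pvf_md: float = -0.01
    missing_counts: dict = field(
        default_factory=lambda: {
            "fornix": 4, "corticospinal": 2, "anterior_commissure": 4,
        }
    )
    in_scanner_prob: float = 0.85
    age_range: tuple[int, int] = (18, 31)

    seed: int = 0

    def __post_init__(self):
        if self.runs * self.blocks_per_run < self.n_environments:
            raise ConfigError(
                f"{self.runs} runs x {self.blocks_per_run} blocks cannot show "
                f"{self.n_environments} environments at least once"
            )
        for name in ("n_subjects", "n_environments", "runs",
                     "blocks_per_run", "n_objects"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not self.area_min <= self.area_max:
            raise ConfigError("area_min must not exceed area_max")

    @property
    def n_blocks(self) -> int:
        return self.runs * self.blocks_per_run


@dataclass
class CohortData:
    """Everything one synthetic session produces, plus the generating truth."""

    config: CohortConfig
    environments: list[Environment]
    profiles: list[SubjectProfile]
    schedules: dict[str, list[str]]
    responses: pd.DataFrame   # subject_id, trial_id, env_id, object_label, x, y
    outcomes: pd.DataFrame    # subject_id, trial_id, env_id, objects_association, objects_room
    tracts: pd.DataFrame      # long: subject_id, tract, hemisphere, measure, value, ...
    truth_record: dict


# ---------------------------------------------------------------------------
# environments and schedules
# ---------------------------------------------------------------------------


def _sample_point_in(polygon: Polygon, rng: np.random.Generator,
                     max_attempts: int = 10_000) -> np.ndarray:
    minx, miny, maxx, maxy = polygon.bounds
    for _ in range(max_attempts):
        p = np.array([rng.uniform(minx, maxx), rng.uniform(miny, maxy)])
        if polygon.contains(ShapelyPoint(p)):
            return p
    raise GenerationError("could not sample a point inside the polygon")


def generate_environment(shape_family: str, area_target: float, n_objects: int,
                         rng: np.random.Generator, env_id: str = "env",
                         wall_margin: float = 0.5, min_separation: float = 1.0,
                         max_attempts: int = 10_000) -> Environment:
    """Build one room: template polygon scaled to the target area, objects
    placed by rejection sampling with wall-margin and separation constraints."""
    if shape_family not in SHAPE_TEMPLATES:
        raise ConfigError(
            f"unknown shape family {shape_family!r}; "
            f"choose from {sorted(SHAPE_TEMPLATES)}"
        )
    template = Polygon(SHAPE_TEMPLATES[shape_family])
    factor = math.sqrt(area_target / template.area)
    scaled = np.asarray(template.exterior.coords[:-1], dtype=float) * factor
    poly = Polygon(scaled)
    centroid = np.asarray(poly.centroid.coords[0])
    perimeter = scaled - centroid  # origin at the perimeter centroid
    poly = Polygon(perimeter)

    inner = poly.buffer(-wall_margin)
    if inner.is_empty:
        raise GenerationError(
            f"wall margin {wall_margin} leaves no interior in {shape_family} "
            f"of area {area_target}"
        )
    placed: list[np.ndarray] = []
    attempts = 0
    while len(placed) < n_objects:
        if attempts >= max_attempts:
            raise GenerationError(
                f"object placement failed after {max_attempts} attempts "
                f"({shape_family}, area {area_target:.1f})"
            )
        attempts += 1
        p = _sample_point_in(inner, rng, max_attempts)
        if all(np.linalg.norm(p - q) >= min_separation for q in placed):
            placed.append(p)
    labels = [f"obj{i + 1}" for i in range(n_objects)]
    truth = PositionalPattern(np.vstack(placed), labels)
    return Environment(env_id=env_id, shape_family=shape_family,
                       perimeter=perimeter, truth=truth, area=float(poly.area))


def generate_session(config: CohortConfig,
                     rng: np.random.Generator) -> list[Environment]:
    """The cohort's shared set of environments.

    Each of the 10 shape families appears at least once when the session has
    >= 10 environments; areas are uniform within the configured bounds.
    """
    families = list(SHAPE_TEMPLATES)
    chosen: list[str] = []
    while len(chosen) < config.n_environments:
        order = list(rng.permutation(families))
        chosen.extend(order)
    chosen = chosen[: config.n_environments]
    envs = []
    for i, family in enumerate(chosen):
        area = rng.uniform(config.area_min, config.area_max)
        envs.append(
            generate_environment(
                family, area, config.n_objects, rng,
                env_id=f"env{i + 1:02d}",
                wall_margin=config.wall_margin,
                min_separation=config.min_separation,
                max_attempts=config.max_attempts,
            )
        )
    return envs


def make_schedule(env_ids: Sequence[str], config: CohortConfig,
                  rng: np.random.Generator) -> list[str]:
    """A subject's block order: every environment at least once, repeats
    spread evenly, sequence randomized per subject."""
    n_blocks = config.n_blocks
    reps = math.ceil(n_blocks / len(env_ids))
    pool = (list(env_ids) * reps)[:n_blocks]
    order = rng.permutation(len(pool))
    return [pool[i] for i in order]


# ---------------------------------------------------------------------------
# responses and outcomes
# ---------------------------------------------------------------------------


def simulate_response(env: Environment, profile: SubjectProfile,
                      rng: np.random.Generator) -> PositionalPattern:
    """One simulated drag-and-drop response for one environment.

    With probability ``fail_prob_max * (1 - ability)`` the response is a
    uniform random placement inside the room (a chance-level trial);
    otherwise the true pattern is distorted by a random similarity
    transform about its centroid, per-object Gaussian jitter, and random
    label transpositions, all scaled by ``1 - ability``.
    """
    a = profile.ability
    noise = 1.0 - a
    truth = env.truth
    n = len(truth)

    if rng.random() < profile.fail_prob_max * noise:
        poly = env.polygon()
        pts = np.vstack([_sample_point_in(poly, rng) for _ in range(n)])
        return PositionalPattern(pts, truth.labels)

    theta = rng.normal(0.0, profile.theta_sd_max * noise)
    log_s = rng.normal(0.0, profile.log_scale_sd_max * noise)
    trans = rng.normal(0.0, profile.translation_sd_max * noise, size=2)
    c = truth.points.mean(axis=0)
    distort = SimilarityTransform(theta, math.exp(log_s), np.zeros(2))
    pts = distort.apply(truth.points - c) + c + trans
    pts = pts + rng.normal(0.0, profile.jitter_sigma_max * noise, size=(n, 2))

    labels = list(truth.labels)
    p_swap = profile.swap_prob_max * noise
    for i in range(n):
        if rng.random() < p_swap:
            j = int(rng.integers(n))
            labels[i], labels[j] = labels[j], labels[i]
    return PositionalPattern(pts, labels)


def simulate_outcomes(profile: SubjectProfile, schedule: Sequence[str],
                      config: CohortConfig,
                      rng: np.random.Generator) -> list[dict]:
    """Binary non-allocentric outcomes (objects-association and objects-room
    tests), Bernoulli with success probability logistic in ability."""
    def logistic(b0, b1):
        return 1.0 / (1.0 + math.exp(-(b0 + b1 * profile.ability)))

    p_assoc = logistic(*config.assoc_logit)
    p_room = logistic(*config.room_logit)
    rows = []
    for t, env_id in enumerate(schedule):
        rows.append({
            "subject_id": profile.subject_id,
            "trial_id": f"t{t + 1:02d}",
            "env_id": env_id,
            "objects_association": int(rng.random() < p_assoc),
            "objects_room": int(rng.random() < p_room),
        })
    return rows


# ---------------------------------------------------------------------------
# tract measures
# ---------------------------------------------------------------------------


def simulate_tract_measures(profiles: Sequence[SubjectProfile],
                            config: CohortConfig,
                            rng: np.random.Generator,
                            trait: Optional[dict[str, float]] = None
                            ) -> pd.DataFrame:
    """Per-subject FA/MD table with a known linear link to a latent trait.

    ``fa = baseline + slope * trait + hemisphere offset + covariate terms
    + noise`` (clipped to [0, 1]); MD analogous with zero slope by default.
    The linked trait defaults to each subject's latent ability; ``trait``
    substitutes any other subject-level quantity (e.g. a realized behavioral
    summary) as the slope's carrier.  Reconstruction failures are injected
    by dropping all rows of a tract for a configured number of subjects.
    """
    rows = []
    missing: dict[str, set[str]] = {}
    for tract, n_miss in config.missing_counts.items():
        k = min(int(n_miss), len(profiles))
        idx = rng.choice(len(profiles), size=k, replace=False)
        missing[tract] = {profiles[int(i)].subject_id for i in idx}

    for prof in profiles:
        link = (trait[prof.subject_id] if trait is not None
                else prof.ability)
        for tract, bilateral, fa_base, md_base in config.tracts:
            if prof.subject_id in missing.get(tract, ()):
                continue
            hemis = ("left", "right") if bilateral else ("none",)
            for hemi in hemis:
                dropout = max(0.0, rng.normal(1.0, 0.3))
                pvf = float(np.clip(rng.normal(0.7, 0.08), 0.3, 0.95))
                hemi_ind = 1.0 if hemi == "right" else 0.0
                fa = (fa_base
                      + config.fa_slope.get(tract, 0.0) * link
                      + config.hemisphere_offset_fa * hemi_ind
                      + config.gamma_dropout_fa * (dropout - 1.0)
                      + config.gamma_pvf_fa * (pvf - 0.7)
                      + rng.normal(0.0, config.fa_noise_sd))
                md = (md_base
                      + config.md_slope.get(tract, 0.0) * link
                      + config.hemisphere_offset_md * hemi_ind
                      + config.gamma_dropout_md * (dropout - 1.0)
                      + config.gamma_pvf_md * (pvf - 0.7)
                      + rng.normal(0.0, config.md_noise_sd))
                base = {
                    "subject_id": prof.subject_id,
                    "tract": tract,
                    "hemisphere": hemi,
                    "dropout": dropout,
                    "pvf": pvf,
                    "age": prof.age,
                    "in_scanner": int(prof.in_scanner),
                }
                rows.append({**base, "measure": "FA",
                             "value": float(np.clip(fa, 0.0, 1.0))})
                rows.append({**base, "measure": "MD", "value": float(md)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# whole cohort
# ---------------------------------------------------------------------------


def make_profiles(config: CohortConfig) -> list[SubjectProfile]:
    rng = substream(config.seed, "profiles")
    a, b = config.ability_beta
    lo, hi = config.age_range
    profiles = []
    for i in range(config.n_subjects):
        profiles.append(SubjectProfile(
            subject_id=f"S{i + 1:03d}",
            ability=float(rng.beta(a, b)),
            jitter_sigma_max=config.jitter_sigma_max,
            theta_sd_max=config.theta_sd_max,
            log_scale_sd_max=config.log_scale_sd_max,
            translation_sd_max=config.translation_sd_max,
            swap_prob_max=config.swap_prob_max,
            fail_prob_max=config.fail_prob_max,
            in_scanner=bool(rng.random() < config.in_scanner_prob),
            age=float(rng.integers(lo, hi + 1)),
        ))
    return profiles


def simulate_cohort(config: CohortConfig | None = None) -> CohortData:
    """End-to-end synthetic session: environments, schedules, responses,
    binary outcomes, tract measures, and the generating truth record."""
    config = config or CohortConfig()
    env_rng = substream(config.seed, "environments")
    environments = generate_session(config, env_rng)
    env_by_id = {e.env_id: e for e in environments}
    profiles = make_profiles(config)

    schedules: dict[str, list[str]] = {}
    resp_rows = []
    outcome_rows = []
    for prof in profiles:
        sched_rng = substream(config.seed, "schedule", prof.subject_id)
        schedule = make_schedule([e.env_id for e in environments], config, sched_rng)
        schedules[prof.subject_id] = schedule
        resp_rng = substream(config.seed, "responses", prof.subject_id)
        for t, env_id in enumerate(schedule):
            pattern = simulate_response(env_by_id[env_id], prof, resp_rng)
            for lab, (x, y) in zip(pattern.labels, pattern.points):
                resp_rows.append({
                    "subject_id": prof.subject_id,
                    "trial_id": f"t{t + 1:02d}",
                    "env_id": env_id,
                    "object_label": lab,
                    "x": float(x),
                    "y": float(y),
                })
        out_rng = substream(config.seed, "outcomes", prof.subject_id)
        outcome_rows.extend(simulate_outcomes(prof, schedule, config, out_rng))

    tract_rng = substream(config.seed, "tracts")
    tracts = simulate_tract_measures(profiles, config, tract_rng)

    truth_record = {
        "seed": config.seed,
        "abilities": {p.subject_id: p.ability for p in profiles},
        "fa_slope": dict(config.fa_slope),
        "md_slope": dict(config.md_slope),
        "n_subjects": config.n_subjects,
        "n_environments": config.n_environments,
        "n_blocks": config.n_blocks,
    }
    return CohortData(
        config=config,
        environments=environments,
        profiles=profiles,
        schedules=schedules,
        responses=pd.DataFrame(resp_rows),
        outcomes=pd.DataFrame(outcome_rows),
        tracts=tracts,
        truth_record=truth_record,
    )
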