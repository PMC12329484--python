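# Methods

`allomem` scores how well a person reproduced the spatial layout of objects
in a small environment and relates that ability to white-matter
microstructure. This note documents the models, the estimation choices, and
what the synthetic data do and do not emulate.

## The scoring model

A trial consists of a *true* layout `Q = {q_1..q_n}` (labeled 2D points in
virtual meters) and a *recalled* layout `P = {p_1..p_n}` produced by
drag-and-drop on a 2D overview of the room. Three measures decompose recall
quality:

**Pattern accuracy.** The recalled layout is brought into register with the
truth by a similarity transform `T_{θ,s,t}(p) = s R(θ) p + t` — translation
(centroids matched), proper rotation (Kabsch closed form on the 2×2
cross-covariance), and bounded scale (least-squares factor, clipped to
`[1/3, 3]`). Because the measure is defined irrespective of object identity,
the point correspondence is itself unknown; the package solves

```
min over bijections π, transforms T  of  Σ_i ‖T(p_i) − q_π(i)‖²
```

by alternating the closed-form transform solve with a minimal-cost
assignment (Hungarian algorithm) — exact coordinate descent on that
objective — from multiple starts: the label-matched correspondence plus the
optimal assignments at 24 evenly spaced seed rotations, with the identity
transform always kept as a candidate. For n ≤ 6 the result provably equals
the exhaustive minimum over all n! correspondences on every seeded instance
tested (the brute-force solver ships as `exhaustive_align`). After
alignment, the residual is the nearest-position error

```
SSE = Σ_i min_j ‖T(p_i) − q_j‖²    (not necessarily bijective)
```

and `pattern accuracy = 1 / (1 + SSE)`, a bounded, strictly decreasing
transform that equals 1 exactly at perfect recall. On rare degenerate
responses the best bijective alignment can leave a larger nearest-position
error than no alignment at all; scoring then falls back to the identity
transform, which guarantees pattern accuracy ≥ untransformed accuracy on
every input.

**Environmental geometry** = untransformed accuracy − pattern accuracy
∈ [−1, 0]: how little translation/rotation/scaling the response needed,
i.e. how well the pattern was anchored to the room's perimeter. Zero means
the identity transform was already optimal.

**Object identity** = the number of response points whose label matches the
label of their assigned true position under the winning correspondence,
in {0..n}.

The scale bound `[1/3, 3]` prevents the optimizer from collapsing a
response onto a single true position under the nearest-position residual;
reflections are excluded because responses live in the same 2D plane as the
overview. Ties between equally scoring transforms break toward the smaller
|θ|, then the smaller |log s|, so results are deterministic.

## Chance level and failed trials

A trial with accuracy at or below chance carries no evidence of allocentric
encoding; keeping it would add noise downstream. Chance is estimated
empirically: genuine scores (responses against their own environment's
truth) are compared with null scores (the same responses scored against
each of 120 foil environments' layouts, the correct one excluded). An ROC
curve over the pooled scores — thresholds at midpoints between adjacent
distinct values with ±∞ sentinels, sensitivity strictly above, specificity
at-or-below — yields the cutoff maximizing sensitivity + specificity
(Youden; closest-to-top-left available via config), with the balanced error
reported alongside. Classification is "failed iff score ≤ cutoff"; the
boundary counts as failed. Failed trials keep their pattern accuracy but
their environmental-geometry and object-identity entries are blanked. The
cutoff is estimated once per cohort from a configurable sub-group of
subjects; per-subject thresholds are not supported.

## The synthetic cohort

The generator emulates the learning paradigm: 83 participants, 15
environments presented over 7 runs × 5 blocks (each environment at least
once, repeats spread evenly, order randomized per subject), rooms drawn
from 10 perimeter families (square, rectangle, triangle, trapezoid,
pentagon, hexagon, octagon, L, T, cross) scaled exactly to a uniform area
in [50, 90] virtual m², five uniquely labeled objects placed by rejection
sampling with a 0.5 m wall margin and 1.0 m pairwise separation.

A single latent ability `a ∈ [0, 1]` (Beta(2.5, 1.5) across subjects)
drives every behavioral error channel, each scaled by `(1 − a)`:

| channel | ceiling (at a = 0) | default | rationale |
|---|---|---|---|
| whole-pattern rotation | sd, rad | 0.4 | mis-anchoring to the room |
| whole-pattern log-scale | sd | 0.2 | compressed/expanded mental maps |
| whole-pattern translation | sd, m | 1.2 | placement offset in an ~8 m room |
| per-object jitter | sd, m | 1.0 | drag-and-drop imprecision |
| label transposition | prob./object | 0.3 | pattern without identity |
| outright failure | prob./trial | 0.3 | uniform placement in the room |

Binary non-allocentric outcomes (objects-association, objects-room) are
Bernoulli with success probability logistic in ability. Tract measures are
generated at the table level: per subject × tract × hemisphere,
`FA = baseline + slope·trait + hemisphere offset + γ·covariates + N(0, 0.02)`,
clipped to [0, 1]; MD analogous with zero slope by default. The default
configuration injects slope 0.10 for ILF, MdLF, and fornix with all other
tracts null, and drops all rows of a tract for a configured number of
subjects (fornix 4, corticospinal 2, anterior commissure 4) to mirror
tractography reconstruction failures. The `trait` carrying the slope
defaults to latent ability and can be overridden with any subject-level
quantity (the recovery experiments link FA to realized mean pattern
accuracy). Randomness is hierarchical: one master seed fans out into named
substreams per stage and subject; no global state.

What the generator does *not* emulate: boundary effects (responses may fall
outside the room), learning across repeated exposures, trial-order or
fatigue effects, object-specific memorability, realistic spatial
autocorrelation of tract measures, or any image-level properties. Passing
tests therefore demonstrate that the estimators recover what this noise
model encodes, not that they would behave identically on human data.

## Association models

Per-trial scores are aggregated per subject over non-failed trials.
Each tract × measure (FA, MD) is modeled separately as

```
value ~ 1 + selected fixed effects + (1 | subject)
```

fit by maximum likelihood (not REML, so fixed-effect structures are
AIC-comparable). The estimator profiles the likelihood exactly: for the
single random-intercept structure, β and σ² have closed GLS forms given the
variance ratio λ = τ²/σ², leaving a 1-D bounded search over log λ with the
λ = 0 (OLS) boundary always evaluated. Estimates, log-likelihoods and
standard errors agree with statsmodels' MixedLM to numerical precision on
cross-check fixtures; with one observation per subject the fit reduces to
OLS.

Candidate fixed effects are the five behavioral measures (z-scored across
subjects by default so coefficients are comparable across tracts),
hemisphere (bilateral tracts only), dropout score, partial-volume fraction,
age, and the in-scanner flag. Selection is greedy forward AIC: each round
adds the candidate with the largest AIC decrease, stopping when none
decreases it; AIC = 2k − 2·loglik with k counting fixed effects plus the
two variance parameters. t statistics use a residual df approximation
(n_obs − n_fixed); this is anti-conservative for subject-level predictors
with a large intra-class correlation, which is why the acceptance checks
rely on empirical nulls rather than nominal p calibration. VIFs (1/(1−R²)
of each selected term on the others) flag collinearity; exact collinearity
reports as infinite. Significance across all models is corrected by
Benjamini–Hochberg over the selected terms' p-values with the denominator
set to the total number of candidate explanatory variables across all
models. Missing tract rows are deleted listwise; singular or non-converged
fits are flagged in the output, never raised.

A known behavior worth stating: the five behavioral summaries are all
driven by one latent ability and correlate 0.7–0.85 at the subject level.
Post-selection inference on such collinear candidates occasionally promotes
a chance association on a null tract past the pooled correction (suppressor
configurations); the acceptance script reports the frequency of such
control-tract flags alongside the detection rate rather than hiding it.

## Problem sizes and numerics

- Alignment: 24 rotation-grid starts (deduplicated), ≤ 50 alternation
  rounds, tie tolerance 1e−9 relative; degenerate (all-coincident) source
  patterns raise a geometry error.
- Acceptance measurements: invariance 500 instances; oracle equivalence
  200 per n ∈ {4, 5, 6}; closed-form agreement 100 instances each; noise
  monotonicity 500 trials per jitter level; chance evaluation 160 + 160
  held-out scores with a 40-response × 60-foil null; recovery 40 end-to-end
  n = 83 replicates; null false-positive rate 80 replicates on a 6-tract
  panel. The test suite runs the same measurements at smaller sizes.
- The chance cutoff for Monte-Carlo work is calibrated once per run from a
  dedicated cohort and reused across replicates — it depends on the
  paradigm's geometry and noise model, not on the tract model under test.
- All tables are tab-separated UTF-8 text with "NA" for missing values and
  `%.10g` floats, which makes end-to-end runs byte-reproducible from the
  master seed.

## Limitations

- The scoring optimum is verified exhaustively only for n ≤ 6 (the
  paradigm uses n = 5); larger layouts rely on the multi-start heuristic.
- The chance threshold assumes the foil library is representative of
  unrelated layouts; with very few foils the cutoff is noisy.
- Mixed-model p-values use a residual df approximation; Satterthwaite or
  Kenward–Roger corrections are out of scope.
- MD is simulated but carries no behavioral link by default, so MD models
  act purely as additional nulls.
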