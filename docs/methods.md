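# Methods

## Model overview

`levyrisk` simulates a tri-trophic random-search system: one searcher, a
field of point targets grouped in patches, and `N_p` predators, all on the
flat torus `[0, L)²` with `L = 500`. The searcher moves at constant speed
`v_s = 1` in straight bouts separated by turns; it captures any active target
it passes within the target encounter radius (1), and dies the first time it
comes within the predator encounter radius (1) of a predator. A lifetime ends
at death or at the maximum search time `T_max = 10⁴`. Batches of independent
lifetimes are accumulated until a total searcher-alive time budget is reached,
and encounter rates are estimated as

* `eta = total captures / total alive time`,
* `gamma = total deaths / total alive time`,
* `k = gamma · T_max` (expected fatal encounters per lifetime),
* `mean search time = total alive time / number of lifetimes`.

`gamma` is the maximum-likelihood hazard estimate for censored exponential
lifetimes; it is the per-unit-time encounter probability entering the fitness
formulas (unit time ΔT = 1, so `n = T_max`).

## Movement strategies

| kind | step law | turn law | parameters |
|---|---|---|---|
| `levy` | `l = l0 · u^{1/(1-μ)}`, `u ∈ (0,1]` | uniform on [-π, π] | `1 < μ ≤ 3`, `l0 = 1` |
| `brownian` | Normal(1, 1) truncated at 0 | uniform | `l0 = 1` |
| `crw` | constant `l0` | wrapped Cauchy, concentration ρ | `ρ ∈ [0, 1]` |
| `cbw` | Brownian at scale `l0` or `10·l0` | uniform | giving-up length |
| `ballistic` | effectively infinite | never turns | — |
| `stationary` | — | — | velocity 0 |

Design choices where the construction was genuinely open:

* **Brownian positivity.** Normal(1, 1) has ≈16% negative mass; we resample
  until positive. This preserves "step length" semantics; taking absolute
  values instead would pile extra mass near zero. The truncated law has mean
  ≈1.2876 and variance ≈0.6304, which the test suite checks against numerical
  integration of the truncated density.
* **Lévy tail is untruncated.** A step longer than `L` simply wraps the torus;
  the inverse-transform law is used exactly as written.
* **CRW** isolates directional persistence: constant step `l0` with
  wrapped-Cauchy turns whose mean resultant length is the shape parameter ρ
  (ρ = 0 uniform turning, ρ → 1 straight-line).
* **CBW** is the standard two-mode composite walk: the intensive mode (scale
  `l0`) is entered on every capture; after travelling the giving-up length
  without a capture the walker switches to the extensive mode (scale `10·l0`).
  These two parameterizations are this package's constructions for the
  general CRW/CBW families; results for them should be read as family-level,
  not as matching any one external calibration.
* **`ballistic`** exists so the ideal-gas formulas (straight-line movers) can
  be tested against the engine directly.

## Landscape

50 patch centres i.i.d. uniform (overlap allowed), 1000 targets assigned to
uniformly random patches (20 per patch on average) and placed uniformly in
the patch disk of radius 10. Captured targets are inactive until the
searcher's path-length odometer crosses the next multiple of 500, when *all*
depleted targets regenerate at freshly drawn uniform positions within their
original patches — density and patch structure are both maintained, and
re-drawing positions prevents deterministic re-harvesting of a remembered
point. Searcher legs are split at each odometer multiple, so a single long
step crossing several multiples triggers each regeneration in order, and
regenerated targets are detectable from the crossing point onward.

## Encounter detection

* **Moving point vs static disk** (targets, sit-and-wait predators): exact
  segment–circle intersection under the minimum-image convention, with
  segments internally split into pieces of at most `L/4` so the nearest
  periodic image is unambiguous (requires disk radius < `L/4`). Long ballistic
  steps therefore cannot tunnel through a detection disk.
* **Two moving agents**: synchronized sub-steps with combined displacement at
  most `substep_fraction` (default 0.2) of the encounter radius per distance
  check. Halving the fraction must not move the measured rates beyond
  Monte-Carlo error; the suite includes this convergence check. When death
  and capture fall in the same sub-step, death wins (predation dominates
  ties).
* **Stationary searcher** is special-cased: predators are mutually
  independent, so each predator's path is intersected exactly with the
  searcher's disk and the earliest hit taken — this branch is exact and fast,
  and is what the ideal-gas cross-check (`2ρR v_p` within Monte-Carlo error)
  exercises.

Predator steps are never truncated by encounters and predators ignore the
searcher (pure random movers, no pursuit). Capture truncates the searcher's
step at the capture point and re-draws both a fresh step length and a uniform
direction.

## Episode protocol and seeding

Each episode re-draws the landscape, the predator layout (uniform i.i.d.
positions; optionally held fixed across episodes via
`re_randomize_predators=False`) and the searcher start (uniform, rejection-
sampled so no predator is within the predator encounter radius; an
alternative mode forces the nearest-predator distance exactly, for the
initial-distance experiment). Episode randomness is derived from the batch
seed by `SeedSequence`: the environment/placement streams depend only on
(seed, episode), the movement stream also on the searcher-strategy kind.
Two strategies compared under one seed therefore see identical landscapes
episode by episode — common random numbers, which cancels most layout noise
from ratio estimates — while their movement draws stay independent. Every
batch is bit-reproducible from its seed.

## Fitness layer

With constant per-unit-time hazard γ the first predator encounter is
geometric; the exact mean search time `(1-(1-γ)ⁿ)/γ` (limit `n` as γ → 0)
equals the explicit sum (checked to 1e-12 against Kahan-compensated brute
force), and the exponential approximation `n(1-e^-k)/k` is accurate to
relative order γ. `(1-e^-k)/k` switches to the series `1 - k/2` below
`k = 1e-8` to avoid cancellation. Relative fitness:
type I `(η_A/η_B)·[(1-e^-k_A)/k_A]/[(1-e^-k_B)/k_B]`, type II
`(η_A/η_B)·e^-(k_A-k_B)`; both are independent of `T_max` in the sense that
the lifetime length `n` cancels exactly between the absolute fitnesses.
Note the plug-in estimator treats η and survival as independent; within an
episode they are weakly correlated (a searcher that dies early in a barren
corner contributes to both), so simulation-based φ ratios can deviate
slightly from episode-averaged fitness. The experiments module reports the
plug-in ratios, and the raw per-episode arrays are kept on every
`EncounterStats` so either view can be computed.

## Problem sizes and uncertainty

Reference experiments in this package default to totals of 10⁵–2×10⁶ time
units per batch, chosen so that rate ratios carry a few percent to ~15%
Monte-Carlo error — enough to resolve the directional results (relative
fitness crossing 1, γ-ratio trends in μ, density invariance) with hundreds
of deaths per batch. The acceptance script uses 2×10⁶ per strategy for the
zero-predator fitness ratio. Confidence intervals are episode-level
percentile bootstraps (default 1000 resamples), resampling focal and
baseline batches independently; resamples with a zero denominator rate are
dropped as uninformative.

## What the simulations do and do not show

The generator *is* the study system: an abstract arena with memoryless
searchers, point targets and non-pursuing predators. Passing tests show the
encounter mechanics, the rate estimators and the fitness algebra are
mutually consistent and agree with the closed-form ideal-gas and geometric-
law oracles. They do not speak to real foragers' cognition (memory,
gradient-following, predator cues), pursuit–evasion dynamics, survival
probability below 1 per encounter, population feedbacks, or 3-D movement —
all outside this model. The relative-motion symmetry between "searcher" and
"predator" labels holds only for non-foraging movers: captures truncate and
re-orient the searcher's steps, which measurably lowers a Lévy searcher's
predator-encounter rate relative to a non-foraging Lévy predator.

## Numerical notes

* Coordinates are float64 on `[0, L)`; wrapping guards against landing
  exactly on `L`.
* Odometer and age accumulate additively over legs; regeneration marks are
  compared with a 1e-9 slack so a leg truncated exactly at a mark fires its
  regeneration once.
* The target scan prefilters by patch disk (radius `patch_radius + R_t`),
  which is exact because every target lies within its patch; with 50 patches
  this cuts the per-leg cost by roughly the patch count over target count.
* Kernel seeds are 31-bit; numba's per-thread RNG is seeded once per episode.
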