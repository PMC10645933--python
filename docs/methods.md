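# Methods

This note documents the models, defaults, and design decisions behind
`pbmstudy`, and what the synthetic-data tests do and do not establish
about real data.

## Behavioral trajectory model

Simulated trials are discrete-time correlated random walks driven by
bouts. At each bout onset a target is drawn from the programmed
preference; each frame the heading is re-aimed at the target and
perturbed with Gaussian angular noise (s.d. `heading_noise`, default
0.15 rad), and the body-center advances by `speed_mean / frame_rate_hz`
(default 10 cm/s, 30 Hz). Keypoints are rigid: head-center 1.5 cm and
nose 2.5 cm ahead of the body-center along the heading, so
‖nose − head‖ is constant by construction. This is deliberately the
simplest motion model whose preference parameters are identifiable from
the downstream metrics; it makes no claim to biomechanical realism.

* **NORT** (40 cm square arena, objects at (±10, 0) cm): roam bouts to
  random waypoints alternate with object bouts; an object bout targets
  the novel object with probability `novelty_preference`, stops the body
  5 cm from the object center (nose at 2.5 cm), and dwells 2.5 s facing
  it. Roam waypoints are drawn so the straight path stays > 7 cm from
  both objects: incidental zone crossings would add symmetric
  exploration time and shrink the measured discrimination index toward
  zero. With per-visit times identically distributed for both objects,
  the expected DI equals 2p − 1, which the recovery tests verify at
  p ∈ {0.5, 0.6, 0.75, 0.9} over 200 trials each.
* **Y-maze** (three 35 × 5 cm arms at 120°): the walker moves arm-end →
  center → next-arm-end, choosing the least-recently-visited of the two
  other arms with probability `alternation_bias` (1.0 forces perfect
  alternation; 0.5 is uniform between the two candidates, which is the
  memoryless walk *without* immediate revisits — distinct from the
  iid-uniform sequences used for the 2/9 chance-level reference, which
  allow them). The visit order is recorded as the latent arm sequence,
  so entry detection can be validated exactly: visits reach 80% arm
  depth while detection requires 50%, and transit between arms passes
  only through the center, so detected and latent sequences must agree
  (the final entry may be mid-walk when the trial ends).
* **MWM**: heading is a `goal_bias`-weighted mix of the platform
  direction and the current heading plus noise; the walker parks on
  reaching the platform (training) or re-draws a target each bout —
  platform vicinity with probability `goal_bias`, else a uniform pool
  point (probe). The pool wall reflects.

## Synthetic sections

Images are generated at 0.6 μm/pixel (the acquisition scale after 2×
down-sampling). Plaques are non-overlapping disks with radii uniform in
8–15 μm, placed by rejection sampling with a configurable minimum
edge-to-edge separation (default 5 μm; tests that require disjoint
plaque neighbourhoods use 95 μm so no plaque's plateau reaches another's
far annulus). The microglia channel is
`baseline × m(d)` where `d` is distance from the nearest plaque edge and
`m` is a plateau of height `enrichment_factor` out to
`enrichment_decay_um` (default 12 μm) followed by a linear falloff to 1
over `falloff_um` (default 4 μm). With these defaults the plateau
exactly covers the near annulus and the far annulus (18–60 μm) sits on
baseline, so the measured ratio equals the programmed factor. Noise is
additive Gaussian clipped at zero, with optional Poisson resampling.
Nuclei are small disks exported both as an intensity channel and as an
instance label mask.

What the generator does **not** emulate: irregular plaque morphology,
cell-shaped (rather than field-like) Iba-1 texture, staining gradients,
tiling artifacts, or annotation error. Passing tests therefore establish
that the *measurement chain* is correct and calibrated, not that
segmentation would succeed on real stains — the study's trained pixel
classifier and nucleus network are explicitly out of scope, and the
global-threshold segmenter here is a declared stand-in (Otsu threshold
within the included region, minimum component area 20 μm², both
config-exposed).

## Measurement conventions

* Coordinates in cm, origin at arena center, y-up; pixel→cm calibration
  belongs to the arena spec. Region polygons are in pixel coordinates,
  y-down, 0-based.
* Facing cone for object exploration: 45° half-angle default. The
  original criterion states only "facing the object"; the cone width is
  a package decision and is exposed for sensitivity analysis.
* Arm entry: body-center beyond 50% of arm length, no minimum dwell,
  consecutive duplicates collapsed — also a package decision, exposed.
* Gap handling: keypoints with likelihood < 0.6 are linearly
  interpolated when the dropout lasts ≤ 0.5 s; longer gaps are excluded
  from every time-based denominator. Speed and path length are computed
  from gap-filled frames with no additional smoothing; post-escape
  frames are excluded from the speed denominator.
* MWM quadrants are the four 90° sectors around the cardinal axes
  (N spans 45°–135°, etc.), with the platform mid-radius in the target
  quadrant.
* Plaque "radius" for irregular components is the equal-area circle
  radius √(area/π). Annulus distances are Euclidean distances to the
  nearest plaque *pixel* (scipy EDT), measured from the mask edge rather
  than the centroid; the brute-force oracle in the tests enumerates the
  same per-pixel distances independently.
* Annulus exclusions: pixels inside any plaque, outside the included
  region, or in an exclusion polygon never contribute. Pixels shared by
  two plaques' neighbourhoods contribute to both by default; `strict`
  mode drops contested pixels. Plaques with an empty near or far annulus
  (region border) are dropped from ratio statistics and logged. The
  region summary reports both mean and median of per-plaque ratios
  (mean is the headline aggregate).
* A known ambiguity: the source describes the microglial response once
  as an intensity ratio and once as a labelled-surface comparison; the
  intensity-ratio definition is implemented.

## Statistical procedure

The Lilliefors statistic is the KS distance between the sample ECDF and
a normal with estimated mean/s.d.; its p-value comes from a seeded
Monte-Carlo null (default 10,000 replicates, parameters re-estimated per
replicate, add-one rule so p > 0 always). This matches the independent
statsmodels implementation of the statistic to machine precision; the
Monte-Carlo p avoids table interpolation and adapts exactly to n.
Decisions taken where the procedure is under-specified: the gate runs
per group (not pooled) at the same α = 0.05 as inference; groups too
small for the gate (n < 4) or with zero variance pass through un-gated;
the non-normal multi-group branch falls back to Kruskal–Wallis and is
flagged in the report. The signed-rank branch uses the exact null for
n ≤ 25 and the normal approximation above. Mixed two-factor ANOVA with
Greenhouse–Geisser correction is delegated to pingouin; this package
owns the design validation, the choice to report GG-corrected
(fractional) degrees of freedom for within-subject effects, and the
report schema. Dunnett post-hocs use scipy; Šídák adjustment is
1 − (1 − p)^m over the family.

Null calibration is verified by simulation: Lilliefors and the gated
ANOVA hold a type-I error within binomial tolerance of 5% over 2,000
null replicates, and the within-effect p of the mixed ANOVA is uniform
under the null.

## Study-design utilities

Randomization shuffles mice within each sex and deals them round-robin
to the groups in a random order, so per-sex group sizes differ by at
most one; explicit unequal group sizes (e.g. 19/20/21) are honoured
while keeping sexes as balanced as the quotas allow. The codebook stores
the id→code map and the sealed code→group map in separate JSON files;
group lookups raise before `unblind()` and every unblinding is logged.
Dose arithmetic: average irradiance = peak × duty cycle (120 mW/cm² for
the 600 mW/cm² arm at 20% duty); per-session fluence = average ×
session seconds / 1000 (14.4 J/cm² at 120 s); cumulative = per-session ×
sessions/week × weeks. Fur transmission is the paired unshaved/shaved
power ratio in percent; attenuation is its complement.

## Problem sizes and numerical choices

Simulation-based tests use trial durations of 40–120 s at 15 Hz,
200-trial recovery sweeps, 2,000-replicate null calibrations, and
512-pixel sections with 5 plaques — sizes chosen so the whole suite runs
in well under a minute of simulation per property while keeping
Monte-Carlo standard errors a few times tighter than the asserted
tolerances. All randomness flows through `numpy.random.default_rng`
seeds carried in the parameter objects; sub-seeds for multi-part runs
derive from `SeedSequence` so components are independent and
reproducible. Degenerate inputs have defined behaviour throughout: zero
exploration time, fewer than three arm entries, and zero-variance
samples raise typed errors (trials excluded from group statistics);
all-zero paired differences report p = 1; empty regions yield empty
tables with a log entry.

## Known limitations

The trajectory model has no thigmotaxis, immobility/floating, or speed
variability structure; the discrimination-index recovery bound (±0.05)
reflects residual truncation effects at trial end. The histology
generator's field-like microglia channel cannot probe cell-level
segmentation choices. Two-way repeated-measures machinery is inherited
from pingouin, including its sphericity estimation; only its decision
wiring is tested here. The blinding utilities enforce process discipline
within this package's file formats and make no claim of GLP-grade
document control.
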