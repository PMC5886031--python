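# Methods

## Stimulus model

An RDK interval is a sequence of `n_updates` dot fields inside a circular
aperture. Defaults describe the reference stimulus: 226 dots of 0.1° diameter
(2 dots/deg²) in a 12°-diameter aperture, 10 positional updates at 18.75 Hz.
The implied duration is `n_updates / update_rate` = 533.3 ms; quoted 530 ms
figures for such stimuli are treated as rounded reports, not constraints.
Dot positions are continuous degrees of visual angle; pixel quantization
(1.35 arc min/pixel at the default rasterization resolution) happens only in
`rasterize`. Dots may overlap — no exclusion rule is imposed.

On every update each dot independently redraws its speed (speed experiments)
or direction (direction experiment) from the governing discrete distribution;
displacement per update is `speed / update_rate`. A dot whose proposed
position leaves the aperture is point-reflected through the aperture center
and placed on the rim — the most literal reading of re-entry "on the opposite
side", and direction-agnostic. An alternative (re-entry along the motion
chord, preserving residual displacement) would change nothing measured here,
since no statistic in the package depends on positions of wrapped dots; the
reflection rule is the only one implemented.

## Distribution constructions

All supports are finite grids. Two conventions do the heavy lifting:

1. **Outer-endpoint anchoring.** Band grids are anchored at the declared
   outer range endpoints and extend inward in `interval` steps. This keeps
   the printed endpoints exact and makes symmetric notches mean-preserving.
   For a range that is not a whole number of grid steps (the 23.2 deg/s span
   at 1 deg/s sampling), the *standard* is likewise gridded from both
   endpoints toward the midpoint: 24 support points, a slightly larger
   central step (1.2 deg/s), endpoints and mean (12 deg/s) exact. A one-sided
   grid cannot satisfy all three printed constraints at once. A consequence
   worth knowing: the 1 deg/s-notch comparison removes no grid point and is
   identical to this standard, so that condition is undiscriminable in
   principle — consistent with near-chance empirical performance at the
   narrowest notch.
2. **Closed bands, open notch.** A grid point exactly on a notch edge belongs
   to the band; only points strictly inside the notch are excluded. A
   zero-width notch therefore reproduces the standard exactly.

Where a band's mean must be steered away from its unweighted value (the
mean-distance and constant-distance families), per-point weights take the
maximum-entropy exponential-tilting form `w_i ∝ exp(λ x_i)`, each band
carrying probability mass 1/2. The tilt is the unique minimally informative
reweighting satisfying the mean constraint and degrades exactly to uniform at
λ = 0. λ is solved with a bracketing root finder (Brent's method after
doubling bracket expansion from |λ| = 1, xtol 1e-12); support values are
centered before exponentiation for numerical conditioning. Constraint
satisfaction is verified to 1e-9 in deg/s (1e-6 is the documented contract).

Open parameters fixed once:

- The grid interval of the mean-distance family is 0.2 deg/s (the finest of
  the plausible sampling intervals, feasible for every target distance).
- The constant distance between band means in the slow/fast families is
  6.0 deg/s — feasible for all four notch widths (1.2–5.2 deg/s) on both the
  slow ([1.2, 8] deg/s) and fast ([17.2, 24] deg/s) ranges.
- Direction arithmetic is linear, not circular: supports span at most 58°
  about the mean, far from wrap-around; an optional trial-level global
  rotation is applied modulo 360 afterwards and defaults to none.

`validate_matched` asserts equal span, equal outer endpoints, and equal
global means (tolerance 1e-6) for every standard/comparison pair; every
catalogued condition passes, which is what licenses calling the oddity task
criterion-free.

## Task and observers

Oddity trials place the comparison uniformly at one of three positions; the
two standards are independent samples. Speed trials share one direction drawn
uniformly from [0°, 360°); direction trials share one fixed speed. Sessions
interleave conditions by default (blocked order is available; which was used
historically is not recorded anywhere authoritative). Observers receive only
interval dot data — never the odd position or provenance — and no feedback;
responses outside the response set are logged as protocol violations,
excluded from proportions, and counted. The displacement-limit task presents
a single interval with every dot displaced identically left or right;
default levels are 27–162 arc min in six equal steps (only the endpoints of
the tested range are documented; the step count is a package choice).

The simulated observers are modeling devices of this package — the original
method used human participants, and no observer here claims to reproduce
human percepts. The decision statistic is the **largest empty gap** between
sorted unique perceived values in an interval, chosen over bimodality
coefficients or mixture fits because it targets the manipulated construct (the
notch) directly and has a trivial brute-force oracle; the decision rule picks
the interval whose statistic is most distant from the other two (ties
uniform). Perceptual limits enter as noise before the gap is measured:

- `SpeedGapObserver(noise_fraction=0.10)`: perceived speed = true speed ×
  (1 + ε), ε ~ N(0, noise_fraction) — multiplicative, Weber-like. Absolute
  uncertainty grows with speed, so the same observer discriminates notches on
  the slow range and collapses to chance on the fast range, mirroring the
  slow-speed dominance of transparency perception. The default 0.10 was
  chosen once, during observer design, to give a graded (neither saturated
  nor floor-bound) psychometric curve over the 1–19 deg/s notch family.
- `DirectionGapObserver(noise_deg=2.0, speed_gain=0.35)`: additive direction
  jitter with s.d. `noise_deg + speed_gain·speed`, so directional gaps are
  detectable at 4 deg/s, marginal at 13 deg/s, and lost at 22 deg/s.
- `DmaxObserver(limit=100, slope=12 arc min)`: answers correctly with
  probability `1/2 + 1/2·σ((limit − d)/slope)` — exactly 0.75 at the limit —
  providing ground truth for threshold-recovery tests.

All observers are stateless across trials (no feedback, nothing to learn).

## Psychometrics

`summarize` uses exact integer counts; the error column is the binomial
standard error for a single observer and ±1 SEM across per-observer
proportions when several observers contributed. `fit_psychometric` maximizes
the binomial likelihood of a Weibull (`γ + (1−γ−λ)(1−exp(−(x/α)^β))`) or
logistic curve with γ fixed by the task, lapse λ free in [0, 0.06], and the
curve's direction inferred from the data when not specified (displacement-
limit curves decline). Optimization is deterministic: a fixed grid of
starting points refined with L-BFGS-B. The threshold is the analytic
inversion of the fitted curve at the criterion (default 0.75); when the
criterion is not bracketed by the fitted curve over the tested levels the
`extrapolated` flag is set, and flat-at-chance data yield a NaN threshold.
The model-free alternative `threshold_highest_passing` (largest level whose
raw proportion still meets the criterion) is provided as well; fits label
which method produced their threshold. `bootstrap_ci` resamples trial counts
within level (parametric binomial) and refits.

The raw proportion-correct curves of the oddity experiments are reported as
tables, not fits — the discrimination curves are the result, and no
functional family is imposed on them.

## Determinism and problem sizes

Every entry point threads a single `numpy` Generator; (configuration, seed)
determine all outputs bit-for-bit, and metadata sidecars carry seeds and a
config hash but no timestamps. Default simulated sizes — 280 trials per
condition in sessions, 2,000 trials per condition for monotonicity
properties, 10,000 trials for the chance-floor estimate, 280 trials per level
for displacement-limit recovery — are the package's reference study sizes,
chosen to make binomial error small relative to the effects being checked.

## What the synthetic pipeline does and does not show

Passing tests establish that the stimulus statistics hit their constraints
exactly, that the task is blind and counterbalanced, and that simple
gap-detection observers reproduce the qualitative result pattern (graded
improvement with notch width, slow/fast asymmetry, speed-modulated direction
performance). They do not establish anything about human vision: human
proportion-correct levels are properties of human observers and are out of
scope. Other known limitations: no gamma correction, photometry, or display
timing; no circular direction statistics; no hierarchical across-subject
modeling; dot overlap permitted.
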