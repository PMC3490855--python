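# Methods

This note documents the models, parameter choices and numerical decisions
behind `rdksim`, and what its simulations can and cannot say about real
psychophysical data.

## Stimulus model

Two random-dot patches overlap in a static circular aperture of 7.5°
diameter. Each patch holds `round(density × aperture area)` dots
(3.4 dots/deg² → 150 dots per patch), scattered uniformly over the disk and
translated at 5°/s at 100 Hz for 3 s. The component directions are
90° ± Δ/2 so the vector average is always straight up. Motion coherence *c*
selects exactly `round(c·N)` *signal* dots per patch at initialization;
signal assignments are fixed for the whole presentation (dot lifetime is
unlimited), which makes coherence conservation exact at every frame.

**Noise-dot dynamics.** Noise dots "move randomly in different directions";
with unlimited lifetime this is read as one independent uniform direction
per dot, fixed across frames (`noise_mode="fixed"`, the default). Per-frame
re-randomization (`noise_mode="walk"`) is available as a configuration
option. All dots move at the common speed regardless of signal status.

**Wrap-around.** A dot that steps onto or past the aperture boundary
re-enters at the diametrically opposite boundary point with its direction
unchanged. The overshoot fraction of that step (≤ 0.05°) is discarded; a
chord-reflection alternative was considered and not implemented.

**Rasterization** (dot positions computed sub-pixel, rounded to the nearest
pixel, painted as 2×2-pixel squares) is provided for completeness but sits
off the analysis path: the synthetic observers consume directions and
geometry, not pixels. Display luminances are metadata only and are never
modelled.

## Parametric observer

The observer maps a condition (Δ, c) to a mean internal separation

    perceived(Δ, c) = max(0, Δ · (1 + b(c) · R(Δ)))

* `b(c)` is piecewise linear: `g₊ · (c − c₀)/(1 − c₀)` above the crossover
  coherence `c₀ = 0.8`, `−g₋ · (c₀ − c)` below it. Positive values produce
  repulsion, negative attraction, and `b(c₀) = 0` makes the percept
  veridical at the crossover for every Δ.
* `R(Δ)` is a two-Gaussian mixture in Δ, `0.55·N(25°, 5°) + 0.45·N(25°, 45°)`
  normalized to 1 at its 25° peak: a distinct local peak on a broad
  pedestal. On the attraction branch the profile is
  `(1 − ρ)·R(Δ) + ρ` with floor `ρ = 0.115`, so attraction keeps a
  low-level effect at 90–120° where repulsion has decayed to near zero.

**Calibration.** Three anchors fix the defaults analytically: perceived
separation ≈42° at (Δ=30°, c=1), ≈16° at (Δ=30°, c=0.6), and mirror
symmetry of the normalized repulsion and attraction profiles
(`g₊ = (1 − ρ) · |b(0.6)|`), which makes the coherence-pooled separation
effect vanish — the configuration in which a two-way repeated-measures
ANOVA shows a strong coherence × separation interaction but no separation
main effect. Solving gives `g₊ = 0.513`, `g₋ = 2.9`, `ρ = 0.115`. The
functional form of `b(c)` (linearity below the crossover) and of `R(Δ)` are
modelling choices; only the crossover coherence and the 25° peak location
are anchored qualitatively.

**Trial level.** Each trial adds Gaussian noise (σ = 3°, floored at 0) to
the mean percept; percepts below the merge threshold (4°) collapse to 0 —
the observer reports a single motion direction. Responses lapse to a random
choice with probability 0.02. The σ = 3° default yields staircases of
roughly 10–25 trials, overlapping the 15–30 range of practiced human
observers. The 2AFC rule is simply `line angle > percept` (optionally with
an additive line-angle bias, default 0, for sensitivity analyses of the
known 1–3° acute-angle expansion of line stimuli). Exact ties are a fair
coin, with one exception: a merged (zero) percept against a zero-angle line
reads as "lines wider", which is what pins a zero-percept staircase at the
floor instead of letting it reverse between 0° and 3°.

**Cohorts.** Subjects are i.i.d. draws around the defaults: one lognormal
gain factor (SD 0.15) scaling both `g₊` and `g₋`, crossover jitter
(SD 0.02) and trial-noise jitter (SD 0.5°). The 15% gain CV is the value
implied by a coherence main effect of F(1,3) ≈ 177 in a four-subject
within-subject design (F ≈ n/CV²). Synthetic subjects deliberately lack
idiosyncratic additive matching biases: such biases would be needed to
reproduce across-subject SDs of 4–8° in the perceived angle, but they
swamp the small (2–3°) genuine repulsion at 90–120° separations, which the
package's own acceptance property requires to remain resolvable at cohort
level. Simulated F ratios of the one-way ANOVAs are therefore larger than
those of comparable human data — the qualitative pattern, not the F
magnitude, is the reproduction target. An extreme observer (merging already
at 50% coherence) can be configured via a high merge threshold.

## Population-channel observer

A demonstrator of the underlying neural hypothesis, not the quantitative
pipeline. 72 direction channels receive von Mises-tuned excitation
(κ = 40) from the stimulus's pooled dot-direction histogram and are
suppressed by a broad inhibitory pool (von Mises kernel, κ = 6, strength
1.2), then rectified:

    A = max(0, E − s_eff · (K_inh ∗ E))

Motion noise shifts the segmentation/integration balance: with the
uniform-noise fraction *u* estimated from the histogram (median bin mass ×
number of bins) and `φ(u) = 1/(1 + 15·u)`, the tuning concentration becomes
`κ·φ` (broader pooling) and the inhibition strength `s·φ` (weaker mutual
inhibition). Decoding smooths the activity (circular Gaussian, SD 8°),
finds local maxima above 0.3 of the peak, and refines the two largest by
parabolic interpolation; a unimodal profile reads out as zero separation.

A purely linear subtractive bank cannot reproduce the coherence dependence —
a uniform noise pedestal shifts excitation and inhibition equally, leaving
peak positions invariant — so the noise-dependent φ factor is the essential
ingredient: it is the "noise prompts integration" hypothesis made
mechanistic. With the defaults the bank shows repulsion at full coherence
(decoded separation > Δ at Δ = 30° and 60°), attraction or a merged single
peak at 60% coherence, and near-veridical readout at Δ = 120°. The channel
count, kernels and thresholds were chosen by direct numerical exploration
against that qualitative pattern.

## Staircase engine

One staircase fixes (Δ, c) and adapts the line angle by 3° against the
response (1-up/1-down), starting uniformly within ±20° of Δ (clipped at 0).
A reversal is scored on the trial where the report switches; the recorded
reversal angle is the line angle of that trial (the turnaround extreme).
The alternative bookkeeping — the angle of the preceding trial — differs by
exactly one step and is available as a config flag. After seven reversals
the matching angle is the mean of the last four reversal angles. The
zero-floor rule is codified as five consecutive "lines wider" responses at
a 0° line angle (matching angle recorded as 0). A 200-trial safety cap
exists only for pathological observers; capped staircases are flagged and
never silently averaged. Monte-Carlo calibration: for internal separations
10–60° and trial noise 1–5°, the mean matching angle over 200 staircases is
within 0.3° of the true value (the 1-up/1-down procedure converges on the
50% point, and the mean-of-reversals estimator is unbiased there by
symmetry).

Inter-stimulus intervals, fixation and interval order are experiment
metadata with no computational effect on model observers, and are not
simulated.

## Experiment designs

Experiment 1: Δ ∈ {30°, 60°} × c ∈ {0.5, 0.6, 0.7, 0.8, 0.9, 1.0} (six
levels, fixing the one-way ANOVA error df at 18 with four subjects).
Experiment 2: c ∈ {0.6, 1.0} × Δ ∈ {15, 25, 30, 45, 60, 90, 105, 120}°
(eight levels → error df 24; the grid is a configuration entry — only the
15–120° range and the 25° peak region are pinned down, the intermediate
levels are an inference). Four subjects × four staircases per condition;
condition order is deterministic (order effects do not exist for model
observers). Every staircase derives its random stream from
(root seed, subject, condition, staircase), so any cell is reproducible in
isolation. A configurable number of practice staircases (default 0) can be
run and discarded per condition; model observers do not learn, so practice
only consumes extra random draws from separate streams.

## Statistics

* **Effect metrics**: difference = perceived − Δ; normalized = difference/Δ
  (positive repulsion, negative attraction). Zero-floor staircases enter the
  analysis as 0°.
* **One-way ANOVA**: between/within sums of squares, df (k−1, N−k), upper
  tail of the F distribution. Subject-level condition estimates (mean of
  four staircases) are the observations, as in the four-subject design.
* **Two-way repeated-measures ANOVA**: both factors within subject; each
  effect is tested against its own subject-interaction error term
  (A: (a−1, (a−1)(n−1)); B: (b−1, (b−1)(n−1));
  A×B: ((a−1)(b−1), (a−1)(b−1)(n−1))) — the standard error structure, which
  reproduces the design-implied df triplets (1,3)/(7,21)/(7,21). No
  sphericity correction by default; Greenhouse–Geisser adjustment is
  available as an option.
* **Wilcoxon signed-rank**: exact null distribution of the positive-rank
  sum for n ≤ 25 (convolution over ranks, ties handled by average ranks on
  a half-rank integer grid), normal approximation with tie and continuity
  corrections above; two-sided p. The result object reports which branch
  ran. The exact branch matches full 2ⁿ enumeration in the tests; the
  approximation tracks the exact p away from the deep tail (the n = 32
  attraction test lands near 10⁻⁶–10⁻⁷ on either branch).
* **Magnitude comparison**: attraction values are sign-inverted before the
  second repeated-measures ANOVA, so attraction and repulsion are compared
  without the sign difference.

Both ANOVA routines and the signed-rank test are validated against
brute-force sums-of-squares / enumeration oracles and against independent
library implementations (scipy, pingouin) in the test suite.

## What the simulations show — and what they do not

Passing tests establish that the *pipeline* is faithful: the staircase
recovers the observer's internal state without bias, the designs produce
the intended df structure, and the statistics agree with independent
oracles. The synthetic observers are calibrated to qualitative regularities
(crossover near 80% coherence, effect peak near 25°, mirrored normalized
profiles, low-level attraction at large separations); they do not model
reference repulsion around cardinal axes, luminance or contrast effects,
learning across the session, or eye movements, and no claim is made that
their trial-level noise structure matches human observers beyond the
trial-count range. Quantities that depend on between-subject variance
(F magnitudes, SEs) reflect the configured cohort heterogeneity, which is
deliberately more homogeneous than a real four-human cohort.

## Numerical conventions

Angles are degrees counter-clockwise, 90° = upward; separations are
non-negative and reported in degrees to one decimal, percent effects to the
nearest integer. Uniform disk sampling uses the square-root radius
transform. The direction histogram is a mass function (sums to 1) over
equal bins of [0°, 360°). Peak interpolation is parabolic in the smoothed
channel activity; an all-zero activity profile is an error, not a zero
separation. All simulations derive their generators from
`numpy.random.SeedSequence` child streams keyed by named integers; no
global random state is touched.
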