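# Methods

This note documents the models, the numerical choices, and what the
synthetic-data studies do and do not establish.

## Signal model of the generator

Per voxel, the generated signal is

```
x(t) = a(t) · sin(2π f t) + σ_n · η(t)
a(t) = A_base + A_move · m(t) + g · 1_move(t) · cos(n (θ(t) − φ))
```

* `f` — theta carrier frequency, default 7 Hz (inside the 4–10 Hz band).
* `m(t)` — movement envelope factor: 1 during translation bouts, a linear
  0→1 ramp over the `onset_lead` (default 0.5 s) before each bout, and a
  linear 1→0 decay over `offset_decay` (default 0.5 s, symmetric with the
  ramp) after it. The decay exists because an instantaneous envelope step at
  bout end is a broadband click landing exactly in the stationary baseline
  window; physiological theta does not switch off discontinuously.
* `1_move(t)` — plain movement indicator: the directional modulation only
  exists while a direction exists.
* `g` — hexadirectional modulation depth (`grid_gain`), planted in exactly
  one voxel; `φ` — grid orientation in [0°, 360°/n), `n = 6` by default.
  The invariant `0 ≤ g ≤ A_base + A_move` keeps `a(t) ≥ 0`.
* `η(t)` — unit-variance noise with PSD ∝ 1/f^γ (default γ = 1), generated
  by spectral shaping of white noise, independent across voxels;
  `σ_n = noise_amp`.

Defaults: `A_base = 1`, `A_move = 1` (patients 0.6), `g = 0.5` (patients 0),
`σ_n = 1`, sample rate 200 Hz. Orientation is drawn independently per task
block by default (`orientation_mode = "per_block"`), matching the finding
that grid patterns realign across visually distinct environments; a
`"jittered"` mode (per-participant base orientation plus per-block Gaussian
jitter) exists for studying graded across-block stability, optionally
coupled to the memory-error scale so that grid instability predicts worse
spatial memory.

## Behavior and kinematics

Navigation alternates immobility (rotation toward the next direction at
90°/s) with straight translation bouts: linear acceleration to the 5 vm/s
top speed over 0.3 s, reflection off the arena boundary (heading updated to
the direction of travel). Bout durations are log-normal with arithmetic
mean 2.2 s (the reported mean movement duration) and pauses log-normal with
mean 2.5 s, so qualifying movement (≥1 s after ≥1 s immobility) and
stationary (≥2 s) periods arise at task-like rates; at the default 400 s
per block and 3 blocks, movement-epoch counts land in the range reported
for the real task. The behavioral log runs at 50 Hz — the logging rate of
the original task is not published, so this is a configurable choice.

Memory responses: per environment, 8 encoding and 32 retrieval trials
(2 and 8 per object, 4 objects drawn from 16 interior grid locations).
Remembered locations are the true locations plus isotropic 2-D Gaussian
error (per-axis SD = `memory_error_scale`, clipped to the arena), giving a
closed-form mean error `scale·√(π/2)` (Rayleigh). Performance is the
reciprocal of the mean error distance ("average then invert"; the
invert-then-average reading is available as an option). Per-participant
error scales vary log-normally (σ = 0.25 in log space) around the group
mean (8 vm controls, 12 vm patients) so group tests face realistic
between-subject variance.

## Analysis pipeline choices

* **Immobility** means translational speed exactly zero; rotation is
  permitted (only translational movement defines the epoch rules). A
  stricter reading can be implemented by thresholding rotation in the
  trajectory before epoching.
* **Boundary durations** (exactly 1 s / 2 s) qualify — inclusive ≥,
  with a 1 ns tolerance against float jitter. Epochs whose full window
  crosses a block edge are flagged `accepted = False`, never zero-padded.
* **Outlier epochs**: two-sided generalized ESD (Rosner) on the
  voxel-averaged log within-epoch variance, α = 0.05, at most ⌈n/5⌉
  removals. Under null Gaussian epochs the familywise rejection rate is ≈ α;
  α = 0 disables rejection. With fewer than 3 epochs the test is skipped
  with a warning.
* **Direction alignment** is nearest-neighbour on the circle — no angular
  interpolation, so a 350°→10° step can never produce ~0°. Within a bout,
  the nearest behavioral index is clipped into the bout, so the trailing
  half-sample keeps the bout's heading.
* **Normalization order**: the default "relative" mode divides raw power by
  the per-time sum across frequencies and then takes log10 — scale
  invariant and positivity-safe. A "literal" mode (log first, then divide
  by the per-time sum of logs) is retained behind a switch; it is ambiguous
  when logs are negative, which is why it is not the default.
* **Morlet edges**: samples within half a wavelet (n_cycles/f/2) of an
  epoch edge are NaN per frequency; normalization and averaging only use
  time points where all 40 bins are valid.
* **Hilbert band power**: 5th-order zero-phase Butterworth band-pass (the
  preprocessing filter family; the original band-pass design is
  unpublished), analytic-signal magnitude, Z-scored per voxel within each
  task block (the unit at which grids are fit). The mean/SD are retained so
  β can be de-standardized into envelope units for gain-recovery checks.
* **Regressions** include an intercept (Z-scoring makes it ≈0, kept for
  safety). Samples excluded by the overlap mask are dropped listwise.
  Blocks contribute equally to the participant average regardless of epoch
  count.
* **Symmetry × band table**: each cell is a one-sample t across
  participants; cells are declared significant under Bonferroni correction
  across the 25 cells. Without correction, a false positive among the 24
  null cells is expected in most cohorts, which would make "significant
  only in the (6, theta) cell" an unreasonable statement for any single
  cohort.
* **Whole-map inference** on the synthetic voxel grid uses a per-voxel
  one-sample t with sign-flip max-|t| permutation correction (1000 flips) —
  a small-grid stand-in for cluster-level random-field inference, which is
  out of scope.
* **Hedges' g CI** inverts the noncentral-t CDF in the noncentrality
  parameter (Brent bracketing), with a normal-approximation fallback if the
  bracket fails.

## Orientation consistency

Consistency of a set of folded orientations is the mean absolute circular
deviation from their n-fold circular mean, always in [0, 180/n]; for
exactly two orientations the pairwise folded difference is used (twice the
deviation from the mean). For uniform orientations the statistic converges
to 180/(2n) — 15° for n = 6 — which is the chance level used in the
consistency tests (negative t = more consistent than chance). Both the
deviation-from-mean and pairwise forms are exposed because the original
definition is not published.

## Verification studies and problem sizes

The studies in `gridtheta.studies` (also driven by `scripts/acceptance.py`)
use desk-scale sizes chosen so the battery runs in minutes on one core;
they are the package's own validation conditions:

* **Orientation/gain recovery**: 50 single-voxel participants, one 180 s
  block each, planted gains spanning 0.25–0.75. Median folded orientation
  error is well under 1°; de-standardized β regresses on planted gain with
  slope ≈ 0.97 (the small shrinkage is the Rice bias of the Hilbert
  envelope, ≈ σ_b²/(2A²) with σ_b the in-band noise amplitude).
* **Null calibration**: 200 cohorts of 10 participants with `g = 0`; the
  group-level one-sample t rejects at ≈5 %, the property the fold-reversal
  design exists to guarantee.
* **Group pattern**: 12 controls vs 10 patients, one 240 s block. Controls
  show strongly positive β, aligned>misaligned power, aligned fraction
  ≈ 0.5, and significance only in the (6-fold, theta) cell; patients show
  nothing; the groups differ.
* **Spectral contrast**: 8 participants, 240 s, with a noise-dominated
  oscillator (`noise_amp = 2.5`). The relative-power normalization measures
  *shares* of total power: with a strong narrowband carrier in weak noise,
  movement inflates total power so much that every noise bin's share falls
  and the 4–10 Hz band average can go negative even though the carrier bin
  rises. Real movement-related theta is a small perturbation on a broadband
  background — the noise-dominated configuration reproduces that regime,
  and there the band-average contrast is positive and already visible in
  the half second before onset. The grid-recovery studies keep the default
  `noise_amp = 1`, where envelope-based gain recovery is nearly unbiased.
  The two regimes are different study conditions, not tuned values.
* **Effect-size plumbing**: 10⁴ simulated 23-vs-17 cohorts at true
  standardized difference 0.66; the corrected estimator's bias is < 0.002.

## What the synthetic studies do not show

The generator plants a stationary sinusoidal carrier, ideal 1/f noise, and
exact cosine directional tuning; real source-space MEG has non-stationary
broadband theta, correlated noise across voxels, beamformer leakage,
eye-movement and muscle artefacts, and directional tuning of unknown shape.
Passing recovery here validates the *pipeline's* correctness and
calibration, not the physiological claim; effect sizes on synthetic data
(e.g. t ≈ 100 for controls' β) are set by the planted gain and are not
comparable to the published magnitudes. Sensor-level preprocessing (ICA,
head localization), beamformer source reconstruction, anatomical ROIs and
cluster-level whole-brain inference are explicitly out of scope: the
pipeline consumes voxel time series directly.
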