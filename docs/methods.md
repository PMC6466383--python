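# Methods

This note records the scientific and numerical choices behind metcalib: what
the model assumes, which knobs matter, what the synthetic data does and does
not emulate, and where the design was genuinely open.

## Signal chain

The device model is a waist-worn triaxial MEMS accelerometer sampling the
vertical (x), anteroposterior (y) and mediolateral (z) axes at 32 Hz with a
3 mG resolution. Per epoch (default 60 s; 10 s supported; any positive length
accepted) each axis is reduced to its mean rectified amplitude — the
time-normalised integral of |a(t)| — and the three amplitudes are combined as
the Euclidean vector magnitude ("synthetic acceleration", mG). Trailing
partial epochs are dropped, never padded: padding would bias amplitudes
downward. The number of emitted epochs is `floor(duration / epoch_length)`.

**Filter realization.** The gravity-removing high-pass is specified only by
its 0.7 Hz cutoff. We use a 2nd-order Butterworth applied forward–backward
(zero-phase) by default: Butterworth for its flat passband, zero-phase to
avoid smearing activity across epoch boundaries. Order and zero-phase are
configurable (`FilterSpec`); the forward–backward pass squares the single-pass
magnitude response, which `FilterSpec.frequency_response` reports and which
the tests use as the analytic oracle. A gait fundamental at 2 Hz passes with
gain 0.985; a 0.1 Hz postural sway is attenuated by a factor of ~2400.

**The unfiltered channel.** The discriminant needs an "unfiltered" synthetic
acceleration whose ratio to the filtered one is ~1 for locomotion and
1.3–2.6 for household activity. If static gravity (~1000 mG) stayed in the
unfiltered channel those ratios would be impossible against a 7–800 mG
filtered channel, so the unfiltered channel is computed from per-epoch
mean-removed axes: static gravity is excluded from both channels while
sub-cutoff postural movement survives only in the unfiltered one. This is the
single most consequential interpretation in the package and is flagged here
deliberately: it reproduces the published ratio scale (sedentary ≈ 2.5,
locomotion ≈ 1.0) without any tuned constant.

**Ratio floor.** The ratio is undefined when the filtered channel is
numerically zero (motionless device). Epochs with filtered synthetic
acceleration below a configurable floor — default 3 mG, the sensor
resolution — carry no ratio, are reported as a third class "still", and are
routed to the non-ambulatory equation for MET prediction (a fixed-intercept
equation returns ≈ 0.9 METs there).

## Classification

An epoch is non-ambulatory iff its ratio strictly exceeds the cutoff
(default 1.16, the published adult threshold, which carries over to young
children; 1.12 is the elementary-school value). Equality is deliberately
assigned to ambulatory so the rule is deterministic; the choice is tested.
Classification is per-epoch with no smoothing — bout aggregation is out of
scope. Raising the cutoff monotonically shrinks the non-ambulatory set
(property-tested). Per-activity discrimination tables report % above / %
below the cutoff (still epochs counted with the non-ambulatory side and also
broken out), summing to 100 per activity.

## Calibration equations and fitting

Equation forms: free-intercept linear (with optional sex/age covariate) and
fixed-intercept-0.9 linear, linear-with-covariate and quadratic. The fixed
intercept encodes the assumption that motionless wakefulness costs 0.9 METs;
fitting a fixed-intercept form is least squares of (y − 0.9) through the
origin, solved by `numpy.linalg.lstsq` on the explicit design matrix. No
prediction is ever clamped: a quadratic evaluated past its vertex or a line
extrapolated to extreme inputs returns the raw polynomial, and negative
predictions are flagged per epoch (`TwoRegressionPrediction.negative`) with a
warning rather than cosmetically corrected.

Reported diagnostics: SEE = √(SSE/(n − p)) with p the number of *fitted*
coefficients (the pinned intercept is not counted — the standard convention;
nothing in the source material fixes the degrees of freedom). R² is reported
in both conventions, centered (1 − SSE/SST about the mean) and uncentered
(normalising by the raw sum of squares of the working response), because the
convention behind the published R² values cannot be determined — the
constrained fits show *higher* R² than the unconstrained one, which suggests
an uncentered convention, so neither is asserted against published values.
Coefficient standard errors come from σ²(XᵀX)⁻¹.

Stair ascent/descent are ambulatory but sit far off the ambulatory line, so
fitting accepts an exclusion label list defaulting to both stair activities.
The sex coding of the covariate equations is not stated anywhere; the package
codes sex ∈ {0, 1} with the mapping configurable and the fixtures using
1 = boy. Predictions with a covariate equation require the covariate
explicitly and fail loudly otherwise.

## Evaluation

Energy expenditure from expired-gas measurements uses Weir's protein-free
two-term equation, EE [kcal/min] = 3.941·VO₂ + 1.106·VCO₂ (L/min), converted
at 4.184 kJ/kcal; METs are activity EE over measured resting EE. Respiratory
quotients outside (0.6, 1.3) are flagged, not rejected.

Differences are predicted − measured throughout (negative =
underestimation). Per-activity tables aggregate per-pair absolute and percent
differences (denominator: the measured MET; pairs with measured 0 are dropped
from the percent column only and counted). Bland–Altman limits of agreement
use mean ± 2 SD — the convention of the source plots, not 1.96 SD — with the
multiplier configurable and SD on n − 1 degrees of freedom.

Several published per-activity percent-difference rows cannot be reconciled
with group-mean arithmetic under any linear equation, because they depend on
per-subject pairings that are not recoverable; only the rows that reconcile
exactly (ascending stairs, jogging) are used as numeric checks. For a linear
equation the mean per-pair difference equals the difference of group means
(linearity of expectation), which is property-tested.

## Synthetic data

The generator defines the conditions everything is tested under.

*Raw archetypes* emulate three signal classes: locomotor (gravity on the
vertical axis + a ≥1.5 Hz gait sinusoid with one harmonic at half amplitude,
plus smaller anteroposterior/mediolateral components), sedentary play
(≤0.3 Hz sway, default 80 mG, plus a 3 Hz component at a quarter of the sway
amplitude) and still (gravity + noise). Sensor noise defaults to 1 mG SD, of
the order of the 3 mG resolution. The harmonic content was chosen once so
that the locomotor ratio lands naturally near 1.0–1.05, not tuned to any
particular output. These archetypes are caricatures: they contain no
biomechanical gait detail, no inter-subject anthropometry, no posture
transitions, and no non-stationarity within an epoch — so end-to-end tests
demonstrate that the signal chain separates spectral classes as designed, not
that classification accuracy on real children is 99%.

*Epoch cohorts* draw filtered acceleration, ratio and measured METs per
activity from independent truncated normals (filtered ≥ 0, ratio ≥ 1,
MET ≥ 0.9) matching the ten published group means ± SD, with the published
per-activity sample sizes (31–37) as defaults. Only marginal moments are
published, so within-activity correlation between MET and acceleration is
not emulated by default; a Gaussian-copula option with configurable
correlation exists for sensitivity checks. The coloring activity's MET
moments are absent from the transcribed table; its mean is imputed as the
quotient of the printed group-mean energy expenditures (3.51/3.06 ≈ 1.15)
and its SD scaled from the energy-expenditure CV — that row is partly
synthetic and is excluded from numeric reproduction checks.

*Calibration samples* draw x uniform on a range, y from an equation plus
Gaussian noise, defaulting the noise SD to the equation's published SEE. The
coefficient-recovery checks use n = 500 per replicate and 200 replicates,
which makes Monte-Carlo error in the replicate-mean coefficient ≲ 0.2% —
small enough to resolve the published three-significant-figure values.

All generators are deterministic given their seed (`numpy.random.default_rng`;
replicate streams in the acceptance script derive from a single
`SeedSequence`).

## Known limitations

- The unfiltered-channel interpretation above, while the only one consistent
  with the published ratio scale, is an inference; device firmware may differ
  in detail (e.g. whole-recording vs per-epoch integration, which is also
  unstated — per-epoch is assumed).
- Elementary-school and adult coefficient sets are not bundled; cross-
  population comparisons require a user-supplied equation-set JSON.
- No energy-expenditure accumulation, MVPA/bout summaries, resampling of
  irregular timestamps, or device binary formats.
- Published R² values and the Bland–Altman limits are not reproduced
  numerically (per-subject data unavailable); they are covered by the
  invariant suites instead.
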