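# metcalib

Two-regression accelerometer calibration of physical-activity intensity
(METs) for young children (4–6 years), from raw waist-worn triaxial
acceleration to per-epoch MET estimates.

Single cut-point or single-equation accelerometer calibrations systematically
misestimate the intensity of non-ambulatory activity (coloring, playing in a
sand box, tidying up …), which dominates young children's days. This package
implements the calibration scheme that fixes that: epochs are first
classified as ambulatory or non-ambulatory from the spectral character of the
acceleration itself, then a class-specific regression converts acceleration
to METs. It is intended for physical-activity and sedentary-behavior
researchers working with waist-worn triaxial accelerometry, and for anyone
who needs the fitting and agreement machinery behind such calibrations.

## The model

Raw accelerations x, y, z (mG, nominally 32 Hz) are reduced per epoch
(default 60 s) to two channels:

* **filtered synthetic acceleration** — each axis is passed through a 0.7 Hz
  high-pass filter (removing gravity), rectified and averaged over the epoch,
  and the three per-axis amplitudes are combined as the vector magnitude
  (X² + Y² + Z²)^½;
* **unfiltered synthetic acceleration** — the same reduction on per-epoch
  mean-removed axes without the high-pass filter, so slow postural movement
  is retained.

Their ratio discriminates activity type: locomotion concentrates its energy
above 0.7 Hz, so ratio ≈ 1; household/play activity has sub-cutoff components
that survive only in the unfiltered channel, so ratio > 1. An epoch with
ratio > 1.16 is **non-ambulatory**, otherwise **ambulatory**; epochs whose
filtered channel is below the 3 mG sensor floor are **still**.

METs are then predicted from the filtered synthetic acceleration *a* by the
class-matched equation:

* non-ambulatory: `METs = 0.0144·a − 0.0000147·a² + 0.9`
  (quadratic with the intercept fixed at 0.9 METs, the intensity of
  motionless wakefulness),
* ambulatory: `METs = 1.0012 + 0.00370·a` (stair climbing was excluded when
  this line was developed),
* still: the non-ambulatory equation, which returns ≈ 0.9 at zero movement.

The package also contains the machinery that produces such equations:
ordinary and fixed-intercept (constrained) least squares with SEE and R²
(`METRegression` → `fit()` → results with `params`, `bse`, `see`,
`summary()`), MET derivation from indirect calorimetry (Weir's equation,
EE/RMR), Bland–Altman agreement statistics with ±2 SD limits, per-activity
error tables, and a seeded synthetic-data generator (raw-signal archetypes
and epoch cohorts matching the study's per-activity distributions).

## Worked example

```python
import metcalib as m
from metcalib.equations import EQ5, EQ6   # the two-regression pair

rec = m.generate_raw_recording(m.ArchetypeSpec("locomotor", seed=7, duration_s=120.0))
epochs = m.compute_epoch_features(rec, epoch_length_s=60.0)
for e in epochs:
    print(f"epoch {e.epoch_index}: filtered {e.filtered_synthetic_mg:.1f} mG, "
          f"unfiltered {e.unfiltered_synthetic_mg:.1f} mG, ratio {e.ratio:.3f}")

pred = m.two_regression_predict(epochs, EQ5, EQ6)
for e, c, met in zip(epochs, pred.classes, pred.mets):
    print(f"epoch {e.epoch_index}: {c.value}, {met:.3f} METs")
```

```
epoch 0: filtered 214.9 mG, unfiltered 217.5 mG, ratio 1.012
epoch 1: filtered 214.9 mG, unfiltered 217.5 mG, ratio 1.012
epoch 0: ambulatory, 1.796 METs
epoch 1: ambulatory, 1.796 METs
```

The synthetic gait recording lands at ratio 1.012 — movement energy sits
above the filter cutoff, so both channels nearly coincide — and is classified
ambulatory; the ambulatory line at 214.9 mG gives 1.80 METs, light walking.

Refitting a simulated calibration sample recovers the generating equation:

```python
import numpy as np
x, _, y = m.generate_calibration_sample(EQ5, 0.350, 500, (5, 300), seed=0)
print(m.fit_fixed_intercept(np.column_stack([x, x**2]), y).summary())
```

```
MET calibration fit
==============================================
form:            quadratic_fixed_intercept
observations:    500
excluded labels: none
SEE (METs):      0.3279
R2 (centered):   0.8695
R2 (uncentered): 0.9739
----------------------------------------------
term                        coef       std err
intercept                 0.9000       (fixed)
filtered_mg            0.0137957      0.000337
filtered_mg_sq      -1.25066e-05      1.43e-06
```

One replicate at noise SD 0.350 METs estimates the linear term as
0.0138 ± 0.0003 against the generating 0.0144 (within 2 standard errors);
the residual SEE 0.33 matches the injected noise.

The same pipeline is available from the shell:

```sh
metcalib simulate raw --archetype locomotor --seed 7 --duration 120 --output raw.csv
metcalib process --input raw.csv --rate 32 --epoch 60 --output epochs.csv
metcalib classify --input epochs.csv --cutoff 1.16 --output classified.csv
metcalib predict --input classified.csv --output mets.csv
```

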