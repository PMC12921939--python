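# Methods

## Device models

A perimeter is reduced to the parameters that determine what stimuli it
can present: background luminance, the brightest (`dLmax`) and dimmest
reliably presentable (`dLmin`) luminance increments, the number of
achievable increment levels, and an optional neutral-density (ND) filter.
Sensitivity is the attenuation-convention decibel
`10*log10(dLmax/dL)` (base-10, factor 10, not 20).

Shipped presets:

| parameter | projection (`octopus900`) | head-mounted (`iowa_hmp`) |
|---|---|---|
| background | 1.27 cd/m² | 10 cd/m² (39.8 cd/m² on screen behind 0.6 OD) |
| dLmax | 318 cd/m² | 12.76 cd/m² |
| dLmin (effective) | 0.1594 cd/m² | 0.3206 cd/m² |
| levels | continuous | 255 |
| dynamic range | 33 dB | 16 dB |

Neither device's `dLmin` is a directly published hardware figure; both are
set so the dynamic ranges are exactly the instruments' stated 33 dB and
16 dB (a 40× ratio for the head-mounted device).  The head-mounted
display's finer 0.13 cd/m² minimal step — which would imply a 19.9 dB
range if it were reliably usable — is retained as `display_step` metadata;
the tension between the two figures is inherent to 8-bit displays viewed
through an ND filter, and both constants are configurable.

Two offsets appear in the code deliberately: the *exact* scale offset
`10*log10(318/12.76) = 13.97 dB` is used wherever a physical luminance is
converted between scales (inside the exam simulation), while the *rounded*
14 dB is used for reporting harmonization (`to_octopus_equivalent`), whose
rule is: add 14 dB to every value above the floor, leave exact 0 dB at 0,
because a floored reading is a censoring indicator rather than a
measurement.

Display quantization snaps a requested increment to the nearest of the 255
equally spaced levels between `dLmin` and `dLmax` (clamping outside); the
projection device is modeled as continuous because quantization is a
property of RGB displays.

## Test grid

The 10-2 pattern is generated as all odd-integer lattice points with
`x² + y² ≤ 82`, which yields exactly 68 locations within the central
10°, four-fold sign-symmetric, none on a meridian.  No vendor coordinate
list is assumed; a custom grid can be loaded from CSV.  The physiological
blind spot is drawn at (±15, −2)° — outside the tested field — purely as a
laterality mark (right eye: right side); the −2° vertical offset is a
display convention.

## Synthetic observers

Ground-truth sensitivities live on the Octopus-equivalent scale
(referenced to dLmax = 318 cd/m²) so a single truth drives both devices'
exams.  The baseline is a hill of vision `33 − 0.5·e` dB at eccentricity
`e` (chosen so normal central values sit near the top of the projection
device's range); disease patterns modify it:

* **OMD** — Gaussian central depression `depth·exp(−e²/2r²)`
  (defaults 18 dB, r = 4°);
* **STGD** — Gaussian annulus centered at a ring radius (depth 25 dB,
  radius 4°, width 2°), optional absolute central scotoma;
* **RP** — sensitivity preserved inside a radius (4°), ramping linearly
  over a transition width (3°) to a floor, absolute scotoma (−∞) beyond.

Defaults are stipulated, not fitted — no quantitative generative model of
IRD fields exists to fit against; they were chosen once to produce the
qualitative central / annular / concentric patterns at clinically
plausible depths.  Cohort variability: a per-subject hill-peak offset
(SD 2 dB) and size-parameter jitter (SD 0.5°) shared between the two eyes,
plus independent per-location jitter (SD 1 dB) per eye.  Finite truths are
clipped to [−10, 45] dB; −∞ encodes absolute scotoma.

Responses follow a cumulative-Gaussian frequency-of-seeing curve with
spread σ = 1.5 dB and lapse rates fp = fn = 0.03 — conventional
perimetric values.  An absolute scotoma responds only via fp.  An optional
per-device dB shift on the effective thresholds (`device_effects`) can
emulate adaptation-state physiology (losses appearing deeper on one
background than another); it is off by default, so the default pipeline
tests pure device optics/statistics, not retinal adaptation.

## ZEST engine

Per location: domain of 0.5 dB-spaced levels spanning the device range
±5 dB guard bands; uniform prior (configurable); stimulus at the pdf mean
clamped to [0, range] and quantized; likelihood = the same
cumulative-Gaussian listener form with engine-side parameters (σ = 1.5,
fp = fn = 0.03 by default — deliberately separable from the observer's
true parameters to allow misspecification experiments); stop when the pdf
SD < 1.5 dB or after 12 presentations; estimate = pdf mean clamped to
[0, range], exact 0 signaling floor.  Locations are independent (no
neighborhood seeding) and interleaved in randomized order.  The "Dynamic"
strategy of real projection perimeters is not reimplemented; both
simulated devices use this one ZEST engine, a simplification that matters
little for agreement questions.  With fp = fn = 0 in the listener model a
zero-mass posterior is theoretically possible; the update then degrades to
a no-op rather than dividing by zero.

Measured recovery at defaults (200 replicates/level, device scale 2–14
dB): |bias| < 0.1 dB, RMSE ≈ 1.1–1.2 dB, 5–7 presentations per location
(see `analysis/04_zest_recovery.py`).

## Agreement statistics

* **Pairing**: matched (subject, eye) fields, all 68 locations pointwise;
  both eyes included, no eye-correlation correction (no inferential tests
  are computed).  Global indices (mean sensitivity/defect) are deliberately
  not computed: with unequal dynamic ranges their comparison is
  meaningless.
* **Censoring**: regression keeps strictly `14 < S_octopus < 30` dB — the
  window where the head-mounted device is neither floored nor ceilinged.
* **Deming regression** (errors in both variables): closed-form slope
  `[s_yy − λ·s_xx + √((s_yy − λ·s_xx)² + 4λ·s_xy²)]/(2·s_xy)` with λ = 1
  (equal error variances; both devices use the same ZEST engine).  95% CIs
  by leave-one-out jackknife with a normal approximation — chosen for
  distribution-freeness.  Zero covariance is reported as an error (the
  perpendicular objective has no unique minimizer), not silently as a
  slope.
* **Bland-Altman**: differences of *uncorrected* values
  (octopus − hmp_raw) over pairs with octopus > 14 dB, mean ± 1.96·SD
  (n−1).  Head-mounted floor values are kept as 0 by default; a flag drops
  them instead.
* **Contingency**: condition positive ⇔ octopus < 14 dB, test positive ⇔
  head-mounted estimate exactly at floor (0 dB); diagnostic sensitivity
  tp/(tp+fn), specificity tn/(tn+fp); undefined ratios raise rather than
  return 0.
* Boundary conventions: regression censoring strict at both ends; the
  contingency splits at < 14 vs ≥ 14.

## What the synthetic pipeline does and does not show

The generator reproduces the *mechanics* of the comparison: scale offsets,
quantization, floor/ceiling censoring, and psychometric response noise.
Under these defaults both devices measure the same observer, so the
Deming slope is ≈ 1 and the mean difference ≈ 14 dB; the shallower slopes
and ≈ 16 dB differences seen with real patients arise from
background-dependent retinal adaptation, which is *not* in the default
model (the `device_effects` hook can inject it).  Passing tests therefore
validate the measurement and analysis chain, not the physiology of any
cohort.  Exam duration, fixation behavior, eye tracking, headset optics
and photometric calibration are out of scope.

## Problem sizes and determinism

The default analysis uses 12 subjects × 2 eyes × 68 locations = 1632
paired truths and ≈ 20,000 stimulus presentations total; recovery sweeps
use 200 replicates per threshold level.  Every stochastic stage takes a
`numpy.random.Generator`; the pipeline spawns independent child generators
from one master seed, so a run is reproducible bit-for-bit from that seed
and CSV round-trips preserve full float precision.
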