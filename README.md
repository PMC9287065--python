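# swipekin

Kinematic analysis of goal-directed finger swipes recorded during tablet
gameplay, built for studies of prospective motor control in young children
(for example comparing autistic and neurotypical preschoolers). The
package takes raw touch-event logs — `(participant, gesture, t, x, y,
phase)` rows at a nominal 60 Hz and 326 ppi — and produces movement-unit
level kinematics and mixed-effects group/age/distance inference, together
with synthetic-data generators so the whole chain is testable without
access to any study's raw data.

## What it computes

**Preprocessing.** Pixel coordinates are converted to mm, resampled onto
the 60-Hz grid when timestamp jitter exceeds 10% of the sampling interval,
smoothed with a fourth-order zero-phase 8-Hz low-pass Butterworth filter
(forward–backward), and differentiated with a five-point stencil; speed is
`|v| = sqrt(vx² + vy²)`.

**Movement units (MU).** A movement unit is one acceleration–deceleration
phase of the speed profile: a velocity maximum retained only if its summed
velocity change (rise from the preceding minimum + fall to the following
minimum) is ≥ 8 mm/s *and* the maximum exceeds 5% of the swipe's peak
velocity (PV). Rejected maxima are merged into the neighbouring unit.
From the units and the speed profile each swipe yields: movement time
(MT), PV, time to PV (TTPV), the first unit's peak (PV1), whether PV lies
in the first unit (PV1-b), the percentage of MT after PV (%Dec), the unit
count (MU) and the number of units after PV (MU-APV).

**Cohort filtering.** Swipes enter the analysis only when goal-directed
(food area → plate area), and survive a fixed exclusion cascade
(multiple-touch → < 5 samples → sub-minimum distance → MT > 2 s →
distance > 70 mm → straightness > 1.5); participants must make ≥ 10%
goal-directed swipes. A stricter sensitivity subset requires < 5 mm of
path before the first and after the last velocity minimum.

**Models.** Each outcome is modelled with a per-subject correlated random
intercept and distance slope:

    log Y_ij = β₀ + β_D Dist_ij + β_A age_i + β_G ASD_i + β_GA ASD_i·age_i
               + b_0i + b_1i Dist_ij + ε_ij,   (b_0i, b_1i) ~ N(0, Σ)

with Dist the centred 10-mm distance-category index and age centred at
4.7 years. MT, PV and TTPV are log-normal (REML, Satterthwaite t-tests);
PV1-b is logistic and MU-APV Poisson (Laplace-approximate ML, Wald
z-tests); total MU is zero-truncated Poisson since every swipe has at
least one unit. Coefficients are reported exponentiated (multiplicative
effects, odds ratios, incidence-rate ratios) with intraclass correlations
and Nakagawa–Schielzeth marginal/conditional R².

## Worked example

Simulate one noisy food-to-plate swipe and extract its kinematics:

```sh
$ swipekin simulate trajectory --seed 3 --out demo
$ swipekin extract --events demo/events.csv --out demo_out
1 food-to-plate swipes from 1 participants; 0 rejected rows
```

`demo_out/kinematics.csv` then contains one row per swipe:

    MT=0.5  PV=156.87  TTPV=0.25  pct_dec=50.0  MU=1  MU_APV=0
    target_distance=41.1  dist_cat=4  straightness=1.012

A noiseless 40-mm, 0.5-s minimum-jerk stroke peaks at 1.875·A/T =
150 mm/s exactly halfway through; the 156.9 mm/s here reflects the 0.3-mm
default sensor noise. Fitting the movement-time model on a simulated
cohort drawn from the generative defaults:

```sh
$ swipekin simulate cohort --seed 3 --out demo2
wrote 4828 swipes from 71 subjects
$ swipekin fit --frame demo2/cohort.csv --outcome MT
...
sigma2=0.0797 tau00=0.1371 tau11=0.0000 rho01=1.000
ICC=0.634 R2m=0.249 R2c=0.725 AIC=1857.5
```

The exponentiated Dist coefficient from such a fit sits near 1.10 — each
10-mm step in target distance lengthens movement time by about 10% — and
the ICC near 0.6 says most residual MT variation is between children.

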