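# Methods

## Signal chain

Touch events arrive as `(participant, gesture, t, x, y, phase)` rows with
phase codes 0 (began), 1 (moved), 3 (ended). Gestures lacking a began or
ended event are structurally invalid and analysed no further; gestures of
one participant whose time intervals strictly overlap are flagged as
multiple touches (intervals sharing a single endpoint are rapid sequential
taps and are not flagged). Goal-directedness is decided from the first
and last event positions alone, against half-open rectangles
`[x0, x1) × [y0, y1)` so that points on shared edges belong to exactly one
region. The layout geometry is not dictated by any data format; the
shipped default is a stylised sharing-game scene on a 2048 × 1536 canvas
(central 600 × 500 food rectangle, four plates) whose nearest
food-to-plate edge gap is 173 px ≈ 13.48 mm at 326 ppi — this gap doubles
as the sub-minimum-distance exclusion threshold, matching the shortest
displacement a genuine food-to-plate swipe can have.

Positions are converted to mm (25.4/326 mm per px) before filtering.
Timestamps within 10% jitter of the nominal 1/60 s interval pass through
untouched; otherwise positions are linearly interpolated onto a uniform
grid of `round(span·60) + 1` points. The tolerance avoids resampling
artefacts on well-behaved streams while bounding grid error on glitchy
ones; it is a package decision (device streams are nominally uniform) and
is exposed in the preprocessing configuration for sensitivity checks.

Smoothing is a fourth-order Butterworth low-pass at 8 Hz applied
forward–backward (zero phase). We deliberately do not pre-warp the cutoff
for the double pass, matching standard biomechanics practice; the
effective amplitude response is the squared digital Butterworth magnitude
`1/(1 + (tan(πf/fs)/tan(πfc/fs))^8)`, which the tests verify at 1, 8 and
25 Hz (exactly 1/2 at the cutoff). Edge handling uses odd reflection
padding of length 3 × order; series too short to pad (≤ 12 samples) pass
through unfiltered with a warning rather than being dropped, because the
only hard length rule upstream is the five-sample minimum. Velocities
come from the five-point central stencil
`(-f[i+2] + 8f[i+1] - 8f[i-1] + f[i-2])/(12·dt)` (exact through degree-4
polynomials, fourth-order convergent); the two samples at each edge use
second-order one-sided/central differences so movement time and landmark
timing stay defined over the full touch interval.

## Movement-unit segmentation

A candidate unit is an interior speed maximum with its flanking minima
(plateaus collapse to their midpoints; the series start/end act as
boundary minima when speed rises from/falls to them). Two retention
criteria apply: the summed velocity change across the unit
(rise + fall) must reach 8 mm/s, and the maximum must exceed 5% of the
swipe's global peak velocity, computed before any rejection. The 8 mm/s
criterion is read as applying to rise and fall *summed* — the
acceleration and deceleration phases jointly — which matches the infant-
reaching movement-unit tradition this definition descends from; a config
switch (`cumulative_rule="each"`) applies it to each side separately for
sensitivity analysis.

When a candidate fails, the weakest failing candidate (smallest
rise + fall; ties by position) is merged first: the higher of its two
boundary minima is deleted so the bump joins its larger neighbour, the
merged unit's peak is the higher of the two peaks (first occurrence on
ties), and both criteria are re-evaluated until stable. Edge candidates
have only one neighbour and merge toward it. This deterministic
weakest-first rule makes the result independent of scan order. At least
one unit is always returned: if nothing survives (monotone or all-zero
profiles) a single degenerate unit spans the series.

An initial deceleration before the first minimum, or a final acceleration
after the last one, belongs to no unit; the path covered there is
reported as `pre_first_min_dist` / `post_last_min_dist` and drives the
sensitivity subset (< 5 mm on both margins), which screens out swipes
that are not a single aimed movement. Peak velocity is the first sample
attaining the global maximum; %Dec is computed from this global PV (the
literal reading of the deceleration-phase definition), not from the first
unit's peak when they differ.

## Exclusion cascade

Rules fire in a fixed order — multiple touch, < 5 samples, sub-minimum
distance, MT > 2 s, distance > 70 mm, straightness > 1.5 — and each swipe
carries exactly the first reason that fires, so per-reason counts sum to
the input and the audit trail supports re-ordering analyses. Boundary
values (MT = 2.0 s, 70 mm, straightness 1.5) are retained. Target
distance uses the raw first/last touch positions; path length and
straightness use the filtered path. Distance categories are six half-open
10-mm bins from 10 mm, the top bin closed at 70 mm.

The participant rule as usually printed ("excluded … participants who made
at least 10% of food-to-plate swipes") reads backwards relative to its
evident intent; we retain participants whose goal-directed ratio is
≥ 10% — the engaged players — with the boundary ratio retained and the
literal direction available behind `literal_participant_rule` rather than
silently chosen.

## Mixed models

Outcomes are modelled with per-subject correlated (intercept, Dist slope)
random effects; Dist enters fixed effects as a single centred category
index (one slope, not five contrasts) and age as mean-centred years
(centre 4.7). Final fixed-effect sets: `Dist + age + ASD + ASD:age` for
log MT, log PV, log TTPV; main effects only for logistic PV1-b; both
`ASD:age` and `ASD:Dist` for Poisson MU-APV; main effects for
zero-truncated-Poisson MU and the linear secondary outcomes PV1 and %Dec.
Interaction retention follows AIC improvement (the `Dist:age` screening
question is likewise decided by AIC).

No installed Python package fits this structure for the non-Gaussian
families (correlated random slopes, and zero-truncated Poisson at all),
so the estimation engine is implemented here and cross-checked in the
test suite against `statsmodels.MixedLM` (Gaussian) and R's `glmmTMB`
(Poisson), to which it agrees to four decimals on shared data:

* **Gaussian, REML.** The residual variance and fixed effects are
  profiled out; the remaining three covariance parameters (log-Cholesky)
  are optimised by bounded Nelder–Mead, with per-subject 2 × 2 Woodbury
  identities making each criterion evaluation O(n). Log-SD parameters
  are clamped at −8 (a variance ratio of ~10⁻⁷) because boundary fits
  otherwise drift indefinitely; convergence on a boundary is certified by
  a simplex restart that must fail to improve the criterion by more than
  10⁻⁴. Satterthwaite degrees of freedom for the t-tests come from
  numerical derivatives of each fixed effect's variance with respect to
  the unprofiled variance parameters and the numerical REML information;
  at degenerate boundaries they fall back to the residual df.
* **GLMM, Laplace ML.** Random effects are reparametrised spherically
  (`b = L·u`, `u ~ N(0, I)`), so the per-subject inner Newton step —
  vectorised across subjects as closed-form 2 × 2 solves — is well-posed
  at variance boundaries without inverting the covariance. The Laplace
  log-likelihood is maximised over fixed effects and Cholesky jointly
  (L-BFGS-B, bounded log-SDs); Wald z inference uses the inverse
  numerical Hessian. The zero-truncated Poisson log-likelihood is
  `y·log μ − μ − log(1 − e^{−μ}) − log y!`, with derivatives computed via
  `expm1` for stability at small rates.

Fits whose random-effect SDs collapse below 10⁻³ or whose correlation
pins at ±1 are returned flagged singular, never raised. Dispersion for
count families is the Pearson ratio conditional on the estimated random
effects, over n minus the number of fixed effects. Variance components
follow the Nakagawa–Schielzeth conventions: between-subject variance is
the observation-averaged `z'Gz` (Johnson's random-slope extension); the
latent residual variance is σ² (Gaussian), π²/3 (logistic) or the
lognormal approximation `ln(1 + 1/λ₀)` with λ₀ the rate at the
fixed-effect intercept (count families) — the estimator for count models
is a pinned convention, since reported ICC/R² statistics rarely name one.

Descriptive cohort tests use Pearson χ² (Yates correction only where the
published convention demands it — the 2 × 2 exclusion table; the sex and
distance-distribution tables reproduce published values only without
correction), pooled-variance t-tests (also computable from published
summary statistics), an F variance-ratio test for age, and a Mann–Whitney
test on the distance category.

## Synthetic data

Trajectory-level: swipes are sums of 1–5 minimum-jerk submovements
(`v(τ) ∝ 30τ² − 60τ³ + 30τ⁴`, peaking at 1.875·A/T), superposed in
velocity space, integrated from a start point in the food area, noised
with isotropic Gaussian positional error and emitted as 60-Hz
began/moved/ended pixel events. Ground truth records the generative
submovement count separately from the expected recovered count, since
overlapping pulses can merge peaks. The default 0.3-mm noise SD is a
calibration choice (no device noise figure is published): at 0.1 mm the
pipeline recovers well-separated submovement counts exactly; at 0.3 mm
velocity ripples reach the 8 mm/s retention threshold and units are
overcounted by one or two — the tests pin this monotone degradation as a
calibration table rather than assuming robustness.

Cohort-level: subjects (default 43 + 28, the study's group sizes) receive
truncated-normal ages on 2.8–6.6 years (mean 4.7, SD 0.905) and
negative-correlated (intercept, slope) random effects drawn per outcome
from the reported variance components; distance categories follow the
pooled observed proportions (5.9/30.7/18.9/21.7/16.4/6.4%); outcomes are
drawn from each model's family with fixed effects defaulting to the
reported exponentiated coefficients. Where no estimates are published
(MU, PV1, %Dec models), defaults are plausible same-magnitude values and
are labelled as such. The reported slope variances for the three
log-scale outcomes are 0.00 at the printed precision and are taken
literally, so those fits sit on the variance boundary by construction and
come back flagged singular — deliberate, as it exercises the boundary
path the real data produced. Outcomes are drawn independently given the
covariates (they are modelled separately); cross-outcome correlation
structure is only available through trajectory-level simulation.

What the generator does *not* emulate: game mechanics and item positions,
participant-level engagement differences beyond the swipe-count
distribution, heavy-tailed or autocorrelated sensor noise, and any
dependence between the outcome variables beyond shared covariates.
Passing tests therefore demonstrate correctness of the estimators and the
pipeline under the stated generative model, not fidelity to any real
cohort.

## Problem sizes and calibration checks

Parameter recovery refits the five primary models on 200 cohorts of 70
subjects × 55 swipes drawn from the generative defaults; estimates are
essentially unbiased (largest |bias| ≲ 0.016 on the link scale, under 5%
of the smallest effect) with CI coverage near nominal, and the group
term's type-I error under a null generative model is checked against its
binomial Monte-Carlo band. With 25 fixed effects tested simultaneously
at per-term two-sigma bounds, isolated marginal exceedances are expected
from Monte-Carlo noise alone (the chance that all 25 clear a 2σ bound
jointly is only ≈ 0.3); the acceptance tests nevertheless apply the
per-term bounds as specified, so a marginal term can fail there while an
independent replication passes. Segmentation is verified against a
brute-force reference on 1,000 random multi-bell profiles with zero
mismatches. The acceptance script runs single fits at full study scale
(71 subjects, ~4,500–4,900 swipes), completing in seconds.

## Known limitations

* Wald z intervals for the GLMM between-subject terms are mildly
  anticonservative at ~70 clusters (a known property of Laplace/Wald
  inference, shared with the reference tooling, which reports identical
  standard errors).
* The Laplace approximation is least accurate for low-rate counts
  (MU-APV rates near 0.3); adaptive quadrature is not implemented, as the
  correlated-slope structure makes it unnecessary at these sizes.
* The segmentation thresholds (8 mm/s, 5% of PV) are taken as given; no
  data-driven re-tuning is attempted, only the documented sensitivity
  switches.
* Endpoint accuracy, jerk metrics and submovement deconvolution are out
  of scope.
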