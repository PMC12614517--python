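# Methods

This note documents the models, numerical choices, and limitations of
`ambientgait`: what each estimator assumes, what the synthetic walker
does and does not emulate, and where the design was genuinely open.

## Trial geometry and conventions

A trial is one pass along a hallway of length 14 m (configurable): the
first and last 3.5 m are acceleration/deceleration zones and the middle
7 m is the monitored steady-state zone. Internally everything is in
meters and seconds; the hallway axis `u` increases in the walking
direction with the origin at the start line. Skeleton coordinates may be
in any rigid camera frame — both skeleton-derived metrics depend only on
inter-joint and inter-frame distances and are rigid-transform invariant
(asserted to 1e-9 relative in the tests). Tracking dropouts are NaN
triplets (all three coordinates of a joint jointly missing); zero is a
legal coordinate and never a sentinel.

## Skeleton speed

The pelvis is the best-tracked joint; its 3-D displacement from the
first tracked position grows linearly during steady-state walking.
Speed is the OLS slope of displacement on time with iterative symmetric
trimming:

1. remove leading/trailing dropout runs; linearly interpolate interior
   dropout runs of ≤ 2 samples; a longer interior run splits the series
   and the longest clean segment is kept (flagged `split`);
2. while R² ≤ 0.98 and more than `min_points` (30 ≈ 1 s) samples
   remain, drop one sample from each end and refit; hitting the floor
   flags the fit `trim_failed` rather than resorting to manual editing;
3. once the threshold is met, trimming continues while each further step
   still improves R² by more than 1e-6.

Step 3 exists because on long trials the acceleration tails are a small
share of the total variance: R² can sit above 0.98 with tails still
present, biasing the slope low by up to a few percent. While a tail is
being consumed each trim measurably raises R²; on steady-state data
(residuals are noise) R² plateaus at once, so the refinement is
self-terminating and never fires on clean linear data (zero trimming,
R² = 1 exactly in tests). R² is the coefficient of determination,
identical to the squared Pearson correlation of fit versus data for a
simple linear regression.

## Skeleton cadence

The foot-swing signal (ankle-to-pelvis 3-D distance) of one foot
oscillates once per stride (two steps): the forward reach and backward
push-off are asymmetric, so the dominant spectral component is the
stride frequency, and cadence = 120 · mean dominant frequency of the
left/right signals. Numerical choices:

* search band 0.5–1.5 Hz — stride frequencies for 60–180 steps/min; DC
  is excluded by mean removal; ties take the earliest frequency;
* the irregularly sampled signal (camera timestamps jitter around
  30 fps) is linearly resampled onto a uniform grid at the median frame
  interval before the FFT;
* zero-padding to ≥ 100 s gives ≤ 0.01 Hz bins, i.e. cadence
  granularity ≤ 1.2 steps/min;
* ≥ 3 s of signal and ≥ 50% joint coverage are required.

## Body dimensions

Torso length is the pelvis→neck segment (configurable; the choice of
joints is a documented convention, not a measurement claim), leg length
hip→knee + knee→ankle averaged over sides, shoulder width the
inter-shoulder distance; medians over frames make the estimates robust
to per-frame tracking noise (≈ 1% error at 5 mm joint noise over 100
frames). Body area = shoulder width × (torso + mean leg). Cohort body
areas are z-scored against the female subset (sample SD), the
convention used for sex comparisons.

## Floor-vibration pipeline

**Preprocessing.** Linear detrend, then forward–backward Butterworth
filtering (order 2): 5 Hz high-pass against structural drift, 250 Hz
low-pass against mechanical noise. The forward–backward pass cancels
phase (an impulse's energy-peak window is unmoved — asserted) and
squares each magnitude response. A half-cosine taper over the first and
last 0.25 s suppresses the filter's edge transient, which otherwise
looks like an impulsive event at the record boundary — or inside the
record once synchronization shifts a channel group. The taper length
covers ~8 time constants of the 5 Hz high-pass; records begin and end
with the hallway quiet, so no signal is lost.

**Synchronization.** The two wireless acquisition units free-run on
independent clocks. One redundant sensor is co-located with a sensor of
the other unit; the lag of their cross-correlation maximum is applied as
an integer-sample shift to the whole second group, after which the
duplicate is dropped. Recovery is within one sample at 16,384 Hz for
lags in ±0.5 s (asserted over 50 seeds), and the lag estimate is
invariant to channel gain.

**Detection.** Per-sensor mean power (acceleration²) in non-overlapping
0.02 s windows, divided by that sensor's median window power — so each
sensor's SNR series has median exactly 1 and any per-channel gain
cancels — then maximized across sensors (SNRmax). Peaks must exceed
median + 9·σ_SNR, where σ_SNR is the SD of SNRmax after one-sided
exclusion of points above median + 3·MAD (footstep peaks are positive
excursions), and be ≥ 0.3 s apart (highest-first suppression, the
standard peak-finder semantics). The 0.02 s window bounds timing error
at one window.

**Cadence.** 60 / mean(Δt) over inter-step intervals, after removing Δt
outside median ± 3·MAD; when MAD = 0 (perfectly periodic steps,
window-quantized times) the fallback removes Δt > 1.5 × median. Each
removed long gap implies round(gap/median) − 1 missed steps, reported so
detected + missed totals can be compared across trials. Instantaneous
cadence (60/Δt), z-scored within trial, is the step-capture diagnostic:
missed steps produce strongly negative z.

**Localization.** Footstep energy at sensor s is modelled as
E_s = E₀·exp(−α·d_s) with d_s the along-hallway distance — 1-D because
the walk follows a straight hallway and the across-hallway offset is
absorbed into the effective decay; 2-D is underdetermined with six
usable sensors and noisy decay on an inhomogeneous floor. Energies are
summed in ±0.05 s windows around each detected step and normalized by
the sensor's median window energy, which (for comparable noise floors)
cancels per-channel gains. Position is found by profile least squares on
log E: for each candidate position on a 2 cm grid (refined 10×), the
decay fit is closed-form, with α ≥ 0 profiled out per trial by default
because floor media vary. Steps whose energies never exceed 3× the
noise floor get NaN positions.

**Kalman speed.** A constant-speed kinematic model [position, speed]
filtered over the step-position observations, then Rauch–Tung–Striebel
smoothed; the reported speed is the terminal smoothed speed (the slope
of the smoothed track). Measurement variance is estimated from the
residuals of a Theil–Sen pre-fit after excluding gross outliers
(beyond max(3 robust SDs, 0.5 m)); observations whose innovation exceeds
max(3·√S, 0.5 m) are skipped, with the state covariance inflated (×4)
on each skip so that consecutive gating widens the gate and the filter
re-acquires the track rather than locking onto a bad prediction.
The 0.5 m floors encode the scale
separation between genuine localization scatter (decimeters) and gross
mislocalizations (meters); without them a collapsed robust scale on an
11–14-step trial can starve the filter. Process noise on speed is small
(1e-4 m²/s³; quasi-constant speed); both noises are exposed. Noiseless
linear tracks are recovered to ≤ 1e-6; a single 3 m outlier is gated
and the speed stays within 10% of truth.

## Synthetic walker

The simulator emulates the study conditions so that every estimator can
be checked against ground truth:

* trajectory: linear speed ramp over 1 s at each end, constant speed
  between; heel strikes only inside the monitored zone, one step length
  apart, with step length = speed/(cadence/60) so speed = Δposition/Δtime
  holds exactly before noise;
* skeleton: 32 named joints at 30 fps with ~2 ms timestamp jitter,
  isotropic 5 mm joint noise, 2% per frame-joint random dropouts, and
  forced 0.5 s dropout runs at each end (the camera locks on late and
  drops off early at its range extremes); pelvis sway/bob at step
  frequency; ankles swing radially so the ankle–pelvis distance is
  exactly leg + 0.12·sin(2π f_stride t + φ side), matching the cadence
  model;
* floor: seven channels at 16,384 Hz (tests mostly use 4,096 Hz to keep
  runtimes short; the statistic is window-based and rate-insensitive,
  and synchronization is exercised at the full rate), Gaussian sensor
  noise (SD 0.01 against unit source amplitude), Gaussian-windowed 80 Hz
  bursts (σ 10 ms, inside the 5–250 Hz passband) with amplitude
  ∝ exp(−α d/2) (energy ∝ exp(−α d)), α = 0.35 m⁻¹, ±10% lognormal
  per-step amplitude jitter, and an injected clock offset on the second
  acquisition group;
* cohort: subject-level speed ~ N(1.2, 0.27²) m/s and cadence
  ~ N(111, 11²) steps/min with age pulling both down (r ≈ −0.34 and
  −0.26 respectively); fast pace scales speed ×1.25 and cadence ×1.14;
  within-subject repeat SDs 0.04 m/s and 1.5 steps/min; device noise
  reflects each sensor's strengths (camera speed SD 0.01 m/s but
  cadence SD 30 steps/min; floor cadence SD 1 steps/min but speed SD
  0.25 m/s); the stopwatch times the full 14 m including the ramps
  (hence a systematic positive device-minus-stopwatch speed difference)
  with 0.3 s reading error and 5% gross errors; frailty scores follow a
  monotone noisy link to slowness and age, and the recovery
  questionnaire's good/poor odds follow a logistic model dominated by
  the speed×cadence interaction.

What the simulator does **not** emulate — and hence what passing tests
do not show about real deployments: soft-soled shoes or carpeted floors
(lower vibration SNR), inhomogeneous floor media (the exponential decay
is exact here, idealized in reality), self-occlusion structure in camera
dropouts (dropouts are independent given the forced edge runs), multiple
walkers, and hesitation or turning mid-trial.

## Statistics

ICC is computed from the ANOVA table: one-way random effects, single
measure — ICC(1) = (MSB − MSW)/(MSB + (k−1)·MSW) — by default, the
common default of the R reliability packages; two-way absolute-agreement
ICC(2,1) and consistency ICC(3,1) are selectable. p-values are the
corresponding F tests. All three forms agree with an independent
implementation to ≤ 1e-10. The permutation test shuffles the
second-trial vector against the fixed first (breaking pairing,
preserving marginals), 10,000 times by default, and reports
Q = (b+1)/(n_perm+1); under a true null Q is uniform (KS-checked). No
multiple-testing adjustment is applied anywhere — p and Q are reported
unadjusted, matching how such analyses are conventionally presented.

Device-versus-stopwatch agreement first drops stopwatch speeds
> 2.5 m/s (physiologically implausible; stopwatch user error), then
pairs whose device−stopwatch difference lies beyond mean ± 2.5 SD, then
reports Pearson r. LOOCV logistic models are unpenalized per-fold
refits; accuracy thresholds held-out probabilities at 0.5 and AUC is the
Mann–Whitney rank statistic with ties averaged. The recovery model is
outcome ~ speed + cadence + speed·cadence with Wald 95% CI on the
interaction odds ratio; separation falls back to a weakly penalized
point estimate, flagged, with no CI.

## Problem sizes

The test suite and acceptance script use simulation sizes chosen to make
each property statistically decisive while staying desk-scale: 60–100
trials per recovery sweep, 4,096 Hz floor records except for the
synchronization checks (16,384 Hz, 20–50 seeds), 100-seed Monte-Carlo
for the Kalman stage, 300–1,000 random tables for the ICC oracle, and a
200-subject cohort rehearsal.

## Known limitations

* Floor-based speed assumes a single walker moving monotonically along
  the hallway; the 1-D localization cannot represent lateral position.
* The SNRmax statistic needs a nonzero noise floor: an exactly silent
  record makes median normalization degenerate (guarded with errors).
* The trimming refinement assumes residual tails monotonically depress
  R²; exotic non-monotone artifacts could over-trim toward the
  `min_points` floor.
* ICC form selection matters near boundaries; the package defaults to
  ICC(1) and exposes the two-way forms rather than guessing.
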