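# Methods

This note documents the models, rules and numerical choices behind
`mobgait`: what the synthetic generator emulates, how each analysis layer is
defined, which decisions were genuinely open, and what the validation does
and does not show.

## Synthetic foot-IMU model

**Stride kinematics.** A stride runs mid-stance to mid-stance: flat foot for
half the stance phase, a swing arc, flat foot again. The horizontal
progression follows a minimum-jerk quintic `s(τ) = 10τ³ − 15τ⁴ + 6τ⁵`
(exact endpoint constraints, zero velocity and acceleration at both ends),
scaled to the stride length along the stride heading. The vertical
excursion is `z(τ) = H·sin³(πτ)` peaking at the maximum sensor lift `H`.
A sin³ bump was chosen over the more common raised cosine because its
vertical *acceleration* is continuous at the swing boundaries; a raised
cosine injects an acceleration step that biases any quadrature-based height
reconstruction by several percent depending on where the step falls between
samples. All position/velocity/acceleration values are evaluated in closed
form on the sample grid, so the signal is exactly consistent with the
ground-truth parameters.

**Orientation.** Sagittal pitch rate is modelled as three lobes over the
swing: sharp negative (plantarflexion) lobes of width 12% of swing time
peaking exactly at toe-off and heel strike (peak 350 deg/s), and a broad
positive dorsiflexion lobe mid-swing whose area balances the edge lobes so
net pitch per stride is zero. Placing the negative peaks at the true events
is deliberate: it makes the generator's event times and the standard
gyroscope event-detection convention refer to the same instants, so stance
percentage is recoverable without calibration offsets. Turning strides add
a smooth yaw ramp (minimum-jerk) of 60° per turn stride (three strides per
180° turn; 60° clears the 45° turn-flag threshold with margin). Sensor
frame: x forward, y left, z up on flat foot; the accelerometer reads
specific force in g (+1 g on z at rest), the gyroscope body rates in deg/s.

**Noise.** White Gaussian per channel, defaults 0.02 g and 0.5 deg/s
(typical MEMS noise at ~100 Hz), deterministic given a seed.

**Phenotype presets.** `mobgait/data/phenotypes.yaml` holds the published
group medians for MSA, PSP and PD: the five gait-test parameters with their
inter-stride CVs and left/right asymmetry indices, per-bout-class daily-life
gait metrics, daily activity volumes, and clinical motor scores
(median/IQR). The per-stride generator draws *gait velocity and stride
time* as primary variables (normal, ±3σ clipped) and derives stride length
as their product: the three printed medians are independent cohort medians
and are not mutually consistent (e.g. PD: 1.31 m / 1.08 s = 1.213 ≠
1.24 m/s), and velocity is the quantity the validation targets most
directly. The derived stride-length mean stays within ~2.5% of its printed
median. Left/right asymmetry a (in %) is applied as multiplicative side
factors 2r/(1+r) and 2/(1+r) with r = (100+a)/(100−a), which preserves the
two-foot mean and reproduces the asymmetry index exactly in expectation.

**Daily schedules.** A day is an ordered, non-overlapping episode list
(walking / non-locomotion activity / sedentary / non-wear) covering a
contiguous span. The default builder draws walking-bout counts per duration
class from the preset medians (e.g. PD: 137 short, 14.5 medium, 7 long
bouts/day), bout durations uniformly inside their class bins, cadences
around the class medians (sd 6 steps/min), and appends sub-10-s ambulation
until the scheduled step total reaches the preset daily step count (6471 /
6189 / 9614 for MSA / PSP / PD). Wear time is drawn in 9–11 h with optional
off-body blocks. Signal model per episode kind:

| kind | accelerometer | gyroscope | rationale |
|---|---|---|---|
| non-wear | 1 g + clipped noise (sd 0.008 g, |dev| < 0.03 g) | clipped, < 2 deg/s | guaranteed inside the non-wear triple threshold |
| sedentary | sd 0.004 g (below the 0.01 g active-minute SD) | sd 3 deg/s micro-movements | a worn-but-resting limb is never 90 min inside the gyro threshold |
| active | sd 0.015 / 0.06 / 0.15 g by intensity | sd 20 deg/s | straddles the low/medium/high SD bins (0.02, 0.10 g) |
| walking | stride trains + sensor noise (0.02 g / 0.5 deg/s) | — | same kinematic model as the gait test |

Week signals are rendered lazily per day from an eagerly drawn plan (the
concrete stride templates), so ground truth exists without holding a week
of samples in memory; rendering the same day twice is bit-identical.

**What the generator does not emulate** (and therefore what passing tests
do not show): tremor, festination or freezing-of-gait signal morphology;
soft-tissue and mounting artifacts; day-to-day sensor re-donning
orientation variance (mounting is fixed); magnetometer channels; curved
overground paths outside turns; double-support timing coupling between the
feet (feet are offset by half a stride but drawn independently).
Recovery results on this data bound algorithmic error, not clinical
validity on pathological signals.

## Instrumented gait analysis

**Segmentation.** Stance candidates are maximal runs where the smoothed
(0.12 s window) gyroscope norm stays below 40 deg/s and the smoothed
|acc norm − 1 g| below 0.12 g. A gap between runs is a swing if it lasts
0.1–1.5 s with a smoothed gyroscope peak ≥ 80 deg/s and a raw acceleration
deviation peak ≥ 0.4 g (the acceleration criterion separates true swings
from vigorous non-locomotion arm/leg movement). Each accepted swing yields
one stride segment bounded by the mid-points of the flanking stance runs;
runs longer than 1.6× the typical stance (standing, mid-bout pauses)
contribute only half a typical stance to the adjacent stride. Indices are
0-based with half-open segments `[start, end)`.

**Events.** Within a segment, the gyroscope axis with the swing signature
(checked in decreasing-variance order, both signs) provides toe-off as the
most negative sample before the swing maximum and heel strike as the most
negative sample after it; the swing maximum must reach 60 deg/s and the
negative peaks 20 deg/s. Segments without the signature (e.g. constant-rate
rotation) are rejected with a logged reason. Stance time is computed as
stride time minus swing time (toe-off → heel strike), which is robust to
the mid-stance phase convention; stance percentage is stance/stride × 100.

**Trajectory.** Initial attitude aligns the mean stance accelerometer with
gravity (yaw unobservable, set to 0); the gyroscope is integrated by
trapezoidal rotation-vector steps; gravity-free world acceleration is
double-integrated with an affine velocity correction forcing zero mean
velocity in the 0.05 s anchor windows at both segment ends (classical
zero-velocity updates). Stride length is the horizontal displacement
between anchor means; maximum lift the peak height above a linear flat-foot
baseline. The zero-velocity contract is enforced on the *anchor-window
mean* velocity (exactly zero by construction, asserted < 1e-6 m/s);
pointwise velocity inside the windows carries O(1e-5 m/s) residue from
trapezoidal integration at 102.4 Hz.

**Aggregation.** Mean and CV (sample SD, n−1, over the pooled strides of
both feet) per parameter; the asymmetry index pairs each left stride with
the next right stride in time (leftovers dropped), takes
|(L−R)/(L+R)|×100 per pair and reports the median. Pairs with zero sum are
dropped with a warning; a zero mean leaves the CV undefined (NaN, logged).
Turn strides (per-stride heading change > 45°) are excluded from the
aggregates by default (configurable): the 2×10 m protocol makes the turn an
artifact of the course, not of gait. A test with fewer than 4 valid strides
is flagged `insufficient`. Noiseless recovery against generator truth is
within ~2% for all presets (tolerance asserted: 5%); at default noise the
aggregate means stay within 10% in ≥ 95 of 100 seeded runs.

## Physical-activity monitoring

* **Non-wear:** a maximal span with |acc norm − 1 g| < 0.05 g **and**
  gyroscope norm < 2 deg/s throughout, lasting > 90 min. Wear and non-wear
  intervals exactly partition the recording.
* **Valid days:** 8 h ≤ wear ≤ 12 h, bounds inclusive (the boundary
  convention is unspecified in the wear-time literature; inclusive keeps
  the printed bounds admissible); subjects need ≥ 3 valid days, otherwise
  the profile is flagged excluded with the triggering rule logged.
* **Bouts:** strides from the same segmentation as in the clinic, both
  feet, merged while the inter-stride gap is ≤ 3 s. Classes: short
  [10, 30] s, medium (30, 60] s, long > 60 s — half-open bins are
  exhaustive and match both printed phrasings ("30–60 s" and "31–60 s") to
  within rounding. Bouts < 10 s are subthreshold: steps count, bouts don't.
* **Steps:** initial contacts of both feet; with two sensors each stride of
  each foot contributes one step. The detector uses the stride-end
  (mid-stance) time as the contact proxy — at minute resolution the offset
  is immaterial, and end-to-end step counts match schedule truth exactly on
  clean signals (asserted within 2%).
* **Macro:** minute epochs over wear time (a minute needs ≥ 30 s wear);
  MVPA iff ≥ 90 steps in the minute; active iff ≥ 1 stride or
  acc-norm SD > 0.01 g; sedentary otherwise; zero sedentary minutes flags
  the ratio infinite. Subject descriptors are the median over valid days,
  plus the maximum for the long-bout count; the long-bout duration
  descriptor is the per-day median of long-bout durations, then the subject
  median.
* **Micro:** per-bout medians pooled over the recording period, per class
  and over all bouts ≥ 10 s; Gaussian KDE with the classic Silverman
  bandwidth 0.9·min(sd, IQR/1.349)·n^(−1/5) on a 512-point grid spanning
  the data range ± 3 bandwidths; mode = grid argmax, maximum performance =
  empirical 95th percentile. Estimates require n ≥ 10 bouts ("larger than
  10" in one phrasing, "minimum of 10" in another; n ≥ 10 implements the
  footnote). Identical values short-circuit to a degenerate density.
* **States and entropy:** 25 states = {locomotion, non-locomotion} ×
  {very short < 10 s, short 10–30 s, medium 30–60 s, long > 60 s} ×
  {low, medium, high intensity} + rest. Intensity uses cadence bins
  < 60 / 60–90 / > 90 steps/min for locomotion and acc-norm SD bins
  (0.02, 0.10 g) for non-locomotion. The exact partition of the original
  taxonomy is published only in prior work, so this is a documented
  reconstruction of the stated factor structure; all bin edges are
  configurable. Non-bout wear time is epoched at 5 s, epochs are
  active/rest by the same SD criterion, and adjacent same-kind epochs merge
  into episodes. Hn = −Σ pᵢ ln pᵢ / ln 25 on the time-weighted state
  distribution (0·ln 0 := 0), computed per day and aggregated by the
  subject median (matching the macro aggregation rule).

## Group statistics

Per feature: Shapiro–Wilk on within-group residuals and Levene's test
(mean-centred) at α = 0.05 select ANOVA (both pass) or Kruskal–Wallis;
groups under 3 observations skip the feature with a log entry, constant
features are flagged degenerate. Effect sizes: η² = SS_between/SS_total
for ANOVA and the rank analogue η²_H = (H − k + 1)/(n − k), floored at 0,
for Kruskal–Wallis (the standard choice when none is prescribed).
Benjamini–Hochberg adjustment (statsmodels) is applied within each feature
family — clinical, IGA, PAM — mirroring per-table reporting; a global scope
is configurable. Features with adjusted p < 0.05 get pairwise post hoc
tests: Student t-tests after ANOVA, otherwise Dunn's rank z-tests
(tie-corrected, implemented here and cross-checked against an independent
brute-force evaluation), both uncorrected at α = 0.05 as stated for the
post hoc stage. Spearman correlations are computed per group with pairwise
deletion and at least 5 complete pairs per cell; strength categories use
the labels weak / moderate / strong / very strong (two label sets exist for
the same bins — small/good/excellent being the other — and the
results-style labels are used); boundary values fall in the lower category
per the "≤ 0.25" phrasing. Under a three-group null the raw omnibus p is
uniform (KS-tested) and the feature-wise false-positive rate after BH stays
below α.

**Synthetic cohorts for the statistics layer** draw features from the
preset medians with sd = IQR/1.349 and a shared latent severity factor per
subject (loading 0.6, signs from clinical expectation: worse severity →
slower gait, shorter strides, fewer steps, higher motor scores). The factor
gives the correlation grid realistic structure; it is a modelling choice,
not an estimate of the true cross-domain covariance. On such cohorts
(n = 30/group) the pipeline reproduces the expected gait-velocity pattern —
omnibus significant, PD ≠ MSA and PD ≠ PSP post hoc, MSA ≈ PSP — in ≥ 90%
of seeds.

## Problem sizes and reproducibility

Gait tests are simulated and analysed at the native 102.4 Hz. Week-scale
simulations in the tests, the analysis scripts and `scripts/acceptance.py`
run at 25.6 Hz with 3–4 recording days and the daily walking volume scaled
to ~8–12% of the preset medians (bout counts and step targets scaled
together); these sizes keep the full validation in the minutes range while
exercising every rule at realistic wear durations. All randomness flows
from a single seed through numpy seed sequences; `mobgait all` with a fixed
config and seed produces byte-identical reports, which the test suite
asserts.

## Known limitations

* Validated on model-generated signals only; the stride model is smooth and
  symmetric apart from the prescribed asymmetry ratios, so event-detection
  robustness to pathological morphologies (festination, freezing, shuffling)
  is untested.
* Non-wear detection is evaluated on the left-foot stream (both sensors are
  removed together in practice and in the generator).
* The yaw of the initial attitude is unobservable from one IMU, so absolute
  heading is arbitrary; only per-stride heading *changes* are used.
* Kruskal–Wallis η²_H and Dunn p-values use large-sample approximations;
  with very small groups (n < 5) they are indicative only.
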