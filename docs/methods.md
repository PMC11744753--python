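# Methods

`luxsleep` analyses the association between habitual daytime light
exposure, measured continuously at eye level, and the architecture of the
following night's sleep. This note describes the models and procedures the
package implements, the choices made where the design was genuinely open,
and what the synthetic-data generator does and does not emulate.

## Light-log cleaning and dosimetry

Wearable spectacle-mounted lux sensors report photopic illuminance at
1 Hz; the reliable range of such devices is 1–40,000 lx. Cleaning assigns
each raw reading a status:

* negative readings → `artifact` (excluded from every statistic);
* readings in [0, 1) lx → clipped to 1 lx, `clipped_low`. A raw 0 is
  treated as a below-detection reading rather than an artifact, because a
  zero is a plausible sensor floor while a negative value is physically
  impossible;
* readings above 40,000 lx → clipped to 40,000 lx, `clipped_high`;
* absent seconds → `missing`.

Because the headline summaries are medians, clipping at either extreme has
negligible influence. The cleaned recording lives on the full one-sample-
per-second grid of the analysis window (default 07:00–19:00), and the
valid-data percentage uses the window length in seconds as its
denominator, so gaps count against the recording. Recordings below 50%
valid data trigger a prominent warning in the orchestrated run.

Summaries per window (the full day, three 4-h slots, six 2-h slots):
median, mean, 10th/90th percentiles (linear interpolation between order
statistics, fixed so independent oracles can match bit-for-bit), and the
percentage of valid samples *strictly below* 20, 80, 200 and 500 lx — a
sample exactly at a threshold counts as not below, and the map is
non-decreasing in the threshold by construction. Windows are half-open
`[start, end)` so the 2-h frames partition the day without double
counting. The time of maximal exposure partitions the day into 36
consecutive 20-min bins, takes the mean of usable samples per bin
(the bin statistic is not prescribed by convention; the mean makes the
statistic sensitive to brief bright episodes, which is what the quantity
is meant to capture), and reports the midpoint of the winning bin, ties
broken to the earliest bin. Cohort tables aggregate individual-first: the
group median and range of individual medians, and means ± SD of individual
means and individual below-threshold percentages.

## Sleep metrics

Hypnograms are 30-s epochs scored W/N1/N2/N3/R. Sleep onset is the first
N2 epoch that opens a four-epoch (2-min) run containing no wake; other
sleep stages may appear inside the run. The alternative reading
(2 cumulative minutes of N2) was rejected because it cannot honor the
"without wake" requirement. End of sleep is the end of the last non-wake
epoch; terminal wake is excluded from the sleep period. SPT = onset to end
of sleep; TST = SPT − wake within it; efficiency = 100·TST/SPT; REM
latency = onset to first REM epoch (undefined and flagged when no REM
follows onset); sleep latency is measured from lights-off (default 23:00,
configurable). Stage minutes and percentages are reported within SPT.
Epochs are indivisible, so every duration is a multiple of 0.5 min. All
arithmetic runs on a linear time axis anchored at the recording start, so
recordings crossing midnight need no special casing.

## Polarity

Each 30-s epoch of a stage inside the sleep period is a unit vector on the
24-h circle at its clock-time angle (24 h = 360°, so 1 h = 15°). The
resultant's angle, mapped back to clock time, is the stage's centroid; its
length is the polarity strength — high when the stage is abundant and
clustered, low when sparse or dispersed. Numerical choices: vectors are
anchored at epoch start times (a 15-s shift is negligible at 30-s
resolution); the centroid comes from the two-argument arctangent of the
summed sines and cosines; a resultant shorter than 1e-9 marks the centroid
undefined instead of returning an arbitrary angle. Strengths are reported
in raw units (epochs, or lx·bins for the illuminance analogue); the
divisors used to fit vectors onto a polar plot (200 for stages, 10,000 for
illuminance) are presentation-only. Illuminance polarity weights each
hourly bin's midpoint vector by that hour's median lux; hourly resolution
is the display convention, and the bin width is configurable. For
association analysis, centroid times are re-expressed as hours after sleep
onset on a linear axis.

A useful identity for checking implementations: a symmetric pair of unit
vectors subtending angle θ has resultant 2·cos(θ/2) at the midpoint time —
e.g. epochs 2 h apart give 2·cos(15°) ≈ 1.93, epochs 4 h apart give
2·cos(30°) = √3.

## DLMO

Evening saliva melatonin is modelled as a flat baseline followed by a
linear rise (the hockey-stick model): c(t) = b for t ≤ τ and
c(t) = b + s·(t − τ) afterwards. The breakpoint τ is searched on a 1-min
grid across the sampling interval; for each candidate, b and s have a
closed-form least-squares solution, and the global minimum is kept (ties
to the earlier τ; the grid scan makes the global-minimum property directly
assertable). DLMO is where the *fitted* curve crosses 10 pg/mL:
τ + (10 − b)/s. This reconciles a threshold definition with a fitted-model
method; the raw linear-interpolation crossing is also reported for
transparency. Flags instead of guesses: baseline already ≥ 10 pg/mL
(DLMO set to the first sample, flagged), fitted curve not reaching
threshold within one hour past the last sample (undefined, flagged), no
positive rise (error). Negative fitted baselines are clamped to zero with
a warning and the slope refitted. Cohort means/SDs are taken on a linear
evening axis (18:00 → 18:00 + 24 h) so times just past midnight average
correctly.

## Association inference

Spearman's rho is the product-moment correlation of average ranks. For
tie-free ranks at n ≤ 10 the p-value is exact: the full n! permutation
null of Σd² is enumerated once and cached, and p is the proportion of
permutations at least as extreme as observed (observed configuration
included). Larger n or tied data fall back to the t approximation
t = rho·√((n−2)/(1−rho²)) and are flagged.

Sidedness is a reconstruction, not a reported fact: back-calculating the
published adjusted p-values (0.049 ≈ 7 × one-sided p for rho = 0.817;
0.014 ≈ 7 × one-sided p for rho = −0.883) is most consistent with
one-sided exact p-values taken in the direction of the observed
coefficient, so that is the default, with `sided="two"` available. Note
that direction-of-observed one-sided testing doubles the effective
per-test level: with it, Holm at α controls the family-wise error at 2α,
not α. The family-wise control property itself is therefore verified
under two-sided p-values, where Holm's guarantee applies; the default
exists to mirror the published table, and this caveat is deliberate and
documented rather than hidden.

Holm's step-down correction multiplies the k-th smallest of m p-values by
(m − k + 1), enforces a running maximum, and caps at 1. The multiplicity
family is the seven light time frames within each outcome column
(m = 7), matching how the published analysis frames multiple comparisons;
correcting over all 56 cells at once is available as `holm_scope="table"`.
Cells are dropped pairwise on missing data, with n reported per cell and
n < 3 cells flagged out of the family. Significance is marked at adjusted
p ≤ 0.05. The correlations use frame *medians* of illuminance, not means:
brief bright bursts inflate a mean strongly and a median hardly at all,
and sustained rather than momentary exposure is the quantity of interest.

## Synthetic data

The generator reproduces the statistical structure the pipeline assumes,
not the physics or physiology beneath it.

**Light** (defaults, chosen once): log-normal indoor baseline with
per-sample log-SD 1.0 around 40 lx × an hourly envelope
(0.4, 1.0, 1.5, 1.25, 0.9, 1.1, 0.8, 0.625, 0.35, 0.25, 0.2, 0.15 for
07:00…18:00) peaking mid-morning with a small secondary noon peak; a
per-day log-normal scale factor (log-SD 0.2) for day-to-day variability;
an indoor ceiling of 450 lx; Poisson-timed outdoor bursts (0.5/h,
1–10 min, log-uniform 3,000–40,000 lx) overwriting the baseline; negative
artifacts at rate 0.08 and per-sample gaps at rate 0.05, together landing
near the ~87% valid fraction typical of such recordings. Under these
defaults the all-day median of a generated day falls around 25 lx, inside
the 12–37 lx band reported for urban winter wear. Because bursts are brief
and extreme, day means sit far above day medians — the motivation for
median-based dosimetry is reproducible as a demonstration.

**Sleep**: after a drawn sleep latency (wake, then two N1 epochs), five
~90-min cycles alternate NREM and REM, with N3 minutes weighted toward
early cycles (front-loading coefficient) and REM episodes lengthening
across the night (back-loading coefficient); stage budgets target
REM 23.1%, N3 24.2%, N1 4.3% of SPT. REM latency is drawn around its
target (default 71 ± 11.8 min) and planted exactly to epoch resolution:
the first REM block begins exactly that long after onset. Wake epochs are
sprinkled at rate 0.066 through the sleep period, sparing the four onset
epochs, the latency-defining first REM epoch and the final epoch, so every
generated hypnogram has a valid onset and its planted latency survives
measurement.

**Melatonin**: hockey-stick-shaped series (baseline 2 pg/mL, rise
16 pg/mL/h) on the half-hourly 20:00–23:00 grid with Gaussian noise; the
noiseless threshold crossing sits exactly at the requested onset time.

**Cohorts**: a Gaussian copula plants a rank correlation between one
frame's median lux and REM latency. The latent correlation is
r = 2·sin(π·ρ/6), the classical monotone map whose population Spearman
coefficient equals the target, giving a closed-form check for recovery
tests. Two construction details make planting rank-exact: inside the
planted frame the day-level scale factor is replaced by the planted
multiplier exp(0.6·z), and the planted frame stays burst-free, so its
measured median is a strictly monotone image of the latent draw. At
ρ = 1 the copula degenerates (z₂ = z₁) and the target cell recovers
rho = 1 exactly, up to occasional ties from the 0.5-min quantization of
REM latency.

What the generator does *not* emulate: spectral composition or melanopic
quantities, weather and sunrise/sunset structure, ultradian EEG
microstructure, arousals, correlated sensor dropout, or any dependence
between light and sleep beyond the single planted cell. Passing tests
therefore demonstrate the correctness and calibration of the pipeline's
statistics under the assumed structure, not that the physiological
associations would be detected in new real-world data.

## Problem sizes

Simulation-based tests use the scales at which their claims are sharp
while staying desk-sized: 500 random hypnograms against the trigonometric
polarity oracle, 500 seeds for noisy breakpoint recovery, 1,000 random
p-vectors against the step-down oracle, and 1,000 synthetic cohorts each
for planted-correlation recovery (ρ = 0.8, n = 9) and for the null
family-wise error measurement.

## Known limitations

* The exact permutation null is enumerated, capping exact inference at
  n = 10; beyond that the flagged t approximation is used.
* Sleep-stage transition structure is schematic (block-wise cycles), so
  metrics sensitive to transition counts would not be meaningful on
  synthetic hypnograms.
* The one-sided default mirrors the published analysis but, being
  direction-of-observed, doubles the per-test level (see above).
* Clock handling is naive local time; the emulated single-site winter
  protocol has no DST transition, and time zones are out of scope.
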