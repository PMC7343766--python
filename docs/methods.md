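# Methods

This note documents the models, parameters and numerical choices behind
`crowdgaze`, and what the synthetic-data tests do and do not establish
about real recordings.

## The measurement model

A wearable eye tracker samples binocular gaze direction at a nominal
50 Hz. Each sample carries azimuth and elevation in Fick coordinates
(degrees) per eye, relative to the scene-camera center, plus a button
voltage. A gaze coordinate is a pair: if either component of an eye is
missing, that eye has no coordinate for the sample. Timestamps are
seconds; all intervals are half-open `[onset, offset)`; a run of *n*
samples lasts *n*·Δt with Δt the nominal sample interval (so a 4-sample
run at 50 Hz is exactly 80 ms, making the 80-ms fixation floor
attainable).

## Data quality

**Precision.** For each of the four signals (left/right × azimuth/
elevation) a 300-ms window slides one sample at a time; within a window
the RMS of the differences of adjacent valid sample pairs is computed,
and the median over window positions is reported. The median makes the
estimate robust to the high velocities of fast phases, which is the point
of the statistic; on iid Gaussian noise it sits ≈ 3–4 % below the
full-signal RMS (which equals σ√2) because each 14-difference window has
few effective degrees of freedom. Windows with fewer than two valid pairs
are skipped; an all-missing signal reports NaN, never 0.

**Data loss** is the percentage of samples for which an eye lacks a
coordinate.

**Validation geometry.** The full angular subtense of an object of size
*s* at distance *d* is 2·arctan(s/2d); the cyclopean-eye distance to a
wall marker is √(horizontal² + (eye height − marker height)²). With the
package's worked numbers (65 cm to the wall, eyes at 170 cm, marker at
155 cm; 0.9-cm dot, 4.5-cm ring) these give 66.71 cm and 0.77°/3.86°.

## Fixation classification

Gaze speed per sample is the average of the backward and forward
one-sided speeds (displacement to the neighboring sample divided by the
time difference; Euclidean in azimuth/elevation degrees, with a
great-circle option). Boundary samples and samples with one missing
neighbor use the single available side; samples with no usable neighbor
are undefined. The classified position signal defaults to the mean of the
two eyes where both are valid (`eye_mode` selects a single eye instead).

The adaptive threshold of a window of speeds is found by iterative
trimming: repeatedly remove speeds above mean + 2.5 SD until the
surviving set no longer changes or 200 iterations have run, then set the
threshold at mean + 3 SD of the survivors. Convergence is defined as an
unchanged survivor set, which avoids a tolerance constant; the SD is the
sample (n−1) form, exposed as a parameter. Windows in which fewer than
two speeds survive are skipped with a warning.

In **windowed** mode an 8-s window slides one sample at a time and each
sample's threshold is the average over all windows that contained it, so
the threshold tracks slow changes in overall gaze velocity (walking,
turning); in **global** mode one threshold from the whole recording
applies everywhere. A recording shorter than the window degrades to
global mode with a warning — the two modes coincide exactly in that case.
Samples strictly below the local threshold are potential fixation
samples ("strictly" means a zero-variance window classifies nothing; a
warning is emitted). Maximal runs of at least 80 ms become fixations with
onset, offset, duration and mean direction.

**Attainable boundary accuracy.** On white Gaussian position noise the
trimmed threshold converges to ≈ the 98.4th percentile of the noise
velocity distribution *independently of the noise scale* (the whole
procedure is scale-equivariant). Roughly 1.5 % of within-fixation samples
therefore exceed the threshold at any signal-to-noise ratio, and each
fixation boundary is recovered to within ±1 sample with ≈ 94–95 %
probability: the sample at the boundary itself always averages one ramp
side and is excluded, and an exceedance within the first or last 80-ms
fragment displaces or deletes the boundary. This is a property of the
method, not of the implementation; the windowed/global comparison and the
recovery rates in `scripts/acceptance.py` quantify it.

## AOI coding and agreement

Each fixation gets exactly one of eight labels: objects, walls, group at
a distance, walker body/head, obstructor body/head, or the non-AOI
fallback. Agreement between two coders is unweighted Cohen's kappa with
chance agreement from the marginal label frequencies; two constant,
identical codings are defined as kappa 1 with a warning. Because coders
mainly confuse obstructors with walkers, the merge head_obstructor →
head_walker and body_obstructor → body_walker (idempotent) is provided
and raises kappa whenever disagreement is confined to those pairs. The
consensus over exactly three coders takes the majority label and falls
back to an explicit tie-break coder for three-way disagreements; the
tie-break rate is reported. A sensitivity analysis can rerun all
downstream measures on each individual coder's labels.

## Crowd measures

Fixations enter the measures only if they begin after and end before the
round boundaries of *both* video coders, implemented as the intersection
window (latest start, earliest end). Per AOI, the number of fixations,
the median duration (midpoint of the central pair for even counts) and
the total duration are reported; empty AOIs report count 0 and a missing
median, so counts and totals always sum to the qualifying-fixation
totals. Round duration is the span from the first to the last qualifying
fixation.

Two distinct visibility windows coexist and are never conflated: the
people-viewing bounds use *group-in-view → last-person-out*, while the
group-size analysis uses *first-person-out → last-person-out* (walking
"in" a group). The lower bound divides the total people-directed fixation
time (group + body + head AOIs) by the in-view time; the upper bound
divides by the in-view time scaled by the proportion of the recording
that contains fixations at all (fast phases and loss cannot look at
anyone). That proportion is computed per recording by default; a per-round
variant is a parameter, since either reading is defensible. The
group-size normalization is n/((g−1)·encounters): the first person of a
group is already out of view once the observer is "in" it. Task
performance across rounds uses ICC(A,1), the two-way absolute-agreement
single-measure intraclass correlation computed from the ANOVA mean
squares; zero total variance is defined as 1 with a warning. Round
differences are round 2 − round 1 per observer × AOI. Direction
statistics pool all valid samples inside fixations per eye; histogram
bins clip extreme values into the outer bins so counts conserve samples.

## Synthetic data

The generator emulates the study scenario: two rounds (drawn uniformly
from 95–125 s unless fixed) separated by an instruction gap, three groups
of 6, 12 and 20 walkers each encountered twice per round, ~30 % watchers
and ~17.5 % obstructors per group, and 24–46 button presses in the
dual-task round carried on a 3.3-V pulse channel.

The gaze signal alternates fixations and fast phases on the sample grid.
Fixation durations are log-uniform over 160–800 ms; each fixation holds a
center plus linear drift (default 0.5 °/s — eyes are rarely still with
respect to the head while walking); fast phases are linear ramps of 40 ms
whose amplitudes are drawn from U(2°, 20°), with the landing direction
redrawn until it stays inside a ±35° × (−30°, 8°) gaze box so the drawn
amplitude is always honored. Both eyes share the true signal and receive
independent white Gaussian noise (default SD 0.5°, chosen so the
sample-to-sample RMS lands near 0.7°, the wearable regime); data loss is
injected as blink-like 200-ms bursts per eye totalling a configurable
fraction (default 8.5 %). True AOI labels are drawn per fixation from
round-dependent tables; inside group encounters heads and bodies
dominate, and the dual-task round shifts probability mass from bodies to
heads — the scripted task effect that the round-difference analysis must
recover in sign. Coder simulations draw labels from a row-stochastic
confusion matrix (identity, uniform, and obstructor↔walker mixtures are
provided); video-coder timelines are the truth plus Gaussian jitter with
ordering enforced by redraw.

Everything is driven by one `numpy` Generator seeded from a single
integer: identical (scenario, noise, seed) triples give bit-identical
outputs.

**What the generator does not model:** vergence (both eyes share one true
direction), smooth pursuit and VOR beyond linear drift, head-on-torso
kinematics, pedestrian trajectories, saccade main-sequence dynamics
(ramps, not velocity profiles), and non-white tracker noise. Passing
tests therefore demonstrate the pipeline's correctness and its behavior
under a controlled oculomotor model, not classifier performance on real
walking data, where slow-phase velocities and noise spectra are richer.

## Problem sizes and benchmarks

The test suite and acceptance script use ~2-min single-round recordings
(≈ 5,700 samples) for classifier benchmarks — matching the study's round
length — and the full two-round scenario (≈ 14,000 samples) for
end-to-end checks; the recovery benchmark pools three seeded recordings.
The two-regime stress signal (60 s at noise SD 0.05°/saccades 2.5°
followed by 60 s at SD 0.6°/saccades 15°) reproduces the failure mode
that motivates the windowed threshold: a single global threshold,
inflated by the noisy half, misses the small fast phases of the quiet
half (recovery drops to ≈ 50 %), while the windowed threshold adapts
(≈ 94 %).

## Cross-checks

Cohen's kappa is verified against scikit-learn's `cohen_kappa_score` and
ICC(A,1) against pingouin's `intraclass_corr` (exact agreement); the
iterative trim loop is verified against an independent naive reference on
1,000 random vectors, including a hand-worked case. These libraries serve
only as test oracles; the package's own implementations are used
throughout the pipeline.
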