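# Methods

## Problem and measurement model

Motor fluctuation in advanced Parkinson's disease — alternation between
medicated "on" periods and symptomatic "off" periods — is usually assessed
from patient diaries, which are subjective. Gait offers an objective
window: parkinsonian off states show up either as *bradykinetic* gait
(cadence below normal, weak push-off) or as *short-stepping / festinating /
freezing* gait (cadence above normal, again with weak push-off). A single
waist-worn tri-axial accelerometer sampling at 100 Hz (10 ms) captures
both: each step imprints a stereotyped pulse on the acceleration-magnitude
signal a = √(ax² + ay² + az²), whose timing gives cadence (steps/min) and
whose height tracks the floor-reaction force.

The package implements the full chain: step detection by template pattern
matching, hourly aggregation, rule-based off/good classification against
control-derived cut-offs, and concordance analysis between objective
gait-off hours and hourly symptom diaries — plus a synthetic-recording
generator that makes the whole chain testable against known ground truth.

## Step detection

**Template extraction.** The magnitude signal is band-passed (Butterworth
order 2, 0.5–5 Hz — wide enough to bracket bradykinetic and festinating
cadences on both sides of the normal band), peaks at least one refractory
interval (0.25 s) apart are picked, filter-ripple micro-peaks are dropped
by a relative prominence floor (25% of the 95th-percentile prominence),
and the contiguous run of up to 30 peaks with the most regular inter-peak
intervals (lowest CV) is selected. The template is the average of raw
magnitude windows (0.6 s) centred on those peaks. A trace whose best run
is still irregular (interval CV > 0.15) or has fewer than 8 usable peaks
raises a no-template error; callers fall back to a canonical synthetic
step pulse centred in the same 0.6 s window. The long window matters: with
a 60-sample template, noise-only stretches essentially never reach the
acceptance correlation, whereas a bare 0.3 s pulse template admits tens of
spurious events per hour.

**Matching.** A sliding Pearson correlation of the magnitude signal
against the template (computed with overlap-add convolution plus rolling
sums) is thresholded at `min_correlation` = 0.6; local maxima are accepted
greedily, highest correlation first, with a 0.25 s refractory spacing
(240 steps/min ceiling). One accepted match is one step, so cadence is
60 / mean inter-event interval; a normal cadence of 110 steps/min implies
~0.545 s peak spacing. Correlation threshold, refractory, band and window
length are free design parameters, exposed in the configuration.

**Amplitude readout.** Each event's amplitude is the magnitude at the
matched wave's peak sample, corrected for the sensor noise floor:
perpendicular noise components add in quadrature at the pulse peak, so the
raw peak over-reads small steps (≈ σ²/A, up to ~6% at A ≈ 1 m/s² under the
default noise). The correction is √(peak² − 2σ̂²), with the per-axis noise
SD σ̂ estimated from the MAD of samples outside every matched window
(noise-only magnitude follows a chi distribution with 3 df, MAD 0.4602·σ).
On a noiseless trace the gaps are exactly zero, σ̂ = 0, and all exactness
properties are preserved. Two alternatives were rejected: the maximum over
the whole matched window carries an extreme-value bias of ≈ +0.2 m/s² at
the default noise, and a template-regression readout is contaminated by
neighbouring pulses once step spacing drops below the window length.

## Hourly profiles

Events are binned by clock hour (boundaries at minute 0). An hour with
fewer than 20 steps is invalid and excluded from every downstream
statistic. Valid hours report cadence = 60 / mean step interval — both
endpoints inside the hour, gaps > 2 s discarded as walking-bout
boundaries — and acceleration = mean event amplitude. Cadence is therefore
a rhythm, not an activity count: ten minutes of walking in an hour reads
at the true cadence. The day-level acceleration CV is the population SD
over mean of the valid hourly accelerations (sample convention
switchable); it is invariant under any uniform sensor-gain change.

## Control norms and cut-offs

Per control subject: mean cadence, mean acceleration and acceleration CV
over valid hours; the norms are the inter-subject mean and sample SD
(n−1) of those subject-level values. Cut-offs follow fixed formulas:
cadence band = mean ± 1 SD, off acceleration = mean − 2 SD, CV ceiling =
mean + 1 SD. The packaged reference norms (17 controls: 110 ± 12
steps/min, 2.78 ± 0.42 m/s², CV 0.20 ± 0.04) reproduce the published
thresholds <98 / >122 steps/min, <1.94 m/s², <0.24 regardless of the SD
convention, because they are stored as the printed values. All comparisons
are strict: a value exactly at a cut-off is neither off nor good.

## Hour labels and patient classification

The decision regions partition the (cadence, acceleration) plane of each
valid hour:

| cadence | acceleration | label |
|---|---|---|
| < 98 | < 1.94 | bradykinetic off |
| > 122 | < 1.94 | short-stepping off |
| > 122 | ≥ 1.94 | activity-related (excluded from off) |
| < 98 | ≥ 1.94 | unconfirmed deviation |
| 98–122 | any | normal |

Patients: any off hour → *definite gait off* (a single hour suffices — the
reference cohort contains single-hour gait-off patients); no off hour but
an unconfirmed deviation → *reserved (probable off)*; cadence never
leaving the band → *definite gait good* if the acceleration CV is below
0.24, else *reserved (probable good)*. Reserved patients are excluded from
diary concordance. Two interpretive choices are deliberate: hours where
only the cadence deviates (no corroborating acceleration drop) reserve the
patient rather than count as off, and activity-related hours do not block
a gait-good call, since activity-driven increases are excluded before any
off/good decision is made.

## Diary concordance

Diary states are good / not good / bad per hour; subjective off = not-good
∪ bad (using bad alone breaks reproduction of the reference table for
patients whose listed subjective hours span not-good periods). A patient
is *synchronized* when at least one exact clock hour is in both the
gait-off and subjective-off sets (a ±k-hour tolerance is available but off
by default — exact sharing reproduces all 44 reference outcomes),
*both good* when both sets are empty, *desynchronized* otherwise.

The packaged reference cohort transcribes a published 44-patient
comparison verbatim, with a normalisation layer for hour tokens: 4-digit
clock style ("0800" → 8), "2400" wraps to hour 0 of the same recording
day, bare integers are hours of day, and one 5-digit token ("01500") is
treated as a typo for 1500 — required for that row's printed match at
hour 15. One row's printed matched-hour list omits members of the true
set intersection; the transcription keeps the printed text and comparisons
use the concordance category only.

## Synthetic recordings

The generator emulates the statistical structure the classifier assumes,
not biomechanics. Each planted walking hour places one pulse per step —
half-sine shaped by an exponential decay, peak exactly the planted
amplitude — at intervals 60/cadence with 3% multiplicative jitter,
rescaled so a planted hour contains exactly round(cadence × minutes)
steps. The pulse energy is distributed over the axes by a fixed unit
direction (the analysis only sees the magnitude, so the direction is
free); per-axis Gaussian noise (default SD 0.2 m/s²) and Poisson
white-noise artifact bursts (default 5/hour, 0.1–0.4 s) are superimposed.
Hour types follow the classifier's geometry — bradykinetic off (low
cadence, low amplitude), short-stepping off (high cadence, low amplitude),
activity (high cadence, high amplitude), normal, rest — and plan
validation rejects any planted hour whose label contradicts its region,
so label recovery is well-posed. Everything derives from an integer seed
via a spawning seed sequence; identical seeds give byte-identical traces.

Cohorts: controls draw subject-level cadence from N(110, 12) and
acceleration from N(2.78, 0.42) (truncated positive), with hour-to-hour
scatter (cadence SD 3 steps/min; amplitude CV 0.20, matching the
reference control CV — the within-subject variability is a free parameter,
as no reference value exists for it). Patients walk in-band with margin
(cadence clipped to 103–117, tight 3% amplitude scatter) except in planted
off hours (bradykinetic 75–90 steps/min, short-stepping 128–145, amplitude
1.0–1.5 m/s²) and occasional activity hours (126–140, 3.2–4.0 m/s²); the
margins keep every planted hour at least ~2 units inside its decision
region so that detection error cannot flip a label. Diaries follow the
planted truth through an awareness probability: each true off hour is
reported (as bad or not good) with probability p, so full awareness,
complete unawareness, and intermediate desynchronisation scenarios can be
planted directly.

What the generator does *not* model — gravity and posture in the axis
signals, gait-phase substructure, dyskinesia, within-hour on/off
transitions, non-stationary noise — bounds what the passing tests show:
they validate the detection/classification chain under the stated
statistical assumptions, not device performance on real patients.

## Numerical and procedural choices

- Magnitude is computed in fixed ax² + ay² + az² order (bit-reproducible
  against a per-sample oracle); non-finite samples fail with the index.
- Correlation lags at the trace boundaries are eligible peaks (the trace
  is padded below threshold), so a trace equal to the template yields its
  single perfect match.
- Hours with ≥ 20 events but no usable interval (all gaps) are treated as
  invalid rather than given an undefined cadence.
- Problem sizes in tests and the acceptance script: the classifier
  recovery runs 20 subjects × 24 h at 100 Hz (8.64 M samples each, ~6 s
  per subject end to end); unit tests use 1–8 hour plans. The analysis
  drivers use an 8-patient + 5-control day with awareness 0.6 as a worked
  cohort.
- The CLI (`gaitrhythm simulate|detect|profile|norms|classify|sync|
  reproduce-cohort|run`) is a thin wrapper; every computation lives in the
  library so tests and scripts import it directly.

## Known limitations

- Cut-off rules operate on hourly means; sub-hour freezing episodes are
  invisible by construction.
- The activity exclusion is purely geometric (high cadence + non-low
  acceleration); diaries are not consulted for it.
- Noise-floor estimation assumes stationary sensor noise across the
  recording and needs ≥ 10 s of pulse-free signal.
- Control norms assume age/height-matched controls; no covariate
  adjustment is computed.
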