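# Methods

## Scope and data model

The package analyses one overground walkway pass at a time. Axis
convention: anterior = +x in metres from the 0 m walkway line,
medio-lateral = +y leftward, vertical = +z; the time origin is the first
trajectory sample and all event times are in seconds. Step metrics are
reported in centimetres, walking speed in m/s, cadence in steps/min.
Trajectories are sampled at 30 Hz (markerless capture), EMG at 1000 Hz;
both share the trial's time origin so gait events index either stream.

## Synthetic gait generator

The generator emulates the statistical structure the analysis assumes, not
musculoskeletal reality. A profile fixes walking speed `v`, mean step
length `L`, right-minus-left step-length asymmetry, mean step width,
cadence `C`, and stance fraction `SF`; the profile is rejected unless
`v ≈ (L/100)·(C/60)` within 5%, and unless `SF` leaves at least 2% of the
cycle in double support. Stride time is `T = 120/C` and stride length
`S = v·T`.

**Kinematics.** The spine base advances at `v` with a smooth within-stride
speed modulation (0.5 cm sinusoid, period `T/2`, random phase). Each
ankle's AP position is built piecewise per stride against a linear spine
so that the relative-AP signal has *exactly* one maximum at foot contact
and one minimum at foot off, and so that the ankle is *exactly* stationary
at its footfall position throughout the single-support window (cubic
Hermite blends connect the segments with matched slopes; the swing segment
is a monotone Hermite to the next footfall). The shared spine modulation
is added to both spine and ankles and therefore cancels in the relative
signal. These two exactness properties are what make the generator an
oracle for the event detector and the step-location estimator.

**Asymmetry.** Right-minus-left step-length asymmetry is realized by
offsetting the contralateral contact phase from 0.5 stride (left contact
earlier lengthens the right step). Both sides then share one waveform
shape, so the recovered asymmetry equals the requested value by
construction; an amplitude-based scheme would have biased the per-side
medians differently.

**Noise.** Isotropic Gaussian noise (default 0.3 cm SD, configurable) is
added to every coordinate of all three body points. The noise spectrum of
real markerless capture is not modelled; the default is a plausible
magnitude, not a claim about sensor accuracy.

**EMG.** Each channel is a sum of raised-cosine activation bursts at fixed
gait-cycle phases, multiplied by a zero-mean Gaussian broadband carrier,
plus powerline interference at 50·k Hz (k = 1..5, amplitude ∝ 1/k, one
common random phase per trial) and additive white noise. The noiseless
burst envelope is retained per channel as ground truth. Default burst
timings loosely follow normal-gait activation phases for the seven
recorded muscles (TA, GAM, SOL, PL, RF, VL, ST, bilateral).

**Determinism.** All randomness flows from the profile seed through
per-operation `numpy` generator streams, so identical profiles give
bit-identical trials.

**What passing tests do not show.** The generator produces steady-state,
strictly periodic gait with stance-stationary ankles and phase-locked
EMG. Real pathological gait has stride-to-stride variability, drifting
speed, occasional missteps, soft-tissue and tracking artefacts, and EMG
whose timing varies across strides; recovery rates measured here are
upper bounds on what the same settings achieve on such data.

## Gait-event detection

The relative AP signal (ankle minus spine base) is low-pass filtered at
6 Hz (zero-lag, 2nd-order Butterworth applied forward-backward) before the
extremum search: the stride fundamental is ≤ ~1.1 Hz, so 6 Hz keeps the
shape-defining harmonics while attenuating frame noise. Extrema must have
≥ 5 cm prominence and be ≥ 60/(2·180) s apart (a 180 steps/min cadence
ceiling); both thresholds are configurable. Flat extrema resolve to the
earlier sample; peak times are refined by parabolic interpolation (bounded
to ±half a frame). Extrema within half a median stride of either recording
boundary are discarded as incomplete, and exactly one foot off is kept
between consecutive contacts (the deepest minimum when several survive
screening). Fewer than two surviving contacts on a side raises an
"insufficient strides" error. Detection is invariant to constant AP
offsets because only the relative signal is used.

Single-support intervals of a side run from contralateral foot off to the
next contralateral foot contact and must lie inside a stance of that side;
partial intervals at the trial edges are dropped, and ordering violations
raise with the offending times.

## Spatiotemporal parameters

Step locations are component-wise medians of the supporting ankle's AP/ML
position over each single-support interval — the median makes a single
tracking glitch inside the window irrelevant. Step length is signed
(backward steps are kept and flagged, not clamped, because pathological
gait may step short); step width is the absolute ML difference.
Consecutive same-side locations (a missed contralateral step) skip that
pair with a log entry. Cadence pools contacts of both feet. Walking speed
uses the spine base as the crossing point of the 2 m and 8 m lines with
linear interpolation between frames. A step belongs to the measurement
window when its *later* location's AP position lies in [2 m, 8 m),
half-open so a step exactly at the 8 m line is not double-counted;
cadence is evaluated between the two line-crossing times. Adding samples
outside the window therefore cannot change the summary.

## EMG pipeline

Filter chain, in order: high-pass 20 Hz, band-stop notches of 2 Hz full
width at 50/100/150/200/250 Hz, rectification as `|hilbert(x)|`, low-pass
5 Hz. "4th-order bidirectional Butterworth" is realized as an order-2
design applied forward-backward (net 4th-order, zero phase), the usual
movement-science convention; the notch bandwidth is a package choice since
only the centre frequencies are standard. Forward-backward filtering uses
Gustafsson's initial-condition method, which makes filtering exactly
time-reversal symmetric (the impulse-response length is capped at 3000
samples on long records for speed). Small negative envelope excursions
from filter ringing are clamped to zero and logged.

Strides (ipsilateral contact to next contact) are resampled to a fixed
101-point 0–100% cycle grid. Artefact screening replaces the visual
inspection used with human recordings by three automated rules: flatline
(variance < 1e-12), stride-RMS outlier (robust z via median and scaled
MAD > 4 — a plain mean/SD z-score cannot flag a single extreme stride
among few strides), and clipping (≥ 5 consecutive samples at ≥ 99% of a
declared ADC range; inactive when no range is declared). A user-supplied
manual exclusion list is honoured regardless. Excluding every stride is an
error, not an empty result.

Peak normalization divides a muscle's retained strides by that muscle's
maximum over the whole assessment (not per stride), so the normalized
matrix is in [0, 1] with maximum exactly 1; an all-zero channel raises
"silent channel".

The stimulated/non-stimulated ratio averages the stride-averaged
normalized envelope over the grid points inside the stimulation window(s)
(closed intervals in cycle fractions; wrapped windows arrive as two
intervals from the scheduler) and divides by the mean outside. The
denominator is guarded at ε = 1e-6 normalized units and the output flags
when the guard fired. Ratio changes across assessments are signed
differences versus baseline; a missing assessment produces a gap, not an
error.

## Stimulation sequencing

Channel specs store onset and duration in milliseconds after ipsilateral
initial contact (50 Hz, pulse width 1–320 µs). The default schedule tiles
the nominal cycle: stance = [0, SF] for the gastrocnemius, then the swing
phase split at 40% and 75% for tibialis anterior, quadriceps, and
hamstrings + gluteii respectively — the paper-level description is
qualitative, so the split fractions are package defaults and
configurable. Timelines restart at each ipsilateral contact: a window
starts at `contact + onset` and ends at
`min(start + duration, next_contact + onset)`, i.e. the restarted
sequence takes over once it reaches that channel's onset; windows pending
after the last contact run to completion. Per stride, a channel's on-time
therefore never exceeds `min(duration, stride time)`. Pulse-level 50 Hz
waveforms are not synthesized — no pulse shape is specified, and the
analysis needs only on/off envelopes.

Pulse-width calibration takes a non-decreasing recruitment curve on
[1, 320] µs and returns the smallest width reaching the motor threshold
and the largest width whose response stays at or below the maximum
tolerated level (evaluated on the integer-microsecond grid the device
uses); an unreachable threshold raises "muscle not stimulable".

## Feasibility analytics

Adherence is attended/planned × 100 over all participants; missed-session
statistics use the sample SD (n−1), reported as not available for a single
participant. Sessions with unresolved technical issues are reclassified as
missed by default (configurable), mirroring how such sessions are counted
in practice. Issue counts are per category (zipper, IMU, connection) with
a resolution breakdown; the total is their sum by construction.
Questionnaire items are validated against declared ordinal scales
(satisfaction 0–10; training frequency 1–4; duration, comfort,
donning/doffing, helpfulness 1–5) and summarized as medians. The
walked-distance series is the percent difference versus the first session;
missed or < 30 min sessions are linearly interpolated over session index
and flagged, never altering recorded values.

## Problem sizes and numerical choices

Recovery statistics use 50 seeded trials spanning 0.2–1.2 m/s and 40–130
steps/min (cadence narrowed per draw so the implied step length stays in
a plausible 15–90 cm), each a full 10 m pass at 0.5 cm trajectory noise —
enough trials that the contact-recovery fraction and parameter biases are
stable to well under their tolerances while the whole suite runs in
seconds. Filter measurements use 10 s probe sinusoids with 1 s edge trims.
Reports are JSON with sorted keys and a schema version, so repeated runs
on the same inputs are bit-identical.

## Known limitations

* The event detector assumes the extremum rule holds; gait with strongly
  reduced relative-AP excursion (< 5 cm prominence) falls below the
  default screening threshold.
* Cycle windows for the ratio statistic come from the *nominal* schedule,
  not from recorded stimulation output; any mismatch between intended and
  delivered stimulation is invisible to the analysis.
* Artefact screening is statistical; it cannot recognize physiologically
  implausible but numerically unremarkable segments the way a trained
  observer can.
* No statistical hypothesis testing is provided: with a handful of
  participants the intended use is descriptive per-participant comparison
  across assessments.
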