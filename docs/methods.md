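# Methods

`runkin` implements two complementary routes to stance-phase kinetics from
wearable sensors worn during outdoor running, plus the simulator used to
exercise and validate them end to end.

## Sensor model and conditioning pipeline

A session consists of three 6-axis IMU streams at 200 Hz (dorsum of each
foot and the sacrum; gravity-aligned axes, vertical acceleration gravity
compensated), per-foot insole normal force at 100 Hz (a proxy for vertical
GRF), and 1 Hz GPS speed and elevation. Conditioning follows the standard
field protocol:

* IMU streams are decimated to 100 Hz (anti-alias guard low-pass at
  0.45 x target Nyquist, then every 2nd sample) and filtered with a
  4th-order zero-lag Butterworth at 35 Hz. "4th order zero-lag" means the
  design order is 4 and the filter is applied forward-backward, so the
  effective attenuation order is 8 with exactly zero phase.
* Force is normalized to body weight (mass x 9.81 m/s²), filtered
  (4th-order zero-lag, 20 Hz), optionally baseline-corrected, and samples
  below 5 % BW are set to exactly 0 BW. The 5 % BW threshold defines foot
  contact throughout the package.
* Baseline correction targets insoles that shift inside the shoe and
  acquire a slow positive offset: swing segments (runs ≥ 0.05 s below 25 %
  of the ~1-s local peak) contribute their medians as knots of a
  piecewise-linear baseline, which is subtracted everywhere and the result
  clipped at 0. Interpolating between swing medians (rather than
  subtracting blockwise per cycle) tracks a slowly varying drift with no
  discontinuities at cycle boundaries.
* IMU and insole clocks disagree by an offset and a slow drift. The clock
  map is affine, t_force = offset + (1 + drift) · t_imu, estimated from the
  two event lists: coarse alignment by the median time difference first
  (events repeat every ~0.35 s, so naive nearest-neighbour matching is
  ambiguous for offsets beyond a quarter cycle), then iterated greedy
  nearest matching within 0.25 s and least-squares refitting until the
  median residual is below half a force sample period (5 ms).
* GPS speed and elevation are smoothed with a centered zero-lag 10-sample
  moving average (reflected edges); grade is arctan(Δelevation/Δdistance)
  with distance integrated from speed. Footfalls are stratified by speed
  bins at the nearest 0.25 m/s in [2.25, 5.25] (below 2.125 m/s is walking,
  above 5.375 m/s is out of range; midpoints round up, except 5.375 which
  can only map to the top bin) and by grade class: incline above +5°,
  decline below −5°, level otherwise (boundaries inclusive to level, since
  field grade noise is about ±4°).

## Gait-event detection

**Force events.** A contact is a contiguous run of samples at or above
5 % BW; IC is the run's first sample and TO its last supra-threshold
sample. (Reading TO as "the last instance below 5 % BW" literally would
place it at the end of swing; the run boundary is the evident intent.)

**Foot-IMU heuristic.** IC candidates are local minima of the sagittal
(x-axis, signed) angular velocity with prominence ≥ 0.5 rad/s and at least
0.500 s separation (the deeper of two conflicting minima wins). Each
candidate is confirmed by a resultant acceleration above 50 m/s² within
0.005–0.045 s after the minimum; IC is the time of the window's resultant
peak, and unconfirmed candidates are dropped. TO is searched from
IC + 0.010 s to half the stride time (estimated from adjacent gyro minima),
clamped before the next IC: the first instant vertical acceleration exceeds
3 g (29.43 m/s², gravity-compensated) wins; otherwise the window's
vertical-acceleration maximum is used. The threshold rule is tried first
because a crossing, when present, marks the push-off onset more sharply
than the maximum.

**Matching.** Estimated contacts are matched to measured ones greedily by
nearest IC time, one-to-one; a pair is kept only if the IC discrepancy is
at most half the measured contact time. Removals are reported on both
sides, so |matched| + |removed| equals each input size.

## Kinetic variables

All computed per stance (IC to TO) on BW-normalized force: stance average
(trapezoidal integral / duration), peak (maximum sample), impulse
(trapezoidal integral, BW·s), and average loading rate — the least-squares
force/time slope over the middle 60 % of the interval from IC to the impact
peak. The impact peak is the first local maximum with prominence ≥ 0.05 BW
in the first 40 % of stance; waveforms without an early transient fall back
to the sample at 13 % of contact time, flagged. A regression slope is used
rather than an endpoint difference because at 100 Hz the middle-60 % span
contains only a handful of samples and endpoint noise dominates; when the
span holds fewer than 3 samples, the two samples nearest the span decide
the slope. Stride frequency is 60 / median(inter-IC interval) per foot,
averaged over feet.

## GRF estimation with a bidirectional LSTM

Inputs are 1-s windows (100 samples) of 24 channels: per location, the
three accelerations, their Euclidean resultant, the three angular
velocities, and their resultant. The target is the summed both-feet insole
force in BW. The network is a bidirectional LSTM with 19 hidden units per
direction (standard gate activations), a per-timestep fully connected layer
with sigmoid activation, and a linear regression output; trained with Adam
(learning rate 0.001), batch size 50, 100 epochs, mean squared error. The
implementation is in NumPy (`runkin/_bdlstm.py`) with exact seeded
reproducibility; its backpropagation-through-time gradients are verified
against central finite differences in the test suite.

Design points left open by convention and fixed here: inputs are z-scored
per channel with statistics from the training subjects only; windows are
non-overlapping for training and inference (overlap is exposed as a
configuration for experimentation); the sigmoid layer width equals the
window length (100); resultants are computed after filtering. The original
Bayesian hyperparameter search is replaced by a plain seeded grid sweep
(`sweep_hyperparams`) over hidden units and window lengths.

Estimated series are post-processed in order: 2nd-order zero-lag 15 Hz
low-pass (estimates are noisier than measured force), sub-5 %-BW zeroing,
and pruning of "contacts" shorter than 0.100 s (not physiological during
running) or longer than 0.500 s (quiet standing); pruned segments are
forced to 0 BW, so swing-phase estimation error is exactly zero wherever
both estimate and truth are sub-threshold. IC/TO of surviving contacts are
the threshold crossings, matched to measured contacts by the
half-contact-time rule before any comparison.

Evaluation uses leave-one-subject-out cross-validation: each fold trains on
all other subjects (including normalization statistics) and estimates the
held-out subject's session, mimicking deployment on a novel runner.

## Agreement analysis

Footfall-level variables are aggregated per (subject, velocity bin, grade
class); cells with fewer than 10 footfalls are excluded, and RMSE-type
columns pool as root-mean-squares rather than plain means. Agreement per
variable is summarized by Bland–Altman bias with 95 % limits of agreement
(bias ± 1.96 x sample SD of estimated − measured, n−1 denominator),
ordinary least squares of estimated on measured (slope), squared Pearson
correlation, and RMSE. Correlation strength is classified half-open upward:
strong r² ≥ 0.8, moderate [0.5, 0.8), weak [0.3, 0.5), else below-weak.
Waveform RMSE pairs samples by absolute timestamp over the measured stance
interval, with zeros where no estimate exists.

## The simulator

No public dataset carries this sensor layout with ground truth, so the
package ships a seeded generator whose outputs have the statistical
structure the detectors and the network assume.

* **Stance force** is the sum of two raised-cosine bells over the contact:
  a narrow impact transient (amplitude 1.0 BW, center 13 % of stance,
  half-width 13 %) and a broad active peak (amplitude 2.35 BW, center 50 %,
  half-width 47 %), both scaled by 1 + 0.05 (v − 3.0) so magnitudes rise
  mildly with speed; declines scale the impact amplitude by 1.5 and
  inclines by 0.6. Defaults put the stance average near 1.23 BW and the
  peak near 2.35 BW at 3.0 m/s on level ground — inside the ranges measured
  for outdoor runners — and the closed-form bell integral (mean = amplitude
  x width fraction) anchors the kinetics tests.
* **Timing.** Contact time is linear in speed, tc = 0.28 − 0.02 (v − 3.0) s;
  stride time is 60/(72 + 3 v) s (cadence rises mildly with speed). Feet
  alternate half a stride apart with genuine flight phases; zero-speed
  segments produce no steps and quiet signals. Ground-truth IC/TO are the
  5 % BW crossings of the continuous waveform, so truth is consistent with
  the force detector by construction.
* **IMU synthesis.** Each channel is a subject-gain-scaled copy of the
  concurrent (foot or summed) GRF plus event-locked raised-cosine
  transients and Gaussian noise (defaults 0.8 m/s² accelerometer,
  0.08 rad/s gyro): an x-gyro dip of −5 rad/s peaking 15 ms before IC, a
  70/60 m/s² burst on the horizontal accelerometers at IC (so the resultant
  rule fires without contaminating the vertical channel), and a 36 m/s²
  vertical burst at TO for the 3 g rule. The GRF-proportional terms make
  the target learnable from the inputs; per-subject gains (SD 3 %) create
  the transfer gap that LOOCV is meant to expose.
* **Artifacts.** Clock drift relabels IMU timestamps affinely (truth keeps
  both clocks); baseline drift adds a slow positive sinusoid (amplitude
  magnitude/3 around the magnitude, 20 s period) to the force after an
  onset.
* **GPS.** Per-second speed follows the course schedule; elevation
  integrates speed x tan(grade + noise) with 4° grade noise, matching the
  noise that motivates the ±5° level band.

What the simulator does *not* emulate: soft-tissue and footwear dynamics,
surface variation, step-to-step timing variability, magnetometer channels,
orientation-estimation error (channels are emitted gravity-aligned), and
GPS positional error. Passing tests therefore demonstrate algorithmic
correctness and end-to-end recovery under the stated signal model, not
field accuracy on real runners.

## Problem sizes and numerical choices

The validation suite uses 20 noise-free 115-s sessions (≥ 150 steps per
foot) for event and clock recovery, and a 6-subject cohort of ~112-s
sessions (~300 steps each) for the LOOCV, which trains 6 models at the
default configuration. The acceptance script uses 6 event-recovery
sessions and a 5-subject, 90-s LOOCV. On this cohort the held-out median
stance waveform RMSE is well below 0.20 BW and contact-time RMSE below
0.040 s; correlations of stance-average force across held-out subjects are
nevertheless weak, because between-subject gain differences shift waveform
magnitude — the same novel-participant transfer limitation reported for
field data.

Numerical details: filters require cutoff < Nyquist and series longer than
3 x order; decimation requires an integer rate ratio; degenerate (zero
variance) input channels have their SD floored at 1e-8 before z-scoring;
event lists shorter than 10 refuse clock fitting; equal early impact peaks
resolve to the first; velocity-bin midpoints round up.
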