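# Methods

`imustep` segments leg-mounted IMU recordings of walking turkeys into
individual steps. A *profile* is one recording of one leg of one animal:
calibrated 100 Hz time series of triaxial acceleration, free
acceleration, angular velocity and magnetic field, plus Euler angles and
a unit quaternion. A *step* is a half-open interval `[start, end)` on
the sample axis, from the foot leaving the ground to the foot striking
it again. The acceleration magnitude `|a| = sqrt(Acc_X² + Acc_Y² +
Acc_Z²)` of a real step rises from the resting value (gravity,
~9.81 m/s²) to a peak above 20 m/s² and then drops below the resting
value at landing; movements peaking below that are, by the annotation
convention the package adopts, not steps (leg tremor, shuffling).

The package implements three detectors over this shared model, an
event-based evaluation protocol, and a synthetic gait generator that
provides ground truth, because the original walkway recordings are
proprietary.

## Conventions

* Intervals are half-open, 0-based, on the sample axis. Seconds convert
  via `round(t * sample_rate_hz)`; all second-valued thresholds are
  stated in seconds and converted once.
* Annotation files store seconds (rate-independent, human-readable);
  recordings store one row per sample.
* Recordings may omit channel families; each detector validates the
  channels it needs.

## Preprocessing

All detectors denoise with a zero-phase (forward–backward) Butterworth
low-pass filter, default order 4, cutoff 10 Hz at 100 Hz sampling.
Zero-phase filtering is deliberate: the entire evaluation is about event
timing and a causal filter would bias every detection late by its group
delay. The 10 Hz default keeps step dynamics (~1.7 steps/s, with
within-step structure up to a few Hz) and removes sample-scale jitter.
The effective magnitude response is the squared Butterworth response.
Both the cutoff and the order are configuration.

## Change-point detection (SST)

For each acceleration axis and each time point *t*, two windows of
`window = 10` samples — just before and just after *t* — are
delay-embedded (dimension 5) into trajectory matrices. Columns are
centred, both matrices are decomposed by SVD, and the score is

    score(t) = 1 − ‖ U_pastᵀ u_future ‖²,

the complement of the squared cosine between the leading future singular
vector and the span of the top 2 past singular vectors. Scores lie in
[0, 1]; edges without complete windows score 0. A trajectory matrix
whose centred Frobenius norm is below 1e-7 × the series' standard
deviation carries no dynamics and scores 0 — the threshold is relative
so that scores are exactly invariant under affine maps of the input
(which is also a tested property).

Each axis is thresholded at strictly above 5 % of that axis's maximum
score (per profile), a 2-of-3 majority vote combines the axes, and
maximal runs of the vote become intervals.

Two properties of this score family matter in practice:

* **Amplitude blindness.** Subspace angles ignore scale, so broadband
  noise produces large scores everywhere; the method depends on the
  low-pass stage and is exercised on clean signals. This is a real
  limitation of the score, documented rather than patched.
* **Two blobs per step.** The score is large where dynamics change
  (step onset and landing) and dips in the smooth mid-step region, so a
  single step typically yields two detected intervals. Combined with
  the fact that the score cannot exceed the 5 % threshold until the
  change has entered its windows, this reproduces the behaviour
  expected of SST step detection: essentially every step is found at a
  1 s matching allowance, but precision at strict allowances is poor
  and detected starts lag annotated starts by a positive, irregular
  delay (~0.26 s mean on the default benchmark).

`window = 10` and the 5 % threshold are fixed by the method; embedding
dimension and subspace rank are free parameters of the SST family,
chosen to be feasible inside a 10-sample window, and configurable.

## Local-extrema approach (LEA)

Nine channels (Acc, Gyr, Euler) are filtered, then:

1. **Extrema** — a sample is a local extremum if it is the strict
   max/min of the 140-sample window centred on it (floor(w/2) before,
   rest after, truncated at edges; ties are never extrema, so plateaus
   and constant stretches yield nothing).
2. **Significance** — an extremum survives if it deviates from the 10
   surrounding samples (5 per side, excluding itself) by at least 0.5
   sample standard deviations; flat surroundings keep an extremum only
   if it deviates at all. This deletes extrema in motionless stretches.
3. **Importance** — surviving extrema from all channels are pooled; an
   index is kept if it occurs on ≥ 2 channels or has another extremum
   within 0.1 s on any channel.
4. **Growing** — an interval of 0.6 s (the mean annotated step length)
   is seeded at the first important extremum; any extremum within
   0.12 s (the minimum inter-step gap) of the current end extends the
   end to it; emit and repeat.
5. **Trimming** — leading extrema more than 0.12 s from their successor
   are dropped and the interval re-derived from the survivors.
6. **Filtering** — a candidate survives only if it lasts ≥ 0.2 s, holds
   ≥ 2 extrema with all consecutive gaps ≤ 0.25 s, and its raw
   acceleration-magnitude peak reaches 11 m/s² (below that: tremor).
   Comparison directions follow the rule statements literally
   (`< 0.2 s` removed, `> 0.25 s` removed, `< 11 m/s²` removed).

Ambiguities resolved as package choices: "surrounding 10 measurements"
is read as 5 each side excluding the extremum; trimming applies after
growing, per candidate; intervals stretched by re-derivation are clipped
against their successor so the output stays disjoint. The first
important extremum of a step is typically the first filtered peak inside
it, ~0.2 s after the annotated start, so LEA carries a small positive
delay at both endpoints — visible on the benchmark as high recall from
0.3 s allowances upward but weak F at 0.2 s.

## Gradient-boosting detector (GBM)

Each sample becomes a feature row: for 20 channels and offsets 5–10 the
features are the differences `x[t] − x[t−k]` (lag) and `x[t] − x[t+k]`
(lead), 12 per channel, 240 in total. At 100 Hz these offsets span
0.05–0.1 s, the time scale of within-step change. Edge positions whose
shifted index falls outside the recording carry NaN; the trees handle
missing values natively (zero-padding would fabricate edge changes).
The 20 channels are the 16 non-magnetometer channels plus four derived
series — acceleration, free-acceleration and angular-velocity
magnitudes, and the yaw first difference. Only the ×12 structure and
the 240 total are fixed; the channel list is configuration.

Labels are 1 inside an annotated step, 0 outside. Profiles are split
60/20/20 into train/validation/test at profile level (largest-remainder
rounding; 20 profiles → 12/4/4), never splitting a profile. The
classifier is a LightGBM ensemble of 50 trees, depth 5, 32 leaves,
learning rate 0.1, deterministic per seed. Predicted probabilities are
thresholded at 0.5; runs of ≥ 10 consecutive step predictions become
candidate steps and candidates with an end-to-start gap ≤ 10 samples
are merged (iterated to a fixed point, which a single pass already
reaches). The probability threshold can alternatively be chosen on the
validation split; 0.5 is the reproducible default.

## Evaluation

A detected step matches an annotated step only if **both** |Δstart| and
|Δend| are within the allowed distance (0.1–0.5 s and 1.0 s by
default). Pairing is one-to-one and maximum-cardinality, with ties
broken by smallest total |Δstart| + |Δend| (implemented as a linear
assignment with a prohibitive cost on ineligible pairs; a greedy
strategy is available for sensitivity analysis). Precision, recall and
the harmonic-mean F-score follow; zero denominators yield an explicit
NA, never a conventional 0. Signed delays (detected − annotated,
negative = early) are summarised over matched pairs at the widest
tolerance of a sweep, where matching is least censored.

## Synthetic data

The generator emulates the walkway-test regime: 20 profiles (two legs
of ten animals), 20 s at 100 Hz, 7–15 steps per profile, step duration
N(0.6 s, 0.06 s) clipped to ±3 SD, gaps ≥ 0.12 s, peak magnitude
U(22, 30) m/s². Each step's magnitude envelope is a raised-cosine rise
from the gravity baseline to the peak (rise fraction U(0.45, 0.6) of
the step) followed by a cosine fall through an undershoot minimum
(baseline − 4.5 m/s²) and recovery — smooth by construction so the
shape survives low-pass filtering, unlike a piecewise-linear envelope.
The envelope is distributed over the three accelerometer axes by a unit
direction that tilts smoothly away from the gravity axis during the
step, so |Acc| reproduces the envelope exactly. Gyroscope pulses with
zero net rotation are synchronised with the steps; Euler angles
integrate the gyroscope; the quaternion re-encodes the Euler
orientation (unit norm to 1e-6); free acceleration subtracts the
orientation-rotated gravity vector; the magnetometer is a constant
field (no detector uses it).

Default stress content: two tremor segments per profile — smooth
wobbles in quiet gaps peaking at 10.5 m/s², below the 11 m/s²
annotation floor, hence excluded from ground truth. These give the
supervised detector negative examples of sub-step movement, which is
what lets it reject tremor-only recordings. Per-channel white sensor
noise and bursts of short fast "hesitation" steps are available as
knobs but off by default: the benchmark represents the clean,
well-separated regime, and the SST score's amplitude blindness makes
broadband noise a stress axis to be studied deliberately, not folded
into every run.

What the generator does **not** model: biomechanically faithful turkey
gait (envelopes are stylised), annotator subjectivity in the ground
truth (truth boundaries are exact, so the supervised detector can be
nearly perfect here in a way it cannot on hand-annotated data),
inter-animal variability of step shape, magnetometer dynamics, and
sensor artefacts (drift, saturation). Passing the benchmark therefore
demonstrates correctness of the pipelines and the *relative* behaviour
of the methods — it does not certify absolute performance numbers on
real recordings.

## Problem sizes and determinism

The default benchmark (20 × 2000 samples, 24 000 training rows × 240
features, three detectors over 4 test profiles, six tolerances) runs in
a few seconds on one CPU; tests and the acceptance script use it
directly. All randomness flows from explicit seeds through
`numpy.random.Generator` (profile streams are spawned from a single
`SeedSequence`) and LightGBM runs in deterministic single-thread mode,
so every artefact — manifests, detections, reports — is byte-identical
across runs at the same seed.

## Known limitations

* The SST score is one member of the transformation family; other
  members (e.g. singular-value-ratio scores) would change the blob
  structure and the delay profile.
* LEA's eight thresholds are tuned to this age group and species by
  construction; the package exposes them but offers no auto-tuning.
* The evaluation is event-based only; per-sample segmentation quality
  is out of scope.
* Undefined metrics are NA: downstream consumers must handle missing
  values rather than assume zeros.
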