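# imustep

Step segmentation of leg-mounted IMU recordings for gait analysis in
heavy poultry (and similar walkway-test settings). Automated locomotion
scoring needs each step isolated before step features can be extracted;
`imustep` finds the start and end of every step in a 100 Hz recording of
triaxial acceleration, angular velocity and orientation, and scores how
well detected steps line up with annotated ones.

Three detectors are implemented over a shared recording/annotation
model:

* **CPD** — unsupervised change-point detection by singular spectrum
  transformation (SST): for each time point, the subspace angle between
  delay-embedded trajectory matrices of the 10 samples before and after
  it gives a novelty score in [0, 1]; each acceleration axis is
  thresholded at 5 % of its maximum score and a 2-of-3 majority vote
  yields step intervals.
* **LEA** — unsupervised local-extrema approach: significant local
  extrema across nine channels are merged into "important extrema",
  dense clusters grow into candidate intervals (0.6 s seed, 0.12 s
  extension gap), and candidates are filtered by duration (≥ 0.2 s),
  extrema density (gaps ≤ 0.25 s) and acceleration-magnitude peak
  (≥ 11 m/s²).
* **GBM** — supervised gradient boosting: every sample gets 240 lag/lead
  difference features (20 channels × offsets 5–10 in both directions),
  a 50-tree depth-5 ensemble predicts per-sample step probability, and
  runs of ≥ 10 step predictions (merged across gaps ≤ 10 samples)
  become steps.

Evaluation is event-based: a detection is a true positive only if both
its start and end are within an allowed distance (0.1–1.0 s) of an
annotated step, under maximum-cardinality one-to-one matching;
precision, recall, harmonic-mean F-score and signed start/end delays
are reported. A synthetic gait generator produces recordings with known
ground truth (two-phase step envelopes peaking above 20 m/s², sub-step
tremor below 11 m/s², 7–15 steps per 20 s profile), so the whole
pipeline is testable without proprietary animal data. See
`docs/methods.md` for the full model description.

## Worked example

One command simulates a 20-profile benchmark (12 train / 4 validation /
4 test profiles), trains the GBM on the training profiles, runs all
three detectors on the held-out test profiles and sweeps the matching
tolerance:

```sh
imustep pipeline --seed 1 --out results/
```

which prints (abridged to the 0.2 s and 1.0 s rows):

```
method  tolerance_s  tp  fp  fn  precision   recall  f_score
   cpd          0.2   0 143  42   0.000000 0.000000      NaN
   cpd          1.0  42 101   0   0.293706 1.000000 0.454054
   lea          0.2   7  34  35   0.170732 0.166667 0.168675
   lea          1.0  41   0   1   1.000000 0.976190 0.987952
   gbm          0.2  42   0   0   1.000000 1.000000 1.000000
   gbm          1.0  42   0   0   1.000000 1.000000 1.000000

method  start_mean_s  start_sd_s  end_mean_s  end_sd_s  n_pairs
   cpd      0.257381    0.293914   -0.304048  0.316221       42
   lea      0.186829    0.060351    0.176585  0.087682       41
   gbm      0.000000    0.003123    0.000000  0.000000       42
```

Reading this: all 42 annotated test steps are found by every method at
the coarse 1 s allowance (recall ≥ 0.98 — any of the three is fine for
step *counting*). At the strict 0.2 s allowance the supervised GBM is
far ahead, LEA is weakened by its systematic ~0.19 s delay (it anchors
intervals at the first filtered extremum inside the step, not at the
onset), and CPD fails entirely: its SST score fires at both the onset
and the landing of each step, splitting detections (143 for 42 steps)
and delaying starts by an irregular +0.26 ± 0.29 s. On the clean
synthetic truth the GBM's delays are near zero; on hand-annotated real
data its advantage is smaller but the ordering GBM > LEA > CPD is the
same.

The library mirrors the CLI one-to-one:

```python
import numpy as np
from imustep import GaitSimSpec, simulate_recording, detect_lea
from imustep import match_steps, metrics

sim = simulate_recording(GaitSimSpec(seed=42), rng=np.random.default_rng(42))
steps = detect_lea(sim.recording)
report = match_steps(sim.truth.intervals, steps, 0.5, 100.0)
print(metrics(report))   # EvalMetrics(precision=1.0, recall=1.0, f_score=1.0)
```

Other subcommands: `simulate` (benchmark to CSV + manifest), `train`
(fit and persist a classifier), `detect` (any method on recording
CSVs, optional `--plot` overlay), `evaluate`/`sweep` (score a
detections file against annotations). All accept `--config cfg.yaml`;
every method constant above is a config key, and the resolved
configuration is written next to each output.

## Layout

```
src/imustep/
  imu_io.py        recordings, step intervals, annotation tables (CSV)
  signal_prep.py   magnitude, zero-phase low-pass, lag/lead features
  cpd_sst.py       SST scores, thresholds, majority vote
  lea.py           extrema pipeline and interval filters
  gbm_detector.py  labels, profile splits, LightGBM, run-length rules
  evaluation.py    matching, metrics, delays, tolerance sweep
  synthetic.py     gait simulator and benchmark suite
  cli.py           click CLI and the pipeline orchestration
```
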