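"""Synthetic leg-mounted IMU recordings with known step ground truth.

The generator emulates the statistical structure of walkway-test
recordings from heavy poultry: roughly 20 s per profile at 100 Hz,
7–15 steps of ~0.6 s mean duration separated by at least 0.12 s, each
step showing the two-phase acceleration-magnitude signature (rise from
baseline to a peak above 20 m/s^2 while the foot lifts, then a drop
below baseline as it lands).  Optional "tremor" segments reproduce
sub-step disturbances whose magnitude stays below 11 m/s^2 and which,
by the annotation convention, are never part of the ground truth.

At rest the accelerometer reads gravity (magnitude ~9.81 m/s^2) along a
fixed sensor axis; during a step the magnitude follows the step envelope
while the sensing direction tilts smoothly and returns.  Gyroscope
pulses are synchronised with the steps, Euler angles integrate the
gyroscope, the quaternion re-encodes the Euler orientation, and free
acceleration subtracts the orientation-rotated gravity vector.  The
magnetometer is emulated as a constant field (no detector uses it).
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial.transform import Rotation

from .imu_io import (
    AnnotationSet,
    ImuRecording,
    StepInterval,
    write_annotations,
    write_recording,
)

__all__ = [
    "GaitSimSpec",
    "SimResult",
    "simulate_step_profile",
    "simulate_recording",
    "benchmark_suite",
    "BenchmarkSuite",
]

GRAVITY_M_S2 = 9.81


@dataclass(frozen=True)
class GaitSimSpec:
    """Generator configuration; defaults mirror the walkway-test regime.

    ``noise_sd`` is additive white sensor noise per channel, off by
    default: the benchmark emulates clean, well-separated steps.  The
    subspace-angle SST score is amplitude blind, so broadband noise is a
    separate stress axis (see the methods note), exercised explicitly
    rather than folded into every test.
    """

    n_profiles: int = 20
    sample_rate_hz: float = 100.0
    duration_s: float = 20.0
    steps_min: int = 7
    steps_max: int = 15
    step_duration_mean_s: float = 0.6
    step_duration_sd_s: float = 0.06
    min_gap_s: float = 0.12
    peak_min_m_s2: float = 22.0
    peak_max_m_s2: float = 30.0
    baseline_m_s2: float = GRAVITY_M_S2
    undershoot_m_s2: float = 4.5
    noise_sd: float = 0.0
    tremor_per_profile: int = 2
    tremor_peak_m_s2: float = 10.5
    hesitation_prob: float = 0.0
    edge_margin_s: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_gap_s < 0.12:
            raise ValueError("min_gap_s must be >= 0.12 s")
        if self.peak_min_m_s2 <= 20.0:
            raise ValueError(
                "peak_min_m_s2 must exceed 20 m/s^2 — weaker movements are "
                "not annotated as steps by convention"
            )
        if self.peak_max_m_s2 < self.peak_min_m_s2:
            raise ValueError("peak_max_m_s2 < peak_min_m_s2")
        if not (0 <= self.steps_min <= self.steps_max):
            raise ValueError("need 0 <= steps_min <= steps_max")
        if self.tremor_peak_m_s2 >= 11.0:
            raise ValueError("tremor_peak_m_s2 must stay below 11 m/s^2")
        max_dur = self.step_duration_mean_s + 3 * self.step_duration_sd_s
        needed = (
            2 * self.edge_margin_s
            + self.steps_max * max_dur
            + (self.steps_max - 1) * self.min_gap_s
        )
        if needed > self.duration_s:
            raise ValueError(
                f"cannot pack up to {self.steps_max} steps into "
                f"{self.duration_s} s (needs ~{needed:.1f} s)"
            )


@dataclass
class SimResult:
    """One simulated profile: recording, ground truth, and an event log."""

    recording: ImuRecording
    truth: AnnotationSet
    events: dict


def simulate_step_profile(
    duration_s: float,
    peak: float,
    rng: np.random.Generator,
    *,
    sample_rate_hz: float = 100.0,
    baseline: float = GRAVITY_M_S2,
    undershoot: float = 4.5,
) -> np.ndarray:
    """Two-phase acceleration-magnitude envelope of a single step.

    Raised-cosine rise from ``baseline`` to ``peak`` over roughly the
    first half of the step, then a fall through a sub-baseline minimum
    (``baseline - undershoot``, the landing) with recovery back to
    baseline at the end.  Smooth (band-limited) by construction so the
    shape survives low-pass filtering.  A ``peak`` at or below the
    baseline produces a flat baseline segment.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    n = max(1, int(round(duration_s * sample_rate_hz)))
    if peak <= baseline:
        return np.full(n, float(baseline) if peak > 0 else float(peak))
    rise_frac = rng.uniform(0.45, 0.60)
    n1 = max(2, int(round(rise_frac * n)))
    n1 = min(n1, n - 2)
    n2 = n - n1
    t1 = np.arange(n1) / n1
    rise = baseline + (peak - baseline) * 0.5 * (1 - np.cos(np.pi * t1))
    vmin = max(baseline - undershoot, 0.5)
    n_fall = max(1, int(round(0.6 * n2)))
    n_rec = n2 - n_fall
    t2 = np.arange(1, n_fall + 1) / n_fall
    fall = vmin + (peak - vmin) * 0.5 * (1 + np.cos(np.pi * t2))
    if n_rec > 0:
        t3 = np.arange(1, n_rec + 1) / n_rec
        recover = baseline + (vmin - baseline) * 0.5 * (1 + np.cos(np.pi * t3))
    else:
        recover = np.empty(0)
    return np.concatenate([rise, fall, recover])


def _bump(n: int) -> np.ndarray:
    """Smooth unit bump over n samples, zero at both ends."""
    t = np.arange(n) / max(n - 1, 1)
    return np.sin(np.pi * t) ** 2


def _place_events(
    rng: np.random.Generator, spec: GaitSimSpec, durations_s: np.ndarray
) -> list[int]:
    """Start samples for events with all gaps >= min_gap_s."""
    rate = spec.sample_rate_hz
    n_events = len(durations_s)
    usable = spec.duration_s - 2 * spec.edge_margin_s
    needed = float(np.sum(durations_s)) + (n_events - 1) * spec.min_gap_s
    slack = usable - needed
    if slack < 0:
        raise ValueError("cannot place events: insufficient slack")
    weights = rng.dirichlet(np.ones(n_events + 1))
    starts = []
    cursor = spec.edge_margin_s + weights[0] * slack
    for i, dur in enumerate(durations_s):
        starts.append(int(round(cursor * rate)))
        cursor += dur
        if i < n_events - 1:
            cursor += spec.min_gap_s + weights[i + 1] * slack
    return starts


def simulate_recording(
    spec: GaitSimSpec,
    *,
    profile_id: str = "sim",
    leg_id: str = "1",
    rng: np.random.Generator | None = None,
) -> SimResult:
    """Generate one profile with ground-truth step annotations."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    rate = spec.sample_rate_hz
    n = int(round(spec.duration_s * rate))

    n_steps = int(rng.integers(spec.steps_min, spec.steps_max + 1))
    durations = rng.normal(
        spec.step_duration_mean_s, spec.step_duration_sd_s, size=n_steps
    )
    lo = spec.step_duration_mean_s - 3 * spec.step_duration_sd_s
    hi = spec.step_duration_mean_s + 3 * spec.step_duration_sd_s
    durations = np.clip(durations, max(lo, 0.25), hi)
    if spec.hesitation_prob > 0 and rng.random() < spec.hesitation_prob:
        # burst of short fast steps after stimulation
        k = min(3, n_steps)
        durations[:k] = rng.uniform(0.25, 0.35, size=k)
    starts = _place_events(rng, spec, durations)

    magnitude = np.full(n, spec.baseline_m_s2)
    tilt_weight = np.zeros(n)
    gyr = np.zeros((n, 3))
    intervals: list[StepInterval] = []
    step_log = []
    for start, dur in zip(starts, durations):
        peak = rng.uniform(spec.peak_min_m_s2, spec.peak_max_m_s2)
        env = simulate_step_profile(
            dur, peak, rng, sample_rate_hz=rate,
            baseline=spec.baseline_m_s2, undershoot=spec.undershoot_m_s2,
        )
        end = min(start + len(env), n)
        seg = slice(start, end)
        magnitude[seg] = env[: end - start]
        bump = _bump(end - start)
        tilt_weight[seg] = np.maximum(tilt_weight[seg], bump)
        # synchronised rotational-velocity pulse; zero net rotation
        amps = rng.uniform(1.0, 4.0, size=3) * rng.choice([-1, 1], size=3)
        swing = np.sin(2 * np.pi * np.arange(end - start) / (end - start))
        gyr[seg] += amps * (swing * bump)[:, None]
        intervals.append(StepInterval(start, end))
        step_log.append({"start": start, "end": end, "peak": float(peak)})

    tremor_log = []
    for _ in range(spec.tremor_per_profile):
        placed = _try_place_tremor(rng, spec, magnitude, intervals, n)
        if placed is not None:
            tremor_log.append(placed)

    # distribute the magnitude across axes via a smoothly tilting unit
    # direction; at rest the direction is the gravity axis, so the norm
    # of the Acc channels reproduces `magnitude` exactly.
    g_dir = np.array([0.0, 0.0, 1.0])
    tilt_dir = rng.normal(size=3)
    tilt_dir[2] = 0.0
    tilt_dir /= np.linalg.norm(tilt_dir[:2])
    tilt_amp = rng.uniform(0.25, 0.45)
    dirs = g_dir[None, :] + tilt_amp * tilt_weight[:, None] * tilt_dir[None, :]
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    acc = magnitude[:, None] * dirs

    euler_rad = np.cumsum(gyr, axis=0) / rate
    euler_deg = np.degrees(euler_rad)
    rot = Rotation.from_euler("xyz", euler_deg, degrees=True)
    quat_xyzw = rot.as_quat()  # scipy order (x, y, z, w)
    gravity_sensor = rot.inv().apply(np.array([0.0, 0.0, GRAVITY_M_S2]))
    free_acc = acc - gravity_sensor

    channels = {
        "Acc_X": acc[:, 0], "Acc_Y": acc[:, 1], "Acc_Z": acc[:, 2],
        "FreeAcc_X": free_acc[:, 0], "FreeAcc_Y": free_acc[:, 1],
        "FreeAcc_Z": free_acc[:, 2],
        "Gyr_X": gyr[:, 0], "Gyr_Y": gyr[:, 1], "Gyr_Z": gyr[:, 2],
        "Mag_X": np.full(n, 20.0), "Mag_Y": np.full(n, 5.0),
        "Mag_Z": np.full(n, -45.0),
        "Roll": euler_deg[:, 0], "Pitch": euler_deg[:, 1],
        "Yaw": euler_deg[:, 2],
        "Quat_W": quat_xyzw[:, 3], "Quat_X": quat_xyzw[:, 0],
        "Quat_Y": quat_xyzw[:, 1], "Quat_Z": quat_xyzw[:, 2],
    }
    if spec.noise_sd > 0:
        for name in channels:
            if not name.startswith(("Quat", "Mag")):
                channels[name] = channels[name] + rng.normal(
                    0.0, spec.noise_sd, size=n
                )

    rec = ImuRecording(
        profile_id=profile_id, leg_id=leg_id,
        channels=channels, sample_rate_hz=rate,
    )
    truth = AnnotationSet(profile_id, leg_id, intervals)
    events = {"steps": step_log, "tremor": tremor_log}
    return SimResult(recording=rec, truth=truth, events=events)


def _try_place_tremor(rng, spec, magnitude, intervals, n):
    """Place one tremor wobble in a quiet gap; peak stays below 11 m/s^2."""
    dur = rng.uniform(0.3, 0.6)
    length = int(round(dur * spec.sample_rate_hz))
    margin = int(round(spec.min_gap_s * spec.sample_rate_hz))
    for _ in range(20):
        start = int(rng.integers(0, n - length))
        candidate = StepInterval(start, start + length)
        clear = all(
            candidate.end + margin <= iv.start or candidate.start >= iv.end + margin
            for iv in intervals
        )
        region = magnitude[candidate.start : candidate.end]
        if clear and np.all(np.abs(region - spec.baseline_m_s2) < 1e-9):
            amp = spec.tremor_peak_m_s2 - spec.baseline_m_s2
            wobble = amp * _bump(length) * np.sin(
                2 * np.pi * np.arange(length) / max(length // 3, 2)
            )
            magnitude[candidate.start : candidate.end] = np.clip(
                spec.baseline_m_s2 + wobble, 0.5, spec.tremor_peak_m_s2
            )
            return {"start": candidate.start, "end": candidate.end}
    return None


@dataclass
class BenchmarkSuite:
    """Profile-level train/validation/test partition of simulated data."""

    train: list[SimResult]
    validation: list[SimResult]
    test: list[SimResult]
    manifest: dict

    @property
    def all_results(self) -> list[SimResult]:
        return self.train + self.validation + self.test


def benchmark_suite(
    spec: GaitSimSpec = GaitSimSpec(),
    seed: int = 1,
    out_dir=None,
) -> BenchmarkSuite:
    """Simulate ``spec.n_profiles`` profiles and split them 60/20/20.

    Profiles are paired two legs per animal.  The split is made at
    profile level (a profile is never shared between sets) and is
    deterministic in ``seed``.  With ``out_dir`` set, recordings,
    ground-truth annotations, and a JSON manifest are written in the
    package's text formats.
    """
    from .gbm_detector import split_profiles

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(spec.n_profiles)
    results: list[SimResult] = []
    for i, child in enumerate(children):
        animal = i // 2 + 1
        leg = i % 2 + 1
        pid = f"t{animal:03d}"
        res = simulate_recording(
            spec,
            profile_id=pid,
            leg_id=str(leg),
            rng=np.random.default_rng(child),
        )
        results.append(res)

    keys = [f"{r.recording.profile_id}_leg{r.recording.leg_id}" for r in results]
    train_k, valid_k, test_k = split_profiles(keys, (0.6, 0.2, 0.2), seed)
    by_key = dict(zip(keys, results))
    suite = BenchmarkSuite(
        train=[by_key[k] for k in keys if k in train_k],
        validation=[by_key[k] for k in keys if k in valid_k],
        test=[by_key[k] for k in keys if k in test_k],
        manifest={
            "seed": seed,
            "n_profiles": spec.n_profiles,
            "split": {
                "train": sorted(train_k),
                "validation": sorted(valid_k),
                "test": sorted(test_k),
            },
            "steps_per_profile": {
                k: len(by_key[k].truth) for k in keys
            },
        },
    )

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        for key, res in zip(keys, results):
            write_recording(
                res.recording, os.path.join(out_dir, f"{key}.csv")
            )
        write_annotations(
            [r.truth for r in results],
            os.path.join(out_dir, "annotations.csv"),
            sample_rate_hz=spec.sample_rate_hz,
        )
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump(suite.manifest, fh, indent=2, sort_keys=True)
    return suite
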