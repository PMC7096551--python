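"""Local-extrema pipeline: each rule in isolation, then composed."""

import numpy as np
import pytest

from imustep.imu_io import ImuRecording, StepInterval
from imustep.evaluation import match_steps
from imustep.lea import (
    Extremum,
    ExtremumKind,
    LeaConfig,
    detect_lea,
    filter_intervals,
    grow_intervals,
    important_extrema,
    significance_filter,
    sliding_extrema,
    trim_leading,
)
from imustep.signal_prep import acceleration_magnitude


def oracle_sliding_extrema(x, window):
    """Brute-force window scan with the same centring convention."""
    x = np.asarray(x, dtype=float)
    half_before = window // 2
    half_after = window - half_before - 1
    found = []
    for i in range(len(x)):
        lo, hi = max(0, i - half_before), min(len(x), i + half_after + 1)
        others = np.concatenate([x[lo:i], x[i + 1 : hi]])
        if others.size == 0:
            continue
        if x[i] > others.max():
            found.append((i, "max"))
        elif x[i] < others.min():
            found.append((i, "min"))
    return found


class TestSlidingExtrema:
    def test_monotone_series_has_no_interior_extrema(self):
        out = sliding_extrema(np.arange(300, dtype=float), 140)
        # only the global endpoints can dominate their (truncated) windows
        assert all(e.index in (0, 299) for e in out)

    def test_constant_series_has_none(self):
        assert sliding_extrema(np.full(300, 2.0), 140) == []

    def test_sine_matches_brute_force(self):
        t = np.arange(400)
        x = np.sin(2 * np.pi * t / 100)
        got = [(e.index, e.kind.value) for e in sliding_extrema(x, 140)]
        assert got == oracle_sliding_extrema(x, 140)
        kinds = {k for _, k in got}
        assert kinds <= {"min", "max"}

    def test_random_series_matches_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.normal(size=200)
            got = [(e.index, e.kind.value) for e in sliding_extrema(x, 21)]
            assert got == oracle_sliding_extrema(x, 21)


class TestSignificanceFilter:
    @staticmethod
    def _ex(i, value):
        return Extremum("c", i, ExtremumKind.MAX, value)

    def test_flat_surroundings_removed(self):
        x = np.full(21, 1.0)
        kept = significance_filter([self._ex(10, 1.0)], x)
        assert kept == []

    def test_spike_over_noisy_surroundings_kept(self):
        # fixed 11-sample vector, sd of surroundings ~ 1
        x = np.array(
            [0.3, -1.2, 0.8, -0.5, 1.1, 10.0, -0.9, 0.4, -1.5, 0.7, 0.2]
        )
        kept = significance_filter([self._ex(5, 10.0)], x)
        assert [e.index for e in kept] == [5]

    @pytest.mark.parametrize("factor,expect_kept", [(0.4, False), (0.6, True)])
    def test_threshold_arithmetic(self, factor, expect_kept):
        """Deviation of exactly `factor` SDs versus the 0.5 SD rule."""
        surroundings = np.array([-1.0, 1.0] * 5)
        sd = surroundings.std(ddof=1)
        x = np.concatenate([surroundings[:5], [factor * sd], surroundings[5:]])
        # surroundings are symmetric: mean 0
        kept = significance_filter(
            [self._ex(5, float(x[5]))], x, sd_factor=0.5
        )
        assert bool(kept) == expect_kept

    def test_odd_neighborhood_rejected(self):
        with pytest.raises(ValueError, match="even"):
            significance_filter([], np.zeros(5), neighborhood=9)


class TestImportantExtrema:
    @staticmethod
    def _per_channel(spec):
        return {
            chan: [Extremum(chan, i, ExtremumKind.MAX, 0.0) for i in idxs]
            for chan, idxs in spec.items()
        }

    def test_isolated_single_channel_extremum_dropped(self):
        got = important_extrema(self._per_channel({"Acc_X": [100]}))
        assert got == []

    def test_same_index_two_channels_kept(self):
        got = important_extrema(
            self._per_channel({"Acc_X": [100], "Gyr_Y": [100]})
        )
        assert got == [100]

    def test_nearby_pair_across_channels_kept(self):
        got = important_extrema(
            self._per_channel({"A": [100], "B": [107]})
        )
        assert got == [100, 107]

    def test_beyond_radius_dropped(self):
        got = important_extrema(
            self._per_channel({"A": [100], "B": [111]})
        )
        assert got == []


class TestGrowIntervals:
    def test_single_extremum_seeds_default_length(self):
        assert grow_intervals([100]) == [StepInterval(100, 160)]

    def test_extension_within_gap(self):
        assert grow_intervals([100, 165]) == [StepInterval(100, 166)]

    def test_split_beyond_gap(self):
        assert grow_intervals([100, 180]) == [
            StepInterval(100, 160),
            StepInterval(180, 240),
        ]

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            grow_intervals([50, 20])


class TestTrimLeading:
    @pytest.mark.parametrize(
        "members,expected",
        [
            ([100, 120, 130], [120, 130]),  # 20-sample lead gap > 12
            ([100, 110], [100, 110]),       # 10 <= 12, kept
            ([100, 115, 126], [115, 126]),  # 15 > 12, then 11 <= 12
            ([100, 115, 130], [130]),       # cascades to a single survivor
        ],
    )
    def test_leading_gap_rule(self, members, expected):
        assert trim_leading([members]) == [expected]


def _recording_with_magnitude(mag, rate=100.0):
    """All-channel recording whose acceleration magnitude equals `mag`."""
    n = len(mag)
    zeros = np.zeros(n)
    channels = {
        "Acc_X": zeros.copy(), "Acc_Y": zeros.copy(),
        "Acc_Z": np.asarray(mag, dtype=float),
        "Gyr_X": zeros.copy(), "Gyr_Y": zeros.copy(), "Gyr_Z": zeros.copy(),
        "Roll": zeros.copy(), "Pitch": zeros.copy(), "Yaw": zeros.copy(),
    }
    return ImuRecording("p", "1", channels, rate)


class TestFilterIntervals:
    REC = None

    @classmethod
    def setup_class(cls):
        mag = np.full(1000, 25.0)
        mag[600:700] = 10.5  # a weak (tremor-level) stretch
        cls.REC = _recording_with_magnitude(mag)

    def test_short_interval_removed(self):
        candidates = [(StepInterval(100, 118), [100, 110, 117])]  # 0.18 s
        assert filter_intervals(candidates, self.REC) == []

    def test_sparse_extrema_removed(self):
        candidates = [(StepInterval(100, 160), [100, 130])]  # 0.30 s gap
        assert filter_intervals(candidates, self.REC) == []

    def test_weak_magnitude_removed(self):
        candidates = [(StepInterval(610, 690), [615, 635, 655, 675])]
        assert filter_intervals(candidates, self.REC) == []

    def test_fewer_than_two_extrema_removed(self):
        candidates = [(StepInterval(100, 160), [120])]
        assert filter_intervals(candidates, self.REC) == []

    def test_dense_strong_interval_kept(self):
        iv = StepInterval(100, 160)
        candidates = [(iv, [100, 120, 140, 159])]
        assert filter_intervals(candidates, self.REC) == [iv]


class TestDetectLea:
    def test_recovers_clean_steps(self, sim_ten_steps):
        rec, truth = sim_ten_steps.recording, sim_ten_steps.truth
        detected = detect_lea(rec)
        report = match_steps(truth.intervals, detected, 0.5, rec.sample_rate_hz)
        assert report.tp >= len(truth) - 1

    def test_deterministic(self, sim_ten_steps):
        rec = sim_ten_steps.recording
        assert detect_lea(rec) == detect_lea(rec)

    def test_channel_order_invariance(self, sim_ten_steps):
        rec = sim_ten_steps.recording
        cfg = LeaConfig()
        reversed_cfg = LeaConfig(channels=tuple(reversed(cfg.channels)))
        assert detect_lea(rec, cfg) == detect_lea(rec, reversed_cfg)

    def test_motionless_wiggle_yields_nothing(self):
        """Sub-threshold wiggles (magnitude << 11 m/s^2) are rejected."""
        rng = np.random.default_rng(2)
        n = 2000
        base = 1.0 + 0.2 * np.sin(2 * np.pi * np.arange(n) / 150)
        rec = _recording_with_magnitude(base + 0.05 * rng.normal(size=n))
        # give the other channels matching low-level wiggle
        for name in ("Gyr_X", "Gyr_Y", "Roll", "Yaw"):
            rec.channels[name] = 0.1 * rng.normal(size=n)
        assert detect_lea(rec) == []

    def test_acceleration_only_configuration_runs(self, sim_ten_steps):
        """An Acc-only channel set is legal (though known to be weak)."""
        cfg = LeaConfig(channels=("Acc_X", "Acc_Y", "Acc_Z"))
        detect_lea(sim_ten_steps.recording, cfg)  # must not raise

    def test_missing_channel_rejected(self, constant_recording):
        cfg = LeaConfig(channels=("Acc_X", "Nope"))
        with pytest.raises(ValueError, match="missing"):
            detect_lea(constant_recording, cfg)

    def test_emitted_intervals_respect_magnitude_floor(self, sim_ten_steps):
        rec = sim_ten_steps.recording
        mag = acceleration_magnitude(
            rec.channel("Acc_X"), rec.channel("Acc_Y"), rec.channel("Acc_Z")
        )
        detected = detect_lea(rec)
        assert detected == sorted(detected)
        for a, b in zip(detected, detected[1:]):
            assert a.end <= b.start
        for iv in detected:
            assert mag[iv.start : iv.end].max() >= 11.0
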