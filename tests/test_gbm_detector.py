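"""Per-timepoint classifier: labels, splits, training and post-processing."""

import numpy as np
import pandas as pd
import pytest

from imustep.evaluation import match_steps, metrics, pool_reports
from imustep.gbm_detector import (
    FeatureMatrix,
    GbmConfig,
    detect_gbm,
    label_timepoints,
    mask_to_steps,
    predict_mask,
    split_profiles,
    train,
)
from imustep.imu_io import AnnotationSet, StepInterval


class TestLabelTimepoints:
    def test_half_open_boundary(self, sim_ten_steps):
        rec = sim_ten_steps.recording
        ann = AnnotationSet(rec.profile_id, rec.leg_id, [StepInterval(120, 180)])
        labels = label_timepoints(rec, ann)
        assert labels[120] == 1 and labels[179] == 1 and labels[180] == 0

    def test_no_annotations_all_zero(self, sim_ten_steps):
        rec = sim_ten_steps.recording
        labels = label_timepoints(rec, AnnotationSet(rec.profile_id, rec.leg_id, []))
        assert labels.sum() == 0

    def test_count_conservation(self, sim_ten_steps):
        rec, truth = sim_ten_steps.recording, sim_ten_steps.truth
        labels = label_timepoints(rec, truth)
        assert labels.sum() == sum(iv.n_samples for iv in truth.intervals)
        # brute-force membership check
        brute = np.array(
            [any(iv.contains(t) for iv in truth.intervals) for t in range(rec.n_samples)]
        )
        np.testing.assert_array_equal(labels.astype(bool), brute)

    def test_out_of_range_interval_rejected(self, sim_ten_steps):
        rec = sim_ten_steps.recording
        ann = AnnotationSet("p", "1", [StepInterval(0, rec.n_samples + 5)])
        with pytest.raises(ValueError, match="exceeds"):
            label_timepoints(rec, ann)


class TestSplitProfiles:
    IDS = [f"p{i:02d}" for i in range(20)]

    def test_sixty_twenty_twenty_shape(self):
        tr, va, te = split_profiles(self.IDS, (0.6, 0.2, 0.2), seed=1)
        assert (len(tr), len(va), len(te)) == (12, 4, 4)

    def test_deterministic_and_partition(self):
        first = split_profiles(self.IDS, (0.6, 0.2, 0.2), seed=7)
        second = split_profiles(self.IDS, (0.6, 0.2, 0.2), seed=7)
        assert first == second
        tr, va, te = first
        assert tr | va | te == set(self.IDS)
        assert not (tr & va or tr & te or va & te)

    def test_too_few_profiles_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            split_profiles(["a", "b"], (0.6, 0.2, 0.2), seed=0)


def _separable_features(rng, n=600):
    X = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("abcd"))
    y = (np.arange(n) % 2).astype(int)
    X.loc[y == 1, "c"] += 10.0  # cleanly separable on one feature
    return FeatureMatrix(X=X, label=y)


class TestTrain:
    CFG = GbmConfig()

    def test_separable_problem_learned(self):
        rng = np.random.default_rng(0)
        fm = _separable_features(rng)
        holdout = _separable_features(rng)
        clf = train(fm, self.CFG, seed=0, validation=holdout)
        assert clf.metadata["validation_accuracy"] >= 0.99

    def test_same_seed_same_predictions(self):
        rng = np.random.default_rng(1)
        fm = _separable_features(rng)
        holdout = _separable_features(rng)
        p1 = train(fm, self.CFG, seed=3).predict_proba(holdout)
        p2 = train(fm, self.CFG, seed=3).predict_proba(holdout)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_rejected(self):
        rng = np.random.default_rng(2)
        fm = _separable_features(rng)
        fm.label[:] = 1
        with pytest.raises(ValueError, match="single class"):
            train(fm, self.CFG, seed=0)

    def test_schema_guard_rejects_renamed_columns(self):
        rng = np.random.default_rng(3)
        fm = _separable_features(rng)
        clf = train(fm, self.CFG, seed=0)
        renamed = FeatureMatrix(
            X=fm.X.rename(columns={"a": "d", "d": "a"})[list("dbca")]
        )
        with pytest.raises(ValueError, match="schema"):
            clf.predict_proba(renamed)


class TestPredictMask:
    @classmethod
    def setup_class(cls):
        rng = np.random.default_rng(4)
        cls.fm = _separable_features(rng)
        cls.clf = train(cls.fm, GbmConfig(), seed=0)

    def test_threshold_zero_all_true(self):
        assert predict_mask(self.clf, self.fm, 0.0).all()

    def test_threshold_one_requires_certainty(self):
        mask = predict_mask(self.clf, self.fm, 1.0)
        p = self.clf.predict_proba(self.fm)
        np.testing.assert_array_equal(mask, p >= 1.0)

    def test_monotone_in_threshold(self):
        low = predict_mask(self.clf, self.fm, 0.3)
        high = predict_mask(self.clf, self.fm, 0.7)
        assert not (high & ~low).any()


def oracle_mask_to_steps(mask, min_run, merge_gap):
    """Enumerate runs then merge, index by index."""
    runs, start = [], None
    for i, v in enumerate(list(mask) + [False]):
        if v and start is None:
            start = i
        elif not v and start is not None:
            if i - start >= min_run:
                runs.append([start, i])
            start = None
    merged = []
    for run in runs:
        if merged and run[0] - merged[-1][1] <= merge_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    return [(a, b) for a, b in merged]


class TestMaskToSteps:
    def _mask(self, n, runs):
        m = np.zeros(n, dtype=bool)
        for a, b in runs:
            m[a:b] = True
        return m

    def test_minimum_run_length(self):
        assert mask_to_steps(self._mask(200, [(50, 59)])) == []
        assert mask_to_steps(self._mask(200, [(50, 60)])) == [StepInterval(50, 60)]

    def test_merge_within_ten_points(self):
        m = self._mask(200, [(100, 115), (123, 140)])  # gap 8
        assert mask_to_steps(m) == [StepInterval(100, 140)]

    def test_keep_beyond_ten_points(self):
        m = self._mask(200, [(100, 115), (126, 140)])  # gap 11
        assert mask_to_steps(m) == [StepInterval(100, 115), StepInterval(126, 140)]

    def test_merge_is_idempotent(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            m = rng.random(300) < 0.5
            once = mask_to_steps(m)
            again = mask_to_steps(
                self._mask(300, [(iv.start, iv.end) for iv in once]), 1, 10
            )
            assert once == again

    def test_matches_oracle_on_random_masks(self):
        rng = np.random.default_rng(6)
        for _ in range(300):
            m = rng.random(rng.integers(1, 120)) < rng.random()
            got = [(iv.start, iv.end) for iv in mask_to_steps(m, 10, 10)]
            assert got == oracle_mask_to_steps(m, 10, 10)


class TestDetectGbm:
    def test_motionless_recording_detects_nothing(
        self, trained_classifier, constant_recording
    ):
        assert detect_gbm(constant_recording, trained_classifier) == []

    def test_end_to_end_accuracy_on_held_out_profiles(self, benchmark_run):
        """Classifier trained on 12 disjoint profiles segments the 4 test
        profiles accurately at the strict 0.2 s allowance."""
        _, _, suite, clf = benchmark_run
        reports = [
            match_steps(
                res.truth.intervals,
                detect_gbm(res.recording, clf),
                0.2,
                res.recording.sample_rate_hz,
            )
            for res in suite.test
        ]
        m = metrics(pool_reports(reports))
        assert m.f_score is not None and m.f_score >= 0.8

    def test_outputs_sorted_disjoint(self, benchmark_run):
        _, _, suite, clf = benchmark_run
        rec = suite.test[0].recording
        detected = detect_gbm(rec, clf)
        for a, b in zip(detected, detected[1:]):
            assert a.end <= b.start
        assert all(0 <= iv.start < iv.end <= rec.n_samples for iv in detected)

    def test_smaller_delays_than_cpd(self, benchmark_run):
        """Supervised boundaries are tighter than SST's lagged ones."""
        from imustep.cpd_sst import detect_cpd
        from imustep.evaluation import delay_summary

        _, _, suite, clf = benchmark_run

        def mean_abs_start_delay(detector):
            reports = [
                match_steps(
                    res.truth.intervals, detector(res.recording), 1.0, 100.0
                )
                for res in suite.test
            ]
            stats = delay_summary(reports)
            return abs(stats.start_mean_s)

        assert mean_abs_start_delay(
            lambda r: detect_gbm(r, clf)
        ) < mean_abs_start_delay(detect_cpd)
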