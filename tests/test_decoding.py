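"""Tests of bin assignment, sub-averaging and SVM decoding time courses."""

import numpy as np
import pytest

from eegmvpa import (ANIMATE, INANIMATE, DecoderConfig, DecodingTimeCourse,
                     GroupEffectSpec, SyntheticDesign, assign_bins,
                     compare_peak_latency, decode_timecourse, decode_timepoint,
                     decoding_significance, find_onset, find_peak,
                     generate_subject, preprocess_epochs, subaverage)
from eegmvpa.decoding import decode_trials_timepoint


def _stim_table(n_per_class):
    ids = np.arange(2 * n_per_class)
    labels = np.array([ANIMATE] * n_per_class + [INANIMATE] * n_per_class)
    return ids, labels


class TestAssignBins:
    def test_sixteen_by_four_gives_four_bins(self, rng):
        ids, labels = _stim_table(16)
        bins = assign_bins(ids, labels, 4, rng)
        assert len(bins[ANIMATE]) == 4 and len(bins[INANIMATE]) == 4

    def test_sixteen_by_three_drops_one_stimulus(self, rng):
        ids, labels = _stim_table(16)
        bins = assign_bins(ids, labels, 3, rng)
        for cls in (ANIMATE, INANIMATE):
            assert len(bins[cls]) == 5
            used = np.concatenate(bins[cls])
            assert len(used) == 15  # one random leftover excluded

    def test_bins_disjoint_and_class_pure(self, rng):
        ids, labels = _stim_table(16)
        bins = assign_bins(ids, labels, 2, rng)
        for cls in (ANIMATE, INANIMATE):
            used = np.concatenate(bins[cls])
            assert len(used) == len(set(used))  # disjoint
            cls_set = set(ids[labels == cls])
            assert set(used) <= cls_set          # no cross-class leakage

    def test_class_smaller_than_bin_rejected(self, rng):
        ids, labels = _stim_table(2)
        with pytest.raises(ValueError, match="fewer"):
            assign_bins(ids, labels, 3, rng)


class TestSubaverage:
    def test_single_stimulus_bin_equals_trial_mean(self, small_preprocessed, rng):
        ds = small_preprocessed
        stim = int(ds.stimulus_ids[0])
        bins = {ANIMATE: [np.array([stim])]}
        ex = subaverage(ds, bins)
        expected = ds.data[ds.stimulus_ids == stim].mean(axis=0)
        assert np.allclose(ex[ANIMATE][0], expected)

    def test_averaging_reduces_noise_variance(self, rng):
        # pooling k white-noise trials shrinks variance by about 1/k
        from eegmvpa.containers import EpochedDataset
        n_stim, reps, k = 8, 20, 4
        data = rng.standard_normal((n_stim * reps, 5, 10))
        ds = EpochedDataset(
            data=data, times_ms=np.arange(10.0), sfreq=1000.0,
            channel_names=[f"c{i}" for i in range(5)],
            stimulus_ids=np.repeat(np.arange(n_stim), reps),
            class_labels=np.array([ANIMATE] * (n_stim * reps), dtype=object))
        bins = {ANIMATE: [np.arange(k)]}
        ex = subaverage(ds, bins)
        ratio = ex[ANIMATE][0].var() / data.var()
        assert ratio == pytest.approx(1.0 / (k * reps), rel=0.4)


class TestDecodeTimepoint:
    def test_separable_exemplars_decoded_perfectly(self):
        ex = {ANIMATE: np.array([[-1.0, 0.0], [-1.0, 0.1], [-0.9, 0.0]]),
              INANIMATE: np.array([[1.0, 0.0], [1.0, 0.1], [0.9, 0.0]])}
        assert decode_timepoint(ex) == 1.0

    def test_adversarial_geometry_decoded_at_zero(self):
        # each fold's training points sit on the opposite side of the
        # held-out pair, so every prediction flips: a hand-checkable oracle
        ex = {ANIMATE: np.array([[-1.0, 0.0], [2.0, 0.0]]),
              INANIMATE: np.array([[1.0, 0.0], [-2.0, 0.0]])}
        assert decode_timepoint(ex) == 0.0

    def test_identical_exemplars_fall_back_to_chance(self):
        ex = {ANIMATE: np.ones((3, 4)), INANIMATE: np.ones((3, 4))}
        with pytest.warns(UserWarning, match="identical"):
            assert decode_timepoint(ex) == 0.5

    def test_no_signal_accuracy_near_chance(self, rng):
        # no class signal: accuracy conditioned on one dataset fluctuates
        # (few stimuli), but the mean over independent datasets sits at 0.5
        n_stim, reps = 16, 6
        cfg = DecoderConfig(n_repetitions=20, seed=0)
        accs = []
        for _ in range(10):
            X = rng.standard_normal((2 * n_stim * reps, 20))
            ids = np.repeat(np.arange(2 * n_stim), reps)
            labels = np.repeat(np.array([ANIMATE, INANIMATE] * n_stim), reps)
            accs.append(decode_trials_timepoint(X, ids, labels, cfg, rng))
        assert np.mean(accs) == pytest.approx(0.5, abs=0.12)

    def test_channel_reordering_invariance(self, rng):
        n_stim, reps = 8, 4
        X = rng.standard_normal((2 * n_stim * reps, 10))
        X[:n_stim * reps, :3] += 1.5
        ids = np.repeat(np.arange(2 * n_stim), reps)
        labels = np.array([ANIMATE] * (n_stim * reps) + [INANIMATE] * (n_stim * reps))
        cfg = DecoderConfig(n_repetitions=25, seed=0)
        a = decode_trials_timepoint(X, ids, labels, cfg, np.random.default_rng(3))
        perm = rng.permutation(10)
        b = decode_trials_timepoint(X[:, perm], ids, labels, cfg,
                                    np.random.default_rng(3))
        assert a == pytest.approx(b, abs=1e-12)


class TestPeakAndOnset:
    def _course(self, times, acc):
        return DecodingTimeCourse(times_ms=np.asarray(times, dtype=float),
                                  accuracy=np.asarray(acc, dtype=float))

    def test_monotone_rising_peaks_at_last_sample(self):
        c = self._course([-50, 0, 50, 100], [0.5, 0.6, 0.7, 0.8])
        t, a = find_peak(c)
        assert (t, a) == (100.0, 0.8)

    def test_flat_curve_breaks_ties_earliest(self):
        c = self._course([-50, 10, 20, 30], [0.6, 0.6, 0.6, 0.6])
        t, _ = find_peak(c)
        assert t == 10.0  # earliest post-stimulus sample

    def test_prestimulus_maximum_ignored(self):
        c = self._course([-50, 10, 20], [0.9, 0.6, 0.7])
        t, a = find_peak(c)
        assert (t, a) == (20.0, 0.7)

    def test_onset_is_first_significant_poststimulus_point(self):
        c = self._course([-50, 10, 20, 30], [0.5, 0.5, 0.8, 0.8])
        flags = np.array([True, False, True, True])
        assert find_onset(c, flags) == 20.0

    def test_onset_without_significance_is_none(self):
        c = self._course([10, 20], [0.5, 0.5])
        assert find_onset(c, np.zeros(2, dtype=bool)) is None


class TestTimecourse:
    def test_peak_recovered_near_injected_latency(self):
        design = SyntheticDesign(sfreq_acquisition=100)
        eff = GroupEffectSpec(signal_amplitude={"HC": 2.5, "MCI": 2.5},
                              latency_jitter_ms=0.0, amplitude_jitter_sd=0.0)
        rec = generate_subject(design, eff, "HC", seed=21)
        pre = preprocess_epochs(rec.dataset)
        cfg = DecoderConfig(n_repetitions=15, seed=0)
        course = decode_timecourse(pre, cfg, times_ms=np.arange(100, 320, 20))
        assert abs(course.peak_time_ms - 200.0) <= 20.0
        assert course.peak_accuracy > 0.9

    def test_empty_channel_group_rejected(self, small_preprocessed):
        from eegmvpa import ChannelGroupMap
        gmap = ChannelGroupMap({"one": [0]})
        with pytest.raises(ValueError, match="group_map"):
            decode_timecourse(small_preprocessed, channel_group="one")
        # restricting to a named group works (bin size 2: 4 stimuli/class)
        cfg = DecoderConfig(n_repetitions=3, bin_sizes=(2,), seed=0)
        c = decode_timecourse(small_preprocessed, cfg, times_ms=[200.0],
                              channel_group="one", group_map=gmap)
        assert c.accuracy.shape == (1,)


class TestPeakLatencyComparison:
    def _courses(self, peaks):
        out = []
        for p in peaks:
            times = np.arange(0.0, 400.0, 20.0)
            acc = np.exp(-0.5 * ((times - p) / 40.0) ** 2) * 0.4 + 0.5
            out.append(DecodingTimeCourse(times_ms=times, accuracy=acc))
        return out

    def test_identical_groups_near_half_p(self, rng):
        peaks = rng.uniform(150, 250, size=10)
        res = compare_peak_latency(self._courses(peaks), self._courses(peaks),
                                   n_boot=400, rng=0)
        assert res.statistic == 0.0
        assert res.p_value > 0.2

    def test_shifted_group_detected(self, rng):
        hc = rng.normal(180, 15, size=10)
        res = compare_peak_latency(self._courses(hc), self._courses(hc + 60),
                                   n_boot=400, rng=1)
        assert res.p_value < 0.05
        lo, hi = res.extras["ci95"]
        assert lo <= 60.0 <= hi

    def test_minimum_p_matches_add_one_formula(self, rng):
        hc = rng.normal(150, 5, size=12)
        res = compare_peak_latency(self._courses(hc), self._courses(hc + 150),
                                   n_boot=10_000, rng=2)
        assert res.p_value == pytest.approx(1 / 10_001)
        assert round(res.p_value, 4) == 0.0001


class TestCohortSignificance:
    def test_no_signal_no_flags_and_chance_mean(self, rng):
        # antithetic pairs center the cohort mean exactly at chance
        half = rng.normal(0.0, 0.05, size=(5, 10))
        accs = np.concatenate([0.5 + half, 0.5 - half])
        courses = [DecodingTimeCourse(times_ms=np.arange(0.0, 100.0, 10.0),
                                      accuracy=a) for a in accs]
        flags, _, _ = decoding_significance(courses, n_boot=300, rng=0)
        assert not flags.any()

    def test_strong_signal_flagged_and_onset_set(self, rng):
        times = np.arange(-20.0, 100.0, 10.0)
        courses = []
        for _ in range(10):
            acc = np.full(times.size, 0.5) + rng.normal(0, 0.01, times.size)
            acc[times >= 50.0] += 0.3
            courses.append(DecodingTimeCourse(times_ms=times, accuracy=acc))
        flags, _, _ = decoding_significance(courses, n_boot=300, rng=1)
        assert flags[times >= 50.0].all()
        assert courses[0].onset_time_ms == 50.0
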