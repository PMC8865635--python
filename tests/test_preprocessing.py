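"""Tests of the preprocessing stages."""

import numpy as np
import pytest

from eegmvpa import (ContinuousRecording, EpochedDataset, GroupEffectSpec,
                     PreprocessConfig, SyntheticDesign, baseline_normalize,
                     epoch, generate_continuous_session, generate_subject,
                     lowpass, preprocess_pipeline, remove_eog_component,
                     rereference_average, resample)
from eegmvpa.containers import default_channel_names


def _sine_epochs(freq_hz, sfreq=1200.0, n_trials=2, n_channels=3):
    """Epoched pure sinusoid for filter characterization."""
    d = SyntheticDesign(sfreq_acquisition=sfreq)
    times = d.epoch_times_ms(sfreq)
    wave = np.sin(2 * np.pi * freq_hz * times / 1000.0)
    data = np.tile(wave, (n_trials, n_channels, 1))
    return EpochedDataset(
        data=data, times_ms=times, sfreq=sfreq,
        channel_names=[f"CH{i}" for i in range(n_channels)],
        stimulus_ids=np.arange(n_trials),
        class_labels=np.array(["animate"] * n_trials, dtype=object))


class TestRereference:
    def test_64_to_63_channels_and_zero_sum(self, small_subject):
        out = rereference_average(small_subject.dataset)
        scalp = [n for n in out.channel_names if not n.startswith("EOG")]
        assert len(scalp) == 63
        assert "REF" not in out.channel_names
        scalp_idx = [out.channel_names.index(n) for n in scalp]
        sums = out.data[:, scalp_idx, :].sum(axis=1)
        assert np.max(np.abs(sums)) < 1e-9

    def test_constant_channels_become_zero(self):
        names = default_channel_names()
        data = np.full((len(names), 50), 3.7)
        rec = ContinuousRecording(data=data, sfreq=100.0, channel_names=names)
        rec.data[[i for i, n in enumerate(names) if n.startswith("EOG")]] = 0.0
        rec.data[names.index("REF")] = 3.7
        out = rereference_average(rec)
        scalp = [i for i, n in enumerate(out.channel_names)
                 if not n.startswith("EOG")]
        assert np.max(np.abs(out.data[scalp])) < 1e-12

    def test_missing_reference_rejected(self, small_subject):
        once = rereference_average(small_subject.dataset)
        with pytest.raises(ValueError, match="reference"):
            rereference_average(once)


class TestEpoching:
    def test_sample_count_at_acquisition_rate(self):
        # [-100, 800) ms at 1200 Hz holds exactly 1080 samples
        rec = ContinuousRecording(data=np.zeros((2, 3000)), sfreq=1200.0,
                                  channel_names=["a", "b"],
                                  events=[(1500, 0, "animate")])
        ds = epoch(rec, window_ms=(-100.0, 800.0))
        assert ds.n_times == 1080
        assert ds.times_ms[0] == -100.0
        assert ds.times_ms[-1] < 800.0

    def test_empty_event_list(self):
        rec = ContinuousRecording(data=np.zeros((2, 500)), sfreq=100.0,
                                  channel_names=["a", "b"], events=[])
        ds = epoch(rec, window_ms=(-100.0, 300.0))
        assert ds.n_trials == 0

    def test_out_of_bounds_events_dropped(self):
        rec = ContinuousRecording(data=np.zeros((1, 200)), sfreq=100.0,
                                  channel_names=["a"],
                                  events=[(5, 0, "animate"), (100, 1, "inanimate")])
        with pytest.warns(UserWarning, match="dropped"):
            ds = epoch(rec, window_ms=(-100.0, 300.0))
        assert ds.n_trials == 1
        assert ds.stimulus_ids.tolist() == [1]

    def test_epoch_content_alignment(self):
        data = np.arange(300.0)[None, :]
        rec = ContinuousRecording(data=data, sfreq=1000.0, channel_names=["a"],
                                  events=[(150, 0, "animate")])
        ds = epoch(rec, window_ms=(-10.0, 20.0))
        assert ds.n_times == 30
        assert ds.data[0, 0, 0] == 140.0       # -10 ms sample
        assert ds.data[0, 0, 10] == 150.0      # t = 0 on the post side


class TestBaseline:
    def test_baseline_mean_zero_sd_one(self, small_subject):
        out = baseline_normalize(rereference_average(small_subject.dataset))
        base = out.data[:, :, out.baseline_mask()]
        assert np.max(np.abs(base.mean(axis=2))) < 1e-10
        assert np.max(np.abs(base.std(axis=2) - 1.0)) < 1e-10

    def test_idempotent(self, rng):
        d = SyntheticDesign(sfreq_acquisition=100)
        data = rng.standard_normal((4, 3, d.n_epoch_samples()))
        ds = EpochedDataset(data=data, times_ms=d.epoch_times_ms(), sfreq=100.0,
                            channel_names=["a", "b", "c"],
                            stimulus_ids=np.arange(4),
                            class_labels=np.array(["animate"] * 4, dtype=object))
        once = baseline_normalize(ds)
        twice = baseline_normalize(once)
        assert np.allclose(once.data, twice.data, atol=1e-12)

    def test_constant_epoch_becomes_zero_with_warning(self):
        d = SyntheticDesign(sfreq_acquisition=100)
        ds = EpochedDataset(data=np.full((1, 2, d.n_epoch_samples()), 5.0),
                            times_ms=d.epoch_times_ms(), sfreq=100.0,
                            channel_names=["a", "b"],
                            stimulus_ids=np.array([0]),
                            class_labels=np.array(["animate"], dtype=object))
        with pytest.warns(UserWarning, match="zero SD"):
            out = baseline_normalize(ds)
        assert np.all(out.data == 0.0)


class TestFilterAndResample:
    def test_passband_preserved(self):
        ds = _sine_epochs(10.0)
        out = lowpass(ds, 50.0)
        sl = slice(200, 880)  # avoid edge effects
        ratio = out.data[0, 0, sl].std() / ds.data[0, 0, sl].std()
        assert ratio == pytest.approx(1.0, abs=0.01)

    def test_stopband_attenuated(self):
        ds = _sine_epochs(100.0)
        out = lowpass(ds, 50.0)
        sl = slice(200, 880)
        ratio = out.data[0, 0, sl].std() / ds.data[0, 0, sl].std()
        assert ratio < 0.1

    def test_dc_unchanged(self):
        ds = _sine_epochs(10.0)
        ds.data[:] = 2.5
        out = lowpass(ds, 50.0)
        assert np.allclose(out.data, 2.5, atol=1e-6)

    def test_zero_phase_keeps_pulse_peak(self):
        ds = _sine_epochs(10.0)
        ds.data[:] = 0.0
        peak_sample = 500
        ds.data[:, :, peak_sample] = 1.0
        out = lowpass(ds, 50.0)
        assert abs(int(np.argmax(out.data[0, 0])) - peak_sample) <= 1

    def test_cutoff_above_nyquist_rejected(self):
        ds = _sine_epochs(10.0, sfreq=80.0)
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass(ds, 50.0)

    def test_resample_1200_to_1000_gives_900_samples(self):
        ds = _sine_epochs(10.0)
        out = resample(ds, 1000.0)
        assert out.n_times == 900
        assert out.sfreq == 1000.0
        assert out.times_ms[0] == -100.0

    def test_resample_identity(self):
        ds = _sine_epochs(10.0)
        out = resample(ds, ds.sfreq)
        assert np.array_equal(out.data, ds.data)

    def test_band_limited_waveform_preserved(self):
        ds = _sine_epochs(10.0)
        out = resample(lowpass(ds, 50.0), 1000.0)
        expected = np.sin(2 * np.pi * 10.0 * out.times_ms / 1000.0)
        sl = slice(100, 800)
        dev = np.max(np.abs(out.data[0, 0, sl] - expected[sl]))
        assert dev < 0.01 * 2.0  # < 1% of the peak-to-peak range

    def test_upsampling_rejected(self):
        ds = _sine_epochs(10.0, sfreq=100.0)
        with pytest.raises(ValueError, match="upsampling"):
            resample(ds, 200.0)


class TestEogRemoval:
    @pytest.fixture
    def blinky(self, small_effects):
        d = SyntheticDesign(n_runs=2, n_animate=4, n_inanimate=4,
                            sfreq_acquisition=100)
        return d, generate_continuous_session(d, small_effects, "HC",
                                              blink_rate=25.0, seed=8,
                                              soa_ms=700.0)

    def test_cleanup_reduces_frontal_eog_correlation(self, blinky):
        _, rec = blinky
        cleaned = remove_eog_component(rec, seed=0)
        fp = rec.channel_names.index("Fp1")
        eog = rec.eog_indices()[0]

        def corr(r):
            return abs(np.corrcoef(r.data[fp], r.data[eog])[0, 1])

        assert corr(cleaned) < corr(rec)

    def test_blink_free_data_nearly_unchanged(self, small_effects):
        d = SyntheticDesign(n_runs=2, n_animate=4, n_inanimate=4,
                            sfreq_acquisition=100)
        rec = generate_continuous_session(d, small_effects, "HC",
                                          blink_rate=0.0, seed=9, soa_ms=700.0)
        cleaned = remove_eog_component(rec, seed=0)
        scalp = [i for i in range(rec.n_channels) if i not in rec.eog_indices()]
        # only one of up to 20 components is removed from pure noise
        resid = np.linalg.norm(cleaned.data[scalp] - rec.data[scalp])
        total = np.linalg.norm(rec.data[scalp])
        assert resid / total < 0.35

    def test_zero_variance_eog_warns_and_noop(self, blinky):
        _, rec = blinky
        rec.data[rec.eog_indices()] = 0.0
        with pytest.warns(UserWarning, match="zero variance"):
            out = remove_eog_component(rec)
        assert np.array_equal(out.data, rec.data)


class TestPipeline:
    def test_end_to_end_matches_epoched_generator(self, small_effects):
        d = SyntheticDesign(n_runs=2, n_animate=3, n_inanimate=3,
                            sfreq_acquisition=100)
        rec = generate_continuous_session(d, small_effects, "HC",
                                          blink_rate=5.0, seed=10, soa_ms=1000.0)
        cfg = PreprocessConfig(lowpass_hz=30.0, resample_hz=None, ica_seed=0)
        ds = preprocess_pipeline(rec, config=cfg)
        direct = generate_subject(d, small_effects, "HC", seed=10)
        assert ds.n_trials == direct.dataset.n_trials
        assert ds.n_channels == d.n_scalp_channels
        stages = [p["stage"] for p in ds.provenance]
        # the stage order is part of the contract: normalize before filter
        assert stages.index("baseline_normalize") < stages.index("lowpass")
        assert stages.index("rereference_average") < stages.index("epoch")

    def test_pipeline_deterministic_given_seed(self, small_effects):
        d = SyntheticDesign(n_runs=2, n_animate=3, n_inanimate=3,
                            sfreq_acquisition=100)
        cfg = PreprocessConfig(lowpass_hz=None, resample_hz=None, ica_seed=3)
        outs = []
        for _ in range(2):
            rec = generate_continuous_session(d, small_effects, "HC",
                                              blink_rate=5.0, seed=11,
                                              soa_ms=1000.0)
            outs.append(preprocess_pipeline(rec, config=cfg))
        assert np.array_equal(outs[0].data, outs[1].data)
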