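"""Cleaning chain: filtering, resampling, bad channels, line noise,
referencing and the composed preprocess operation."""

import numpy as np
import pytest

from rtmspredict import (
    EEGRecording,
    PreprocessConfig,
    SyntheticCohortConfig,
    bandpass,
    detect_bad_channels,
    generate_cohort,
    preprocess,
    remove_line_noise,
    rereference_average,
    resample_to,
    welch_band_power,
)
from rtmspredict.preprocessing import InsufficientDataError


def _rec(data, fs=1000.0, montage=None):
    n_ch = data.shape[0]
    labels = [f"C{i}" for i in range(n_ch)]
    positions = {lb: np.array([float(i), 0.0, 0.0]) for i, lb in enumerate(labels)}
    return EEGRecording(data=data, fs=fs, labels=labels, positions=positions)


class TestBandpass:
    def test_constant_channel_becomes_zero(self):
        rec = _rec(np.full((2, 5000), 7.0))
        out = bandpass(rec, 1.0, 60.0)
        assert np.allclose(out.data, 0.0, atol=1e-6)

    def test_in_band_sine_preserved(self):
        t = np.arange(5000) / 250.0
        rec = _rec(np.sin(2 * np.pi * 10 * t)[None, :], fs=250.0)
        out = bandpass(rec, 1.0, 60.0)
        mid = slice(500, 4500)  # avoid filter edges
        assert np.abs(out.data[0, mid]).max() == pytest.approx(1.0, rel=0.05)

    def test_out_of_band_sine_attenuated_20db(self):
        t = np.arange(10000) / 1000.0
        rec = _rec(np.sin(2 * np.pi * 80 * t)[None, :], fs=1000.0)
        out = bandpass(rec, 1.0, 60.0)
        rms_in = np.sqrt(np.mean(rec.data**2))
        rms_out = np.sqrt(np.mean(out.data[0, 1000:-1000] ** 2))
        assert 20 * np.log10(rms_in / rms_out) >= 20.0

    def test_band_violating_nyquist_rejected(self):
        rec = _rec(np.zeros((1, 1000)), fs=100.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(rec, 1.0, 60.0)


class TestResample:
    def test_sample_count(self):
        rec = _rec(np.random.default_rng(0).standard_normal((2, 300 * 1000)))
        out = resample_to(rec, 250.0)
        assert out.data.shape == (2, 75_000)
        assert out.fs == 250.0

    def test_sine_preserved_through_resampling(self):
        t = np.arange(20_000) / 1000.0
        rec = _rec(np.sin(2 * np.pi * 5 * t)[None, :])
        out = resample_to(rec, 250.0)
        ref = np.sin(2 * np.pi * 5 * np.arange(out.n_samples) / 250.0)
        r = np.corrcoef(out.data[0], ref)[0, 1]
        assert r > 0.999

    def test_identity_and_upsampling_guard(self):
        rec = _rec(np.random.default_rng(1).standard_normal((1, 4000)), fs=250.0)
        assert np.allclose(resample_to(rec, 250.0).data, rec.data)
        with pytest.raises(ValueError, match="upsampling"):
            resample_to(rec, 500.0)


class TestBadChannels:
    def test_single_scaled_channel_flagged(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((32, 4000))
        data[13] *= 20.0
        rec = _rec(data, fs=250.0)
        assert detect_bad_channels(rec, 3.1) == [rec.labels[13]]

    def test_identical_channels_give_empty_list(self):
        rec = _rec(np.tile(np.arange(1000.0), (5, 1)), fs=250.0)
        assert detect_bad_channels(rec) == []

    def test_unreachable_threshold_gives_empty_list(self):
        rec = _rec(np.random.default_rng(2).standard_normal((8, 1000)), fs=250.0)
        assert detect_bad_channels(rec, k=1e9) == []


class TestLineNoise:
    def test_pure_line_reduced_15db(self):
        rng = np.random.default_rng(0)
        t = np.arange(30_000) / 250.0
        x = 5 * np.sin(2 * np.pi * 50 * t) + rng.standard_normal(len(t))
        rec = _rec(x[None, :], fs=250.0)
        out = remove_line_noise(rec, 50.0)
        before = welch_band_power(rec.data[0], 250.0, (49.5, 50.5))
        after = welch_band_power(out.data[0], 250.0, (49.5, 50.5))
        assert 10 * np.log10(before / after) >= 15.0

    def test_no_notch_hole_in_neighbourhood(self):
        rng = np.random.default_rng(1)
        t = np.arange(60_000) / 250.0
        noise = rng.standard_normal(len(t))
        x = 5 * np.sin(2 * np.pi * 50 * t) + noise
        rec = _rec(x[None, :], fs=250.0)
        out = remove_line_noise(rec, 50.0)
        # broadband power next to the line must survive (compare against the
        # line-free noise floor, which is free of leakage from the line)
        def side(data):
            return (welch_band_power(data, 250.0, (47.0, 49.0))
                    + welch_band_power(data, 250.0, (51.0, 53.0)))
        assert side(out.data[0]) > 0.8 * side(noise)

    def test_clean_signal_left_untouched(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(10_000)
        rec = _rec(x[None, :], fs=250.0)
        out = remove_line_noise(rec, 50.0)
        assert np.sqrt(np.mean(out.data**2)) == pytest.approx(
            np.sqrt(np.mean(x**2)), rel=0.02
        )

    def test_drifting_amplitude_removed(self):
        rng = np.random.default_rng(3)
        t = np.arange(50_000) / 250.0
        amp = 3 + 2 * np.sin(2 * np.pi * 0.05 * t)
        x = amp * np.sin(2 * np.pi * 50 * t) + 0.5 * rng.standard_normal(len(t))
        rec = _rec(x[None, :], fs=250.0)
        out = remove_line_noise(rec, 50.0)
        before = welch_band_power(rec.data[0], 250.0, (49.5, 50.5))
        after = welch_band_power(out.data[0], 250.0, (49.5, 50.5))
        assert after < 0.1 * before


class TestAverageReference:
    def test_column_means_vanish(self):
        rec = _rec(np.random.default_rng(0).standard_normal((6, 2000)), fs=250.0)
        out = rereference_average(rec)
        assert np.abs(out.data.mean(axis=0)).max() < 1e-10

    def test_idempotent(self):
        rec = _rec(np.random.default_rng(1).standard_normal((6, 2000)), fs=250.0)
        once = rereference_average(rec)
        twice = rereference_average(once)
        assert np.allclose(once.data, twice.data)

    def test_antisymmetric_pair_unchanged(self):
        rec = _rec(np.vstack([np.ones(100), -np.ones(100)]), fs=250.0)
        assert np.allclose(rereference_average(rec).data, rec.data)


class TestPreprocessChain:
    def test_output_shape_rate_and_reference(self):
        cfg = SyntheticCohortConfig(n_responders=1, n_nonresponders=1,
                                    duration_s=20.0, fs=1000.0, seed=5)
        rec = generate_cohort(cfg)[0][0]
        out = preprocess(rec, PreprocessConfig(keep_duration_s=16.0))
        assert out.fs == 250.0
        assert out.n_samples == 16 * 250
        assert out.n_channels in (31, 32)  # one injected bad channel
        assert np.abs(out.data.mean(axis=0)).max() < 1e-9
        assert np.isfinite(out.data).all()
        assert len(out.log) >= 4

    def test_bad_channel_detection_matches_truth(self, contrast_cohort):
        hits = 0
        recordings = contrast_cohort["recordings"]
        truth = contrast_cohort["truth"]
        for rec, rep in zip(recordings, contrast_cohort["reports"]):
            true_bad = set(truth["subjects"][rec.subject_id]["bad_channels"])
            excluded = {lb for line in rep["log"] if "excluded bad" in line
                        for lb in true_bad if f"'{lb}'" in line}
            hits += excluded == true_bad
        assert hits / len(recordings) >= 0.95

    def test_near_idempotence_of_signal_path(self):
        """Filtering/line-removal/referencing do not compound on a second
        pass.  Compared over the channels both passes keep: the SD-outlier
        channel rule may legitimately cascade when the strongest genuine
        channel becomes the outlier once a truly bad channel is gone."""
        cfg = SyntheticCohortConfig(n_responders=1, n_nonresponders=1,
                                    duration_s=24.0, fs=250.0, seed=6)
        rec = generate_cohort(cfg)[0][0]
        once = preprocess(rec, PreprocessConfig(keep_duration_s=20.0))
        twice = preprocess(once, PreprocessConfig(keep_duration_s=20.0))
        common = [lb for lb in twice.labels if lb in once.labels]
        a = once.data[[once.labels.index(lb) for lb in common]]
        b = twice.data[[twice.labels.index(lb) for lb in common]]
        rms1 = np.sqrt(np.mean(a**2))
        rms2 = np.sqrt(np.mean(b**2))
        assert abs(rms2 - rms1) / rms1 < 0.01

    def test_short_recording_rejected(self):
        cfg = SyntheticCohortConfig(n_responders=1, n_nonresponders=1,
                                    duration_s=20.0, fs=250.0, seed=7)
        rec = generate_cohort(cfg)[0][0]
        with pytest.raises(InsufficientDataError):
            preprocess(rec, PreprocessConfig(keep_duration_s=300.0))
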