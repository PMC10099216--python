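"""Resampling, windowing, STFT, log-frequency mapping, normalisation, RGB."""

import numpy as np
import pytest

from mmldms.preprocessing import (
    NormStats,
    StftConfig,
    WindowSpec,
    amplitude_to_db,
    compute_spectrogram,
    extract_windows,
    fit_modality_norm,
    jet_colormap,
    map_to_log_frequency,
    render_rgb,
    standardize_sampling,
)

CFG = StftConfig()


class TestStandardizeSampling:
    def test_conforming_input_unchanged(self, rng):
        x = rng.standard_normal(1024)
        np.testing.assert_array_equal(standardize_sampling(x, 512, 512), x)

    def test_upsample_sample_count(self):
        x = np.zeros(30 * 256)
        assert standardize_sampling(x, 256, 512).size == 30 * 512

    def test_band_limited_upsampling_matches_analytic_sine(self):
        t_src = np.arange(int(4 * 128)) / 128
        x = np.sin(2 * np.pi * 5.0 * t_src)
        y = standardize_sampling(x, 128, 512)
        t_dst = np.arange(y.size) / 512
        ref = np.sin(2 * np.pi * 5.0 * t_dst)
        core = slice(int(0.5 * 512), -int(0.5 * 512))
        assert np.abs(y[core] - ref[core]).max() < 1e-3

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError, match="finite"):
            standardize_sampling(np.array([1.0, np.nan]), 256, 512)


class TestWindowing:
    def test_default_count_is_21_per_epoch(self, small_cohort):
        record = small_cohort[0]
        wins = extract_windows(record, "EEG", "EEG", WindowSpec())
        assert len(wins) == 21 * record.n_epochs

    def test_consecutive_windows_overlap_90_percent(self, small_cohort):
        wins = extract_windows(small_cohort[0], "EEG", "EEG", WindowSpec())
        a, b = wins[0], wins[1]
        shared = int(9 * 512)
        np.testing.assert_array_equal(a.samples[512:], b.samples[:shared])
        assert shared / a.samples.size == 0.9

    def test_labels_match_parent_epoch_exhaustively(self, small_cohort):
        for record in small_cohort:
            stages = {a.epoch_index: a.stage for a in record.annotations}
            for w in extract_windows(record, "EMG", "EMG", WindowSpec()):
                assert w.stage == stages[w.epoch_index]
                assert w.disorder == record.disorder
                assert 0 <= w.offset_s <= 20.0

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            WindowSpec(window_len=10, stride=11, epoch_len=30)


class TestSpectrogram:
    def test_zero_window_zero_spectrogram(self):
        mag, _, _ = compute_spectrogram(np.zeros(5120), CFG)
        assert np.all(mag == 0)

    def test_sine_peaks_at_nearest_native_bin(self):
        t = np.arange(5120) / 512
        mag, freqs, _ = compute_spectrogram(np.sin(2 * np.pi * 32.0 * t), CFG)
        target = np.argmin(np.abs(freqs - 32.0))
        assert np.all(mag.argmax(axis=0) == target)

    def test_magnitude_is_homogeneous(self, rng):
        x = rng.standard_normal(5120)
        a, _, _ = compute_spectrogram(x, CFG)
        b, _, _ = compute_spectrogram(2 * x, CFG)
        np.testing.assert_allclose(b, 2 * a, rtol=1e-10)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="5120"):
            compute_spectrogram(np.zeros(5000), CFG)


class TestLogFrequencyMapping:
    def test_centers_are_geometric(self):
        centers = CFG.log_bin_centers()
        ratios = centers[1:] / centers[:-1]
        assert np.abs(ratios - ratios[0]).max() < 1e-9
        assert centers[0] == CFG.fmin and centers[-1] == CFG.target_rate / 2

    def test_narrowband_energy_lands_on_nearest_log_bin(self):
        t = np.arange(5120) / 512
        mag, freqs, times = compute_spectrogram(np.sin(2 * np.pi * 4.0 * t), CFG)
        out = map_to_log_frequency(mag, freqs, times, CFG)
        centers = CFG.log_bin_centers()
        nearest = np.argmin(np.abs(np.log(centers) - np.log(4.0)))
        # interior columns only: boundary frames are half zero-padding
        n = out.shape[1]
        interior = out[:, n // 10 : -n // 10]
        assert np.all(np.abs(interior.argmax(axis=0) - nearest) <= 1)

    def test_constant_spectrum_maps_to_constant(self):
        freqs = np.linspace(0, 256, 257)
        times = np.linspace(0, 10, 41)
        out = map_to_log_frequency(np.full((257, 41), 3.5), freqs, times, CFG)
        np.testing.assert_allclose(out, 3.5, rtol=1e-12)
        assert out.shape == (CFG.n_freq_bins, CFG.n_time_bins)

    def test_fmin_must_be_positive(self):
        with pytest.raises(ValueError):
            StftConfig(fmin=0.0)


class TestNormalization:
    def test_average_of_minima_and_maxima(self):
        imgs = [np.array([[0.0, 10.0]]), np.array([[2.0, 14.0]])]
        stats = fit_modality_norm(imgs, "EEG")
        assert stats.avg_min == 1.0 and stats.avg_max == 12.0

    def test_single_image_uses_own_range(self):
        stats = fit_modality_norm([np.array([[3.0, 9.0]])], "ECG")
        assert (stats.avg_min, stats.avg_max) == (3.0, 9.0)

    def test_permutation_invariant(self, rng):
        imgs = [rng.standard_normal((8, 8)) for _ in range(10)]
        a = fit_modality_norm(imgs, "EMG")
        b = fit_modality_norm(imgs[::-1], "EMG")
        assert np.isclose(a.avg_min, b.avg_min, rtol=1e-12)
        assert np.isclose(a.avg_max, b.avg_max, rtol=1e-12)

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            NormStats("EEG", 5.0, 5.0)


class TestRgbRendering:
    def test_jet_matches_matplotlib_reference(self):
        from matplotlib import colormaps

        x = np.linspace(0, 1, 257)
        ours = jet_colormap(x)
        ref = colormaps["jet"](x)[:, :3]
        assert np.abs(ours - ref).max() < 0.02  # reference LUT is 256-sampled

    def test_extremes_map_to_jet_endpoints(self):
        norm = NormStats("EEG", 0.0, 10.0)
        img = render_rgb(np.array([[0.0, 10.0], [-5.0, 25.0]]), norm, 2)
        lo = np.round(jet_colormap(np.array(0.0)) * 255).astype(np.uint8)
        hi = np.round(jet_colormap(np.array(1.0)) * 255).astype(np.uint8)
        np.testing.assert_array_equal(img.pixels[1, 0], lo)  # avg_min (bottom row)
        np.testing.assert_array_equal(img.pixels[1, 1], hi)
        np.testing.assert_array_equal(img.pixels[0, 0], lo)  # clamped below
        np.testing.assert_array_equal(img.pixels[0, 1], hi)  # clamped above

    def test_global_offset_saturates_opposite_ends(self, rng):
        norm = NormStats("EEG", -10.0, 30.0)
        base = rng.uniform(-5, 5, (16, 16)) - 20.0  # everything below avg_min
        low = render_rgb(base, norm, 16)
        high = render_rgb(base + 2 * (norm.avg_max - norm.avg_min), norm, 16)
        lo = np.round(jet_colormap(np.array(0.0)) * 255).astype(np.uint8)
        hi = np.round(jet_colormap(np.array(1.0)) * 255).astype(np.uint8)
        assert np.all(low.pixels == lo)
        assert np.all(high.pixels == hi)

    def test_output_contract(self, rng):
        norm = NormStats("ECG", 0.0, 1.0)
        img = render_rgb(rng.uniform(0, 1, (64, 48)), norm, 32)
        assert img.pixels.shape == (32, 32, 3)
        assert img.pixels.dtype == np.uint8

    def test_low_frequencies_at_bottom(self):
        norm = NormStats("EEG", 0.0, 1.0)
        spec = np.zeros((4, 4))
        spec[0, :] = 1.0  # row 0 = lowest frequency, hot
        img = render_rgb(spec, norm, 4)
        hi = np.round(jet_colormap(np.array(1.0)) * 255).astype(np.uint8)
        np.testing.assert_array_equal(img.pixels[3, 0], hi)

    def test_end_to_end_determinism_bit_identical(self, small_cohort, tmp_path):
        from mmldms.signal_io import write_image_dataset

        record = small_cohort[0]
        paths = []
        for run in range(2):
            w = extract_windows(record, "EEG", "EEG", WindowSpec())[0]
            mag, freqs, times = compute_spectrogram(w.samples, CFG)
            spec_db = amplitude_to_db(map_to_log_frequency(mag, freqs, times, CFG))
            norm = fit_modality_norm([spec_db], "EEG")
            img = render_rgb(spec_db, norm, 64, record_id=w.record_id,
                             stage=w.stage, disorder=w.disorder)
            manifest = write_image_dataset([img], tmp_path / f"run{run}")
            paths.append(next(manifest.parent.glob("*.png")))
        assert paths[0].read_bytes() == paths[1].read_bytes()
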