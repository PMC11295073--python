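"""Artifact rejection, TFR convolution, baseline normalization, band power."""

import numpy as np
import pandas as pd
import pytest

from effortdm.spectral import (BandSpec, LFPEpochSet, TFRGrid, baseline_correct,
                               compute_tfr, detect_beta_peak,
                               extract_band_power, reject_artifact_trials,
                               sliding_band_power, taper_length_samples)

FS = 422.0


def make_epochs(data, fs=FS, t0=-2.0, channels=("ch",)):
    data = np.asarray(data, float)
    return LFPEpochSet(data=data, fs=fs, t0=t0, channels=list(channels),
                       regions={c: "BG" for c in channels},
                       trial_ids=np.arange(data.shape[0]), participant="T")


def direct_dft_power(epochs, channel, freq, t, n_cycles=4):
    """Independent oracle: Hanning-windowed segment DFT at the matching bin.

    A 4-cycle window always places the analysis frequency exactly at DFT bin
    4 of the segment, so the convolution coefficient equals a plain windowed
    DFT evaluated on the centered segment.
    """
    ci = epochs.channels.index(channel)
    L = int(round(n_cycles / freq * epochs.fs))
    center = int(round((t - epochs.t0) * epochs.fs))
    seg = epochs.data[:, ci, center - L // 2: center - L // 2 + L]
    win = np.hanning(L)
    n = np.arange(L)
    coef = np.sum(seg * win[None, :] *
                  np.exp(-2j * np.pi * freq * n[None, :] / epochs.fs), axis=1)
    return np.abs(coef) ** 2


class TestRejection:
    def test_identical_trials_reject_nothing(self):
        trial = np.sin(np.linspace(0, 20, 500))
        ep = make_epochs(np.tile(trial, (10, 1, 1)))
        clean, report = reject_artifact_trials(ep)
        assert report.n_rejected == 0
        assert clean.n_trials == 10

    def test_constructed_outliers_rejected_exactly(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 4, 1000)
        # clean trials: fixed-amplitude oscillation, tiny noise -> tight max stat
        data = np.stack([np.sin(2 * np.pi * 8 * t + rng.uniform(0, 6.28))
                         + 0.01 * rng.standard_normal(len(t))
                         for _ in range(100)])[:, None, :]
        bad = [11, 55, 80]
        data[bad, 0, 300:340] += 10.0
        clean, report = reject_artifact_trials(make_epochs(data))
        assert sorted(report.rejected.tolist()) == bad
        assert report.per_channel_counts["ch"] == 3

    def test_gaussian_noise_rejection_rate_moderate(self):
        rng = np.random.default_rng(1)
        ep = make_epochs(rng.standard_normal((100, 1, 2000)))
        _, report = reject_artifact_trials(ep)
        assert report.n_rejected < 10  # upper-tail mass of the max statistic

    def test_literal_within_trial_rule_rejects_nearly_all(self):
        rng = np.random.default_rng(2)
        ep = make_epochs(rng.standard_normal((20, 1, 4000)))
        with pytest.raises(ValueError, match="within_trial"):
            # max of 4000 gaussian samples always exceeds 2 within-trial SDs
            reject_artifact_trials(ep, rule="within_trial")

    def test_needs_minimum_population(self):
        ep = make_epochs(np.zeros((3, 1, 100)))
        with pytest.raises(ValueError):
            reject_artifact_trials(ep)


class TestTFR:
    def test_taper_lengths(self):
        assert taper_length_samples(2.0, FS) / FS == pytest.approx(2.0)  # 2 s at 2 Hz
        assert taper_length_samples(10.0, FS) / FS == pytest.approx(0.4, abs=1 / FS)

    def test_pure_tone_peaks_at_its_frequency_and_power_is_quadratic(self):
        t = np.arange(int(11 * FS)) / FS - 2.0
        x1 = np.sin(2 * np.pi * 10 * t)
        ep = make_epochs(np.stack([x1, 2 * x1])[:, None, :])
        tfr = compute_tfr(ep, "ch", freqs=np.arange(2.0, 41.0),
                          times=np.arange(0.0, 1.0, 0.05))
        mean_pow = np.nanmean(tfr.power, axis=2)
        assert tfr.freqs[np.argmax(mean_pow[0])] == 10.0
        ratio = mean_pow[1] / mean_pow[0]
        assert ratio[np.argmax(mean_pow[0])] == pytest.approx(4.0, rel=1e-6)

    def test_matches_direct_dft_oracle(self):
        rng = np.random.default_rng(3)
        ep = make_epochs(rng.standard_normal((3, 1, int(11 * FS))))
        freqs = np.array([2.0, 5.0, 13.0, 27.0])
        times = np.array([-0.5, 0.0, 0.5, 1.0, 1.5])
        tfr = compute_tfr(ep, "ch", freqs=freqs, times=times)
        for fi, f in enumerate(freqs):
            for ti, t in enumerate(times):
                oracle = direct_dft_power(ep, "ch", f, t)
                np.testing.assert_allclose(tfr.power[:, fi, ti], oracle,
                                           rtol=1e-6)

    def test_linearity_of_complex_coefficients(self):
        # parallelogram law on power holds iff the operator is linear
        rng = np.random.default_rng(4)
        n = int(11 * FS)
        x1, x2 = rng.standard_normal((2, n))
        ep = make_epochs(np.stack([x1, x2, x1 + x2, x1 - x2])[:, None, :])
        tfr = compute_tfr(ep, "ch", freqs=np.array([6.0, 18.0]),
                          times=np.array([0.2, 0.9]))
        p = tfr.power
        np.testing.assert_allclose(p[2] + p[3], 2 * p[0] + 2 * p[1], rtol=1e-9)

    def test_edge_cells_missing_not_zero(self):
        ep = make_epochs(np.ones((2, 1, int(3 * FS))), t0=-1.0)  # short epoch
        tfr = compute_tfr(ep, "ch", freqs=np.array([2.0]),
                          times=np.array([-0.5, 0.5, 1.5]))
        # 2 Hz taper is 2 s; centered at -0.5 or 1.5 it leaves the 3 s epoch
        assert np.isnan(tfr.power[:, 0, 0]).all()
        assert np.isfinite(tfr.power[:, 0, 1]).all()
        assert np.isnan(tfr.power[:, 0, 2]).all()
        assert tfr.n_missing == 4

    def test_times_outside_epoch_error(self):
        ep = make_epochs(np.ones((2, 1, 100)), t0=0.0)
        with pytest.raises(ValueError, match="outside"):
            compute_tfr(ep, "ch", freqs=np.array([10.0]),
                        times=np.array([5.0]))


def make_tfr(power, freqs, times, normalization="raw"):
    return TFRGrid(power=np.asarray(power, float), freqs=np.asarray(freqs, float),
                   times=np.asarray(times, float), fs=FS,
                   normalization=normalization)


class TestBaseline:
    def test_hand_median_mad_arithmetic(self):
        times = np.array([-0.8, -0.6, -0.4, -0.2, -0.1, 0.5])
        power = np.array([[[1.0, 2.0, 3.0, 4.0, 10.0, 7.0]]])
        out = baseline_correct(make_tfr(power, [10.0], times))
        # baseline {1,2,3,4,10}: median 3, MAD 1 -> (7-3)/1 = 4
        assert out.power[0, 0, -1] == pytest.approx(4.0)
        assert out.normalization == "baseline_corrected"

    def test_additive_offset_invariance(self):
        rng = np.random.default_rng(5)
        times = np.arange(-1.0, 2.0, 0.05)
        power = rng.random((4, 3, len(times)))
        a = baseline_correct(make_tfr(power, [4, 5, 6], times))
        b = baseline_correct(make_tfr(power + 17.3, [4, 5, 6], times))
        np.testing.assert_allclose(a.power, b.power, atol=1e-9)

    def test_stationary_signal_centered_on_zero(self):
        rng = np.random.default_rng(6)
        times = np.arange(-1.0, 2.0, 0.01)
        power = rng.exponential(size=(20, 2, len(times)))
        out = baseline_correct(make_tfr(power, [5, 15], times))
        post = out.power[:, :, times >= 0]
        assert abs(np.median(post)) < 0.2

    def test_zero_mad_flagged_and_excluded(self):
        times = np.array([-0.7, -0.5, -0.3, -0.1, 0.5])
        power = np.array([[[2.0, 2.0, 2.0, 2.0, 9.0]]])
        out = baseline_correct(make_tfr(power, [8.0], times))
        assert np.isnan(out.power).all()
        assert out.meta["n_zero_mad"] == 1

    def test_requires_raw_input(self):
        times = np.arange(-1.0, 1.0, 0.1)
        tfr = make_tfr(np.ones((1, 1, len(times))), [5.0], times,
                       normalization="baseline_corrected")
        with pytest.raises(ValueError):
            baseline_correct(tfr)


class TestBetaPeak:
    def _corrected(self, spectrum, freqs):
        times = np.arange(0.0, 2.0, 0.05)
        power = np.tile(np.asarray(spectrum, float)[None, :, None],
                        (3, 1, len(times)))
        return make_tfr(power, freqs, times, normalization="baseline_corrected")

    def test_injected_16hz_gives_14_18_band(self):
        freqs = np.arange(10.0, 23.0)
        spec = np.exp(-0.5 * ((freqs - 16.0) / 1.5) ** 2)
        band = detect_beta_peak(self._corrected(spec, freqs))
        assert (band.lo, band.hi) == (14.0, 18.0)
        assert band.provenance == "peak_detected"
        assert band.peak_hz == 16.0

    def test_flat_spectrum_tie_breaks_low(self):
        freqs = np.arange(10.0, 23.0)
        band = detect_beta_peak(self._corrected(np.ones_like(freqs), freqs))
        assert band.peak_hz == 12.0

    def test_boundary_peak_band_extends_outside_search_range(self):
        freqs = np.arange(10.0, 23.0)
        spec = -(freqs - 10.0)  # decreasing: peak of the 12-20 range at 12
        band = detect_beta_peak(self._corrected(spec, freqs))
        assert (band.lo, band.hi) == (10.0, 14.0)

    def test_band_width_invariant(self):
        with pytest.raises(ValueError):
            BandSpec("beta", 12.0, 17.0, provenance="peak_detected")


class TestBandPower:
    def test_constant_grid_returns_constant(self):
        times = np.arange(-1.0, 2.0, 0.05)
        tfr = make_tfr(np.full((5, 4, len(times)), 2.5), [4, 5, 6, 7], times,
                       normalization="baseline_corrected")
        out = extract_band_power(tfr, BandSpec("theta", 4, 7))
        np.testing.assert_allclose(out["power"], 2.5)

    def test_theta_band_is_inclusive_4_to_7(self):
        times = np.arange(0.0, 2.0, 0.1)
        freqs = np.arange(2.0, 11.0)
        power = np.tile(freqs[None, :, None], (1, 1, len(times))).astype(float)
        tfr = make_tfr(power, freqs, times, normalization="baseline_corrected")
        out = extract_band_power(tfr, BandSpec("theta", 4, 7))
        assert out["power"].iloc[0] == pytest.approx(np.mean([4, 5, 6, 7]))

    def test_degenerate_band_reduces_to_indexing(self):
        rng = np.random.default_rng(7)
        times = np.round(np.arange(0.0, 2.0, 0.004), 6)
        freqs = np.arange(10.0, 23.0)
        power = rng.random((6, len(freqs), len(times)))
        tfr = make_tfr(power, freqs, times, normalization="baseline_corrected")
        out = extract_band_power(tfr, BandSpec("one", 14.9, 15.1),
                                 window=(1.0, 1.0004))
        fi = list(freqs).index(15.0)
        ti = int(np.argmin(np.abs(times - 1.0)))
        np.testing.assert_allclose(out["power"], power[:, fi, ti])

    def test_missing_cells_excluded_and_counted(self):
        times = np.arange(0.0, 2.0, 0.1)
        power = np.full((2, 1, len(times)), 3.0)
        power[0, 0, :5] = np.nan
        tfr = make_tfr(power, [5.0], times, normalization="baseline_corrected")
        out = extract_band_power(tfr, BandSpec("t", 4, 7), window=(0.0, 2.0))
        assert out["power"].iloc[0] == pytest.approx(3.0)
        assert out["n_missing_cells"].iloc[0] == 5


class TestSliding:
    def test_window_count_for_2s_span(self):
        times = np.round(np.arange(0.0, 2.0 + 1e-9, 0.004), 6)
        tfr = make_tfr(np.ones((2, 1, len(times))), [5.0], times,
                       normalization="baseline_corrected")
        out = sliding_band_power(tfr, BandSpec("t", 4, 7))
        assert out["window"].nunique() == 73
        np.testing.assert_allclose(out["power"], 1.0)

    def test_burst_localized_in_overlapping_windows(self):
        times = np.round(np.arange(0.0, 2.0 + 1e-9, 0.004), 6)
        power = np.zeros((1, 1, len(times)))
        power[0, 0, (times >= 0.9) & (times <= 1.1)] = 5.0
        tfr = make_tfr(power, [5.0], times, normalization="baseline_corrected")
        out = sliding_band_power(tfr, BandSpec("t", 4, 7))
        peak_start = out.loc[out["power"].idxmax(), "t_start"]
        assert 0.8 <= peak_start <= 1.1
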