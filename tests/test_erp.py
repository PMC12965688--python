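import numpy as np
import pandas as pd
import pytest

import dynexpect as dx
from dynexpect.erp import DEFAULT_BANDS, EpochSet, ROI_PRESETS


FS = 250.0


def sinusoid_epochs(freq=10.0, amp=1.0, n_trials=3, channels=("Cz",),
                    t0=-500.0, dur_ms=1500.0, window=None):
    times = t0 + np.arange(int(dur_ms / 1e3 * FS)) * 1e3 / FS
    sig = amp * np.sin(2 * np.pi * freq * times / 1e3)
    if window is not None:
        sig = sig * ((times >= window[0]) & (times <= window[1]))
    data = np.tile(sig, (n_trials, len(channels), 1))
    return EpochSet(data, FS, t0, list(channels))


class TestEpochSet:
    def test_validation(self):
        with pytest.raises(ValueError, match="channel"):
            EpochSet(np.zeros((2, 3, 10)), FS, 0.0, ["a", "b"])
        with pytest.raises(ValueError, match="unique"):
            EpochSet(np.zeros((2, 2, 10)), FS, 0.0, ["a", "a"])
        with pytest.raises(ValueError, match="fs"):
            EpochSet(np.zeros((2, 1, 10)), 0.0, 0.0, ["a"])

    def test_save_load_roundtrip(self, tmp_path):
        ep, _ = dx.simulate_erp_epochs(n_trials=4, fs=FS, seed=0)
        ep.save(str(tmp_path / "ep"))
        back = EpochSet.load(str(tmp_path / "ep"))
        np.testing.assert_array_equal(ep.data, back.data)
        assert back.channels == ep.channels and back.fs == ep.fs


class TestN2P2:
    def test_latency_offset_invariance(self):
        ep, _ = dx.simulate_erp_epochs(n_trials=20, fs=FS, noise_sd=0.2,
                                       seed=1)
        _, lat_a = dx.measure_n2_p2(ep)
        shifted = EpochSet(ep.data + 42.0, ep.fs, ep.t0, ep.channels)
        _, lat_b = dx.measure_n2_p2(shifted)
        assert lat_a == lat_b

    def test_noisy_latency_within_10ms(self):
        ep, truth = dx.simulate_erp_epochs(
            n_trials=160, fs=FS, noise_sd=5.0, amplitude_jitter=0.0, seed=2)
        _, lat = dx.measure_n2_p2(ep)
        assert abs(lat["n2"] - truth.attrs["n2_latency"]) <= 10.0
        assert abs(lat["p2"] - truth.attrs["p2_latency"]) <= 10.0

    def test_trialwise_amplitude_tracks_plant(self):
        """Per-trial estimates correlate with planted amplitudes at r > 0.7
        even at noise half the bump amplitude."""
        ep, truth = dx.simulate_erp_epochs(n_trials=160, fs=FS, noise_sd=5.0,
                                           amplitude_jitter=0.5, seed=3)
        amps, _ = dx.measure_n2_p2(ep)
        r_n2 = np.corrcoef(amps["n2"], truth["n2_amplitude"])[0, 1]
        r_p2 = np.corrcoef(amps["p2"], truth["p2_amplitude"])[0, 1]
        assert r_n2 > 0.7 and r_p2 > 0.7

    def test_window_outside_epoch_raises(self):
        ep, _ = dx.simulate_erp_epochs(n_trials=2, fs=FS, seed=4)
        with pytest.raises(ValueError, match="outside"):
            dx.measure_n2_p2(ep, n2_window=(2000.0, 3000.0))

    def test_finite_outputs_and_nan_propagation(self):
        ep, _ = dx.simulate_erp_epochs(n_trials=8, fs=FS, noise_sd=1.0,
                                       seed=5)
        ep.data[3] = np.nan
        amps, _ = dx.measure_n2_p2(ep, lowpass=None)
        assert amps.drop(index=3).notna().all().all()
        assert amps.loc[3].isna().all()


class TestTfr:
    def test_steady_sinusoid_cancels_after_baseline(self):
        ep = sinusoid_epochs()
        tfr = dx.compute_tfr(ep)
        # residual window-phase leakage is below 1% of the signal power
        np.testing.assert_allclose(tfr.power, 0.0, atol=0.01)

    def test_burst_localizes_in_frequency_and_time(self):
        ep = sinusoid_epochs(window=(500.0, 900.0),
                             channels=("P3", "Pz", "P4"))
        tfr = dx.compute_tfr(ep)
        mag_box = dx.roi_magnitude(tfr, preset="alpha_erd")
        outside = dx.roi_magnitude(tfr, band=(60, 90), window=(500, 900),
                                   channels=("P3", "Pz", "P4"))
        assert (mag_box > 0.1).all()
        assert np.all(np.abs(outside) < 0.01)
        # energy concentrated near 10 Hz within the burst window
        ti = (tfr.times >= 600) & (tfr.times <= 800)
        prof = tfr.power[0, 0][:, ti].mean(axis=1)
        assert tfr.freqs[np.argmax(prof)] == pytest.approx(10.0, abs=1.0)

    def test_amplitude_doubling_quadruples_power(self):
        a = dx.compute_tfr(sinusoid_epochs(amp=1.0), baseline=None)
        b = dx.compute_tfr(sinusoid_epochs(amp=2.0), baseline=None)
        i = np.argmin(np.abs(a.freqs - 10.0))
        ratio = b.power[0, 0, i] / np.maximum(a.power[0, 0, i], 1e-300)
        np.testing.assert_allclose(ratio, 4.0, rtol=1e-6)

    def test_edge_windows_dropped(self):
        ep = sinusoid_epochs()
        tfr = dx.compute_tfr(ep, baseline=None)
        assert tfr.times[0] >= -500.0 + 125.0 - 1e-9
        assert tfr.times[-1] <= 1000.0 - 125.0 + 1e-9

    def test_epoch_too_short_raises(self):
        ep = sinusoid_epochs(dur_ms=200.0, t0=0.0)
        with pytest.raises(ValueError):
            dx.compute_tfr(ep, t_range=(-500, 1000))


class TestRoi:
    def test_zero_tfr_gives_zero(self):
        ep = EpochSet(np.zeros((2, 3, 375)), FS, -500.0, ["P3", "Pz", "P4"])
        tfr = dx.compute_tfr(ep)
        assert np.all(dx.roi_magnitude(tfr, preset="alpha_erd") == 0.0)

    def test_locality(self):
        """ROI means ignore channels outside the preset."""
        ep = sinusoid_epochs(window=(500.0, 900.0),
                             channels=("P3", "Pz", "P4", "Fz"))
        tfr = dx.compute_tfr(ep)
        base = dx.roi_magnitude(tfr, preset="alpha_erd")
        tfr.power[:, 3] += 99.0                 # corrupt Fz only
        np.testing.assert_array_equal(
            dx.roi_magnitude(tfr, preset="alpha_erd"), base)

    def test_presets_match_published_boxes(self):
        assert ROI_PRESETS["lep"]["band"] == (1.0, 10.0)
        assert ROI_PRESETS["alpha_erd"]["window"] == (500.0, 900.0)
        assert ROI_PRESETS["gamma_ers"]["channels"] == ("FC1", "FC2", "Cz")


class TestBandPower:
    @staticmethod
    def four_second(signal_fn, n_trials=1, channels=("Cz",)):
        t = np.arange(0, 4.0, 1 / FS)
        sig = signal_fn(t)
        data = np.tile(sig, (n_trials, len(channels), 1))
        return EpochSet(data, FS, -4000.0, list(channels))

    def test_alpha_sinusoid_dominates(self):
        ep = self.four_second(lambda t: np.sin(2 * np.pi * 10 * t))
        bp = dx.anticipatory_band_power(ep)
        bands = dict(zip(DEFAULT_BANDS, bp[0, 0]))
        for other in ("theta", "beta", "gamma"):
            assert bands["alpha"] > 100 * bands[other]

    def test_white_noise_power_proportional_to_bandwidth(self):
        rng = np.random.default_rng(6)
        data = rng.normal(size=(200, 1, 1000))
        ep = EpochSet(data, FS, -4000.0, ["Cz"])
        bp = dx.anticipatory_band_power(ep).mean(axis=0)[0]
        widths = np.array([hi - lo for lo, hi in DEFAULT_BANDS.values()])
        density = bp / 1.0                     # PSD is flat: equal densities
        rel = density / density.mean()
        assert np.all(np.abs(rel - 1.0) < 0.2)

    def test_zero_signal_zero_power(self):
        ep = self.four_second(lambda t: 0.0 * t)
        assert np.all(dx.anticipatory_band_power(ep) == 0.0)

    def test_parseval_with_rectangular_taper(self):
        rng = np.random.default_rng(7)
        data = rng.normal(size=(3, 2, 1000))
        ep = EpochSet(data, FS, -4000.0, ["Cz", "C4"])
        from scipy.signal import periodogram
        f, psd = periodogram(ep.data, fs=FS, window="boxcar", detrend=False,
                             axis=-1)
        total = psd.sum(axis=-1) * (f[1] - f[0])
        np.testing.assert_allclose(total, np.mean(ep.data ** 2, axis=-1),
                                   rtol=0.01)

    def test_dpss_mode_close_to_hann(self):
        rng = np.random.default_rng(8)
        data = rng.normal(size=(50, 1, 1000))
        ep = EpochSet(data, FS, -4000.0, ["Cz"])
        h = dx.anticipatory_band_power(ep, taper="hann").mean(axis=0)
        d = dx.anticipatory_band_power(ep, taper="dpss").mean(axis=0)
        np.testing.assert_allclose(h, d, rtol=0.25)

    def test_resolution_quarter_hz(self):
        ep = self.four_second(lambda t: np.sin(2 * np.pi * 10 * t))
        from scipy.signal import periodogram
        f, _ = periodogram(ep.data, fs=FS, axis=-1)
        assert f[1] - f[0] == pytest.approx(0.25)
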