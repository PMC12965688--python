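"""Trial-wise EEG feature measurement: N2/P2 amplitudes, time-frequency ROI
magnitudes and anticipatory band power.

Works on epoch arrays (trials x channels x samples) carried by
:class:`EpochSet`.  The N2/P2 recipe follows the standard laser-evoked
potential measurement: group latencies are found on the all-trials grand
average at Cz (trough in 180-300 ms, peak in 250-500 ms after a 30-Hz
zero-phase low-pass), then per-trial amplitudes are means over a 30-ms
window centred on those latencies.  Oscillatory power uses a sliding
250-ms Hanning-windowed Fourier transform with a subtractive pre-stimulus
baseline; anticipatory spectra use full-epoch periodograms at the native
frequency resolution (1 / epoch length) averaged within canonical bands.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

__all__ = ["EpochSet", "TFR", "lowpass_filter", "measure_n2_p2",
           "compute_tfr", "roi_magnitude", "anticipatory_band_power",
           "ROI_PRESETS", "DEFAULT_BANDS"]

#: band x time-window x channel boxes where each laser-evoked oscillatory
#: response is maximal
ROI_PRESETS = {
    "lep": {"band": (1.0, 10.0), "window": (100.0, 400.0),
            "channels": ("FC1", "FC2", "Cz")},
    "alpha_erd": {"band": (7.0, 13.0), "window": (500.0, 900.0),
                  "channels": ("P3", "Pz", "P4")},
    "gamma_ers": {"band": (60.0, 90.0), "window": (200.0, 350.0),
                  "channels": ("FC1", "FC2", "Cz")},
}

DEFAULT_BANDS = {"theta": (4.0, 7.0), "alpha": (7.0, 13.0),
                 "beta": (13.0, 30.0), "gamma": (30.0, 90.0)}


@dataclass
class EpochSet:
    """Epoched multichannel data (trials x channels x samples, microvolts)."""
    data: np.ndarray
    fs: float
    t0: float                       # ms of the first sample re stimulus onset
    channels: list[str]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if self.data.shape[1] != len(self.channels):
            raise ValueError("channel axis does not match channel names")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel names must be unique")
        if not self.fs > 0:
            raise ValueError("fs must be > 0")

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms relative to stimulus onset."""
        return self.t0 + np.arange(self.data.shape[2]) * 1e3 / self.fs

    def channel_index(self, name: str) -> int:
        return self.channels.index(name)

    # -- simple on-disk container: binary array + JSON header --------------
    def save(self, path: str) -> None:
        np.save(path + ".npy", self.data)
        with open(path + ".json", "w") as fh:
            json.dump({"fs": self.fs, "t0": self.t0,
                       "channels": self.channels}, fh)

    @classmethod
    def load(cls, path: str) -> "EpochSet":
        with open(path + ".json") as fh:
            hdr = json.load(fh)
        return cls(data=np.load(path + ".npy"), **hdr)


@dataclass
class TFR:
    """Time-frequency power (trials x channels x frequencies x times)."""
    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray               # ms, window centres
    channels: list[str]
    baselined: bool = False


def lowpass_filter(epochs: EpochSet, cutoff: float = 30.0) -> EpochSet:
    """Zero-phase FIR low-pass (order = 3 fs / cutoff, Hamming design)."""
    numtaps = int(3 * epochs.fs / cutoff)
    numtaps += 1 - numtaps % 2          # odd length for a type-I filter
    taps = signal.firwin(numtaps, cutoff, fs=epochs.fs)
    out = signal.filtfilt(taps, [1.0], epochs.data, axis=-1)
    return EpochSet(out, epochs.fs, epochs.t0, list(epochs.channels))


def _window_slice(times: np.ndarray, lo: float, hi: float) -> np.ndarray:
    idx = np.flatnonzero((times >= lo) & (times <= hi))
    if idx.size == 0:
        raise ValueError(f"window [{lo}, {hi}] ms outside epoch span "
                         f"[{times[0]:.1f}, {times[-1]:.1f}] ms")
    return idx


def _extremum(ga: np.ndarray, idx: np.ndarray, kind: str) -> int:
    sub = ga[idx]
    j = int(np.argmin(sub) if kind == "trough" else np.argmax(sub))
    if j in (0, sub.size - 1) and sub.size > 2:
        warnings.warn(f"{kind} latency hit the search-window boundary",
                      stacklevel=3)
    return int(idx[j])


def measure_n2_p2(epochs: EpochSet, channel: str = "Cz",
                  n2_window: tuple = (180.0, 300.0),
                  p2_window: tuple = (250.0, 500.0),
                  amp_halfwidth: float = 15.0,
                  lowpass: float | None = 30.0) -> tuple[pd.DataFrame, dict]:
    """Per-trial N2/P2 amplitudes with grand-average latencies.

    Steps: (1) grand average across all trials at ``channel`` (after the
    30-Hz low-pass unless ``lowpass`` is None); (2) N2 latency = trough in
    ``n2_window`` ms, P2 latency = peak in ``p2_window`` ms, snapped to the
    sample grid; (3) per-trial amplitudes = mean over latency +/-
    ``amp_halfwidth`` ms.

    Returns ``(amplitudes, latencies)``: a DataFrame with columns
    ``n2, p2`` and a dict with the group latencies in ms.
    """
    filt = lowpass_filter(epochs, lowpass) if lowpass else epochs
    ci = filt.channel_index(channel)
    times = filt.times
    ga = filt.data[:, ci, :].mean(axis=0)
    i_n2 = _extremum(ga, _window_slice(times, *n2_window), "trough")
    i_p2 = _extremum(ga, _window_slice(times, *p2_window), "peak")
    lat = {"n2": float(times[i_n2]), "p2": float(times[i_p2])}
    amps = {}
    for name, i in (("n2", i_n2), ("p2", i_p2)):
        win = _window_slice(times, times[i] - amp_halfwidth,
                            times[i] + amp_halfwidth)
        amps[name] = filt.data[:, ci, win].mean(axis=1)
    return pd.DataFrame(amps), lat


def compute_tfr(epochs: EpochSet,
                t_range: tuple = (-500.0, 1000.0), step: float = 10.0,
                f_range: tuple = (1.0, 100.0), f_step: float = 1.0,
                window_ms: float = 250.0,
                baseline: tuple | None = (-400.0, -100.0)) -> TFR:
    """Sliding Hanning-window Fourier power.

    Windows are centred every ``step`` ms within ``t_range``; centres whose
    window would need samples beyond the epoch are dropped (no padding).
    The FFT is zero-padded to 1 s so the frequency grid is 1 Hz regardless
    of window length; power is scaled so a unit-amplitude sinusoid yields
    power 1 at its frequency.  With ``baseline`` the per-trial mean power
    over the baseline interval is subtracted per channel and frequency.
    """
    times = epochs.times
    half = window_ms / 2.0
    centres = np.arange(t_range[0], t_range[1] + 1e-9, step)
    centres = centres[(centres - half >= times[0] - 1e-9)
                      & (centres + half <= times[-1] + 1e-9)]
    if centres.size == 0:
        raise ValueError("epoch too short for the requested window and range")
    nwin = int(round(window_ms / 1e3 * epochs.fs))
    win = np.hanning(nwin)
    nfft = max(int(round(epochs.fs / f_step)), nwin)
    freqs = np.arange(f_range[0], f_range[1] + 1e-9, f_step)
    bins = np.round(freqs / (epochs.fs / nfft)).astype(int)
    n_tr, n_ch, _ = epochs.data.shape
    power = np.empty((n_tr, n_ch, freqs.size, centres.size))
    wsum = win.sum()
    for k, c in enumerate(centres):
        start = int(round((c - half - epochs.t0) / 1e3 * epochs.fs))
        seg = epochs.data[:, :, start:start + nwin] * win
        spec = np.fft.rfft(seg, n=nfft, axis=-1)
        power[:, :, :, k] = (2.0 * np.abs(spec[:, :, bins]) / wsum) ** 2
    tfr = TFR(power=power, freqs=freqs, times=centres,
              channels=list(epochs.channels))
    if baseline is not None:
        bidx = np.flatnonzero((centres >= baseline[0])
                              & (centres <= baseline[1]))
        if bidx.size == 0:
            raise ValueError("baseline interval contains no TFR time points")
        tfr.power = tfr.power - tfr.power[:, :, :, bidx].mean(
            axis=-1, keepdims=True)
        tfr.baselined = True
    return tfr


def roi_magnitude(tfr: TFR, band: tuple | None = None,
                  window: tuple | None = None,
                  channels: tuple | None = None,
                  preset: str | None = None) -> np.ndarray:
    """Per-trial mean power over a frequency-band x time-window x channel box.

    Either give ``preset`` (one of ``lep``, ``alpha_erd``, ``gamma_ers``)
    or the three box edges explicitly.
    """
    if preset is not None:
        spec = ROI_PRESETS[preset]
        band, window, channels = spec["band"], spec["window"], spec["channels"]
    fi = np.flatnonzero((tfr.freqs >= band[0]) & (tfr.freqs <= band[1]))
    ti = np.flatnonzero((tfr.times >= window[0]) & (tfr.times <= window[1]))
    ci = [tfr.channels.index(c) for c in channels]
    if fi.size == 0 or ti.size == 0 or not ci:
        raise ValueError("empty ROI box")
    box = tfr.power[:, ci][:, :, fi][:, :, :, ti]
    return box.mean(axis=(1, 2, 3))


def anticipatory_band_power(epochs: EpochSet,
                            bands: dict | None = None,
                            taper: str = "hann",
                            nw: float = 2.0) -> pd.DataFrame | np.ndarray:
    """Band-averaged power spectral density of pre-stimulus epochs.

    The PSD is computed per epoch and channel at the native resolution
    (1 / epoch duration; 0.25 Hz for 4-s epochs) with a single Hann taper by
    default; ``taper="boxcar"`` gives the untapered periodogram (for which
    total power times bin width equals the time-domain mean square,
    Parseval) and ``taper="dpss"`` averages a small Slepian ensemble with
    time-bandwidth ``nw``.  Returns an array (trials x channels x bands);
    band order follows the ``bands`` dict (default theta, alpha, beta,
    gamma).
    """
    bands = bands or DEFAULT_BANDS
    n = epochs.data.shape[2]
    if taper in ("hann", "boxcar"):
        freqs, psd = signal.periodogram(epochs.data, fs=epochs.fs,
                                        window=taper, detrend=False,
                                        axis=-1)
    elif taper == "dpss":
        k = max(int(2 * nw - 1), 1)
        tapers = signal.windows.dpss(n, nw, Kmax=k)
        specs = []
        for w in tapers:
            f, p = signal.periodogram(epochs.data, fs=epochs.fs, window=w,
                                      detrend=False, axis=-1)
            specs.append(p)
        freqs, psd = f, np.mean(specs, axis=0)
    else:
        raise ValueError(f"unknown taper {taper!r}")
    out = np.empty(epochs.data.shape[:2] + (len(bands),))
    for j, (name, (lo, hi)) in enumerate(bands.items()):
        sel = (freqs >= lo) & (freqs <= hi)
        if not sel.any():
            raise ValueError(f"band {name} resolves to no frequency bins")
        out[:, :, j] = psd[:, :, sel].mean(axis=-1)
    return out
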