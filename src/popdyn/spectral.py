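"""Multitaper power spectrum of multi-unit activity (MUA).

The MUA vector of a trial is the mean spike count across units in 10 ms
bins over the 2000 ms trial window.  Its power spectrum is estimated per
trial with DPSS (Slepian) tapers, averaged across trials per condition,
and normalised by the mean power over the analysed 1-10 Hz band, so a
white (unmodulated Poisson) population gives a flat normalised spectrum
around 1 and oscillatory population activity shows a band-limited peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import dpss

from .binning import BIN_MS


@dataclass
class SpectrumResult:
    freq_hz: np.ndarray
    power: np.ndarray  # trial-mean multitaper power in the band
    norm_power: np.ndarray  # power / band-mean power
    nw: float
    n_tapers: int


def mua_spectrum(
    counts: np.ndarray,
    nw: float = 3.0,
    n_tapers: int = 5,
    band_hz: tuple = (1.0, 10.0),
    bin_ms: float = BIN_MS,
) -> SpectrumResult:
    """Multitaper MUA spectrum for one condition.

    ``counts`` is (n_trials, n_units, n_bins); per trial the unit-mean
    count series is tapered (time-bandwidth ``nw``, ``n_tapers`` tapers),
    the squared FFT magnitudes are averaged over tapers, and spectra are
    averaged over trials before band-restriction and normalisation.
    The trial mean is removed before tapering so the DC term does not
    leak into the low-frequency band.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 3 or counts.shape[0] == 0 or counts.shape[1] == 0:
        raise ValueError("need a (n_trials, n_units, n_bins) count tensor")
    fs = 1000.0 / bin_ms
    mua = counts.mean(axis=1)  # (n_trials, n_bins)
    mua = mua - mua.mean(axis=1, keepdims=True)
    n_bins = mua.shape[1]
    tapers = dpss(n_bins, nw, Kmax=n_tapers)  # (K, n_bins)
    freqs = np.fft.rfftfreq(n_bins, d=1.0 / fs)
    # (trials, K, n_bins) -> power
    tapered = mua[:, None, :] * tapers[None, :, :]
    spec = np.abs(np.fft.rfft(tapered, axis=-1)) ** 2 / fs
    spec = spec.mean(axis=1)  # over tapers
    power = spec.mean(axis=0)  # over trials
    sel = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    f, p = freqs[sel], power[sel]
    mean_p = p.mean()
    norm = p / mean_p if mean_p > 0 else np.full_like(p, np.nan)
    return SpectrumResult(freq_hz=f, power=p, norm_power=norm, nw=nw,
                          n_tapers=n_tapers)
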