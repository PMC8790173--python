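"""Morlet-wavelet spectral power and band utilities.

Power is computed per epoch with 7-cycle complex Morlet wavelets at 1-Hz
frequency resolution, sampled on a 10-ms grid over a 400-ms analysis window,
then averaged in groups of five 10-ms bins into 8 time-segments -- the
classifier's feature vector.  No baseline normalisation is applied: the
POST-PRE difference downstream is the normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, EdgeContaminationError
from .preprocess import EpochSet

DEFAULT_FREQS = np.arange(1.0, 50.0)  # 1..49 Hz, 1-Hz steps
N_CYCLES = 7
T_RESOLUTION = 0.01  # 10 ms
WINDOW_LEN = 0.4  # 400 ms
SEGMENT_GROUP = 5  # five 10-ms bins per segment -> 8 segments


@dataclass(frozen=True)
class BandDefinition:
    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if self.f_lo > self.f_hi:
            raise ConfigurationError("band requires f_lo <= f_hi")


#: Canonical bands.  The alpha band follows the 9-13 Hz definition used for
#: band averaging; an 8-13 Hz variant can be constructed where needed.
BANDS = {
    "theta": BandDefinition("theta", 4, 8),
    "alpha": BandDefinition("alpha", 9, 13),
    "beta": BandDefinition("beta", 14, 30),
    "gamma": BandDefinition("gamma", 31, 49),
}

ALPHA_WIDE = BandDefinition("alpha", 8, 13)


@dataclass
class SpectralFeatures:
    """Per-epoch power: epochs x channels x frequencies x time bins."""

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray  # bin centres, seconds relative to the epoch anchor
    channel_names: list[str]
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if np.any(np.diff(self.freqs) <= 0):
            raise ConfigurationError("frequencies must be strictly increasing")


def default_window(epochs: EpochSet, freqs, n_cycles: int = N_CYCLES):
    """Analysis-window start for an epoch set.

    Task epochs (t0_offset > 0): the window starts at stimulus onset (t=0).
    Rest epochs: the window starts one wavelet half-support (at the lowest
    analysed frequency) into the epoch, keeping it clear of the edge.
    """
    if epochs.t0_offset > 0:
        return 0.0
    return 0.5 * n_cycles / float(np.min(freqs))


def morlet_transform(data: np.ndarray, rate: float, freqs,
                     n_cycles: int = N_CYCLES) -> np.ndarray:
    """Complex Morlet wavelet transform of the last axis, vectorized.

    The complex Morlet wavelet at frequency f has a Gaussian envelope with
    sigma_t = n_cycles / (2 pi f); the transform is realized as FFT-domain
    multiplication with the wavelet's Gaussian frequency response, scaled to
    analytic-signal convention (gain 2 at the centre frequency), so a unit
    amplitude sinusoid at f yields |coefficient|^2 ~= 1.  Returns an array
    of the input shape (complex).
    """
    x = np.asarray(data, dtype=np.float32)
    n = x.shape[-1]
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    spec = np.fft.fft(x, axis=-1).astype(np.complex64)
    fax = np.fft.fftfreq(n, 1.0 / rate)
    sigma_t = n_cycles / (2 * np.pi * freqs)
    gain = (2.0 * np.exp(-2 * np.pi ** 2 * sigma_t[:, None] ** 2
                         * (fax[None, :] - freqs[:, None]) ** 2)
            ).astype(np.float32)
    out = np.fft.ifft(spec[..., None, :] * gain, axis=-1)
    return out


def morlet_power(epochs: EpochSet, freqs=None, n_cycles: int = N_CYCLES,
                 window_start: float | None = None,
                 window_len: float = WINDOW_LEN,
                 t_resolution: float = T_RESOLUTION) -> SpectralFeatures:
    """Complex-Morlet power on a 10-ms grid over the analysis window.

    The wavelet transform runs over the full epoch (using the available
    padding) and is then cropped to the window.  A frequency whose 7-cycle
    support does not fit inside the epoch raises
    :class:`EdgeContaminationError` naming the offending frequency.
    """
    if freqs is None:
        freqs = DEFAULT_FREQS
    freqs = np.asarray(freqs, dtype=float)
    epoch_dur = epochs.data.shape[2] / epochs.rate
    for f in freqs:
        if n_cycles / f > epoch_dur:
            raise EdgeContaminationError(
                f"{n_cycles}-cycle wavelet at {f:g} Hz spans "
                f"{n_cycles / f:.2f} s > {epoch_dur:.2f} s epoch"
            )
    if window_start is None:
        window_start = default_window(epochs, freqs, n_cycles)
    t = epochs.times()
    centers = window_start + t_resolution * (0.5 + np.arange(
        int(round(window_len / t_resolution))))
    if centers[-1] > t[-1] + 1e-9:
        raise ConfigurationError("analysis window extends past the epoch")
    idx = np.searchsorted(t, centers - 0.5 / epochs.rate)

    n_ep, n_ch, n_samp = epochs.data.shape
    power = np.empty((n_ep, n_ch, len(freqs), len(idx)))
    # chunk frequencies to bound the complex intermediate at ~256 MB
    chunk = max(1, int(1.6e7 // (n_ep * n_ch * n_samp + 1)))
    for i in range(0, len(freqs), chunk):
        coef = morlet_transform(epochs.data, epochs.rate, freqs[i:i + chunk],
                                n_cycles=n_cycles)
        power[:, :, i:i + chunk, :] = np.abs(coef[..., idx]) ** 2
    return SpectralFeatures(power=power, freqs=freqs, times=centers,
                            channel_names=list(epochs.channel_names),
                            meta=epochs.meta.copy())


def segment_average(features, group: int = SEGMENT_GROUP):
    """Average consecutive non-overlapping groups of time bins.

    Accepts a :class:`SpectralFeatures` (returns a new one with segment-centre
    times) or a bare array whose last axis is time.  40 bins in groups of 5
    yield the canonical 8 time-segments.
    """
    if isinstance(features, SpectralFeatures):
        seg = segment_average(features.power, group)
        times = features.times.reshape(-1, group).mean(axis=1)
        return replace(features, power=seg, times=times,
                       meta=features.meta.copy())
    arr = np.asarray(features)
    n = arr.shape[-1]
    if n % group:
        raise ConfigurationError(
            f"grid length {n} not divisible by group {group}"
        )
    return arr.reshape(*arr.shape[:-1], n // group, group).mean(axis=-1)


def band_average(values: np.ndarray, freqs, band: BandDefinition,
                 axis: int = -1) -> np.ndarray:
    """Unweighted mean over the integer frequencies inside ``band`` (inclusive)."""
    freqs = np.asarray(freqs)
    mask = (freqs >= band.f_lo) & (freqs <= band.f_hi)
    if not mask.any():
        raise ConfigurationError(
            f"band {band.name} [{band.f_lo}, {band.f_hi}] has no frequencies"
        )
    return np.take(np.asarray(values), np.flatnonzero(mask), axis=axis).mean(axis=axis)


def band_filter(x: np.ndarray, rate: float, band: BandDefinition,
                transition: float = 2.0) -> np.ndarray:
    """Zero-phase FIR band-pass of the last axis to ``band``."""
    import mne

    if band.f_hi >= rate / 2:
        raise ConfigurationError(
            f"band {band.name} exceeds Nyquist at rate {rate}"
        )
    shape = x.shape
    flat = np.ascontiguousarray(x, dtype=float).reshape(-1, shape[-1])
    out = mne.filter.filter_data(
        flat, rate, l_freq=band.f_lo, h_freq=band.f_hi,
        l_trans_bandwidth=min(transition, band.f_lo),
        h_trans_bandwidth=transition, phase="zero", fir_design="firwin",
        verbose="ERROR",
    )
    return out.reshape(shape)


def hilbert_band_power(signal: np.ndarray, rate: float | None = None,
                       band: BandDefinition | None = None,
                       prefiltered: bool = False) -> np.ndarray:
    """Squared magnitude of the analytic signal (band-limited power).

    The input must be band-limited: pass ``prefiltered=True`` for data already
    filtered to ``band``, otherwise ``rate`` and ``band`` are required and a
    zero-phase band-pass is applied first.
    """
    from scipy.signal import hilbert

    x = np.asarray(signal, dtype=float)
    if not prefiltered:
        if rate is None or band is None:
            raise ConfigurationError(
                "rate and band required unless prefiltered=True"
            )
        x = band_filter(x, rate, band)
    return np.abs(hilbert(x, axis=-1)) ** 2
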