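"""Cochlear front-end: gammatone filterbank and cochleogram extraction.

The default configuration mirrors a peripheral auditory model with 194
bandpass channels whose center frequencies span 73-7,630 Hz, sampled every
1 ms.  Channel spacing follows the ERB-rate scale of Glasberg & Moore, and
each channel is a 4th-order IIR gammatone filter.  The per-channel envelope
is obtained by half-wave rectification followed by a 2nd-order lowpass at
100 Hz, then decimated to the frame step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy import signal
from scipy.io import wavfile

__all__ = [
    "Filterbank",
    "Cochleogram",
    "build_filterbank",
    "cochleogram",
    "read_wav",
    "write_wav",
    "save_cochleogram",
    "load_cochleogram",
]

# ERB-rate scale (Glasberg & Moore 1990).
_ERB_A = 21.4
_ERB_B = 0.00437


def _hz_to_erb_rate(f):
    return _ERB_A * np.log10(1.0 + _ERB_B * np.asarray(f, dtype=float))


def _erb_rate_to_hz(e):
    return (10.0 ** (np.asarray(e, dtype=float) / _ERB_A) - 1.0) / _ERB_B


def _erb_bandwidth(f):
    """Equivalent rectangular bandwidth (Hz) at center frequency f (Hz)."""
    return 24.7 * (1.0 + 4.37 * np.asarray(f, dtype=float) / 1000.0)


@dataclass(frozen=True)
class Filterbank:
    """A bank of gammatone bandpass filters.

    Attributes
    ----------
    center_freqs : ndarray
        Channel center frequencies in Hz, strictly ascending.
    bandwidths : ndarray
        ERB bandwidth of each channel in Hz.
    sample_rate : float
        Waveform sample rate in Hz.
    """

    center_freqs: np.ndarray
    bandwidths: np.ndarray
    sample_rate: float

    @property
    def n_channels(self) -> int:
        return len(self.center_freqs)


@dataclass
class Cochleogram:
    """Channels x frames matrix of non-negative filterbank envelope energies."""

    energy: np.ndarray
    frame_step: float  # ms
    center_freqs: np.ndarray = field(repr=False)

    @property
    def n_channels(self) -> int:
        return self.energy.shape[0]

    @property
    def n_frames(self) -> int:
        return self.energy.shape[1]


def build_filterbank(
    n_channels: int = 194,
    f_lo: float = 73.0,
    f_hi: float = 7630.0,
    fs: float = 16000.0,
) -> Filterbank:
    """Build a gammatone filterbank with ERB-rate-spaced center frequencies.

    Center frequencies run from ``f_lo`` to ``f_hi`` inclusive, equally
    spaced on the ERB-rate scale.

    Raises
    ------
    ValueError
        If the frequency span is invalid or reaches the Nyquist frequency.
    """
    if not (0.0 < f_lo < f_hi):
        raise ValueError(f"need 0 < f_lo < f_hi, got {f_lo}, {f_hi}")
    if f_hi >= fs / 2.0:
        raise ValueError(f"f_hi={f_hi} must lie below Nyquist {fs / 2.0}")
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if n_channels == 1:
        centers = np.array([f_lo])
    else:
        erbs = np.linspace(_hz_to_erb_rate(f_lo), _hz_to_erb_rate(f_hi), n_channels)
        centers = _erb_rate_to_hz(erbs)
        # pin the endpoints exactly
        centers[0], centers[-1] = f_lo, f_hi
    return Filterbank(centers, _erb_bandwidth(centers), float(fs))


def cochleogram(
    waveform: np.ndarray,
    filterbank: Filterbank,
    frame_step: float = 1.0,
    lowpass_hz: float = 100.0,
    log_compress: bool = False,
) -> Cochleogram:
    """Convert a waveform to a cochleogram.

    Each channel is gammatone-filtered, half-wave rectified, smoothed by a
    2nd-order Butterworth lowpass at ``lowpass_hz``, and sampled every
    ``frame_step`` ms.  The number of frames is
    ``floor(duration_ms / frame_step)``.

    Parameters
    ----------
    log_compress : bool
        If True, apply log(1 + x) compression to the energies.
    """
    x = np.asarray(waveform, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("waveform must be a non-empty 1-D array")
    fs = filterbank.sample_rate
    hop = int(round(frame_step * fs / 1000.0))
    n_frames = x.size // hop
    if n_frames == 0:
        raise ValueError("waveform shorter than one frame")
    b_lp, a_lp = signal.butter(2, lowpass_hz / (fs / 2.0))
    out = np.empty((filterbank.n_channels, n_frames))
    for c, fc in enumerate(filterbank.center_freqs):
        b, a = signal.gammatone(fc, "iir", fs=fs)
        y = signal.lfilter(b, a, x)
        env = signal.lfilter(b_lp, a_lp, np.maximum(y, 0.0))
        out[c] = np.maximum(env[: n_frames * hop : hop], 0.0)
    if log_compress:
        out = np.log1p(out)
    return Cochleogram(out, float(frame_step), filterbank.center_freqs.copy())


def read_wav(path) -> tuple[np.ndarray, int]:
    """Read a mono RIFF PCM WAV file; returns (float waveform in [-1, 1], fs)."""
    fs, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError("expected mono audio")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / np.iinfo(data.dtype).max
    return data.astype(float), int(fs)


def write_wav(path, waveform: np.ndarray, fs: int = 16000) -> None:
    """Write a float waveform in [-1, 1] as 16-bit PCM mono WAV."""
    x = np.clip(np.asarray(waveform, dtype=float), -1.0, 1.0)
    wavfile.write(path, fs, (x * 32767.0).astype(np.int16))


def save_cochleogram(path, cg: Cochleogram, dataset: str = "cochleogram") -> None:
    with h5py.File(path, "w") as h5:
        ds = h5.create_dataset(dataset, data=cg.energy)
        ds.attrs["frame_step_ms"] = cg.frame_step
        ds.attrs["center_freqs_hz"] = cg.center_freqs


def load_cochleogram(path, dataset: str = "cochleogram") -> Cochleogram:
    with h5py.File(path, "r") as h5:
        ds = h5[dataset]
        return Cochleogram(
            ds[()], float(ds.attrs["frame_step_ms"]), np.asarray(ds.attrs["center_freqs_hz"])
        )
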