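"""Spectro-temporal receptive fields of network units.

STRFs of first-layer units are their bases.  A deeper unit's STRF is the
linear combination of the previous layer's STRFs weighted by the unit's
basis, with the basis nearest-neighbour-expanded by the cumulative
down-sampling ratio between the input and that layer and zero-padded by the
pooling offset before the (full-mode) 2-D convolution.

Each STRF is summarized by its rank-1 SVD factors (spectral and temporal
profiles) and four derived scalars: center frequency and best temporal
modulation (profile peaks), and bandwidth and duration (smallest contiguous
window around the peak holding 90% of the squared-profile energy).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import convolve2d

from .model import ArchitectureSpec, DictionaryBank, SHMAXResults

__all__ = [
    "STRF",
    "STRFParams",
    "compose_strf",
    "compose_layer_strfs",
    "strf_profiles",
    "strf_parameters",
    "spectral_modulation",
    "strf_population_summary",
]


@dataclass
class STRF:
    """Composed 2-D receptive field (channels x frames) of one unit."""

    matrix: np.ndarray
    layer_id: str
    unit_index: int


@dataclass
class STRFParams:
    """Scalar STRF descriptors.  ``best_t`` and ``duration`` are in ms,
    ``center_f`` and ``bandwidth`` in Hz; ``spectral_mod`` is the peak of the
    spectral profile's magnitude spectrum in cycles per channel span."""

    center_f: float
    bandwidth: float
    best_t: float
    duration: float
    spectral_mod: float = float("nan")
    unit_index: int = -1
    layer_id: str = ""


def _nn_expand(mat: np.ndarray, d: int) -> np.ndarray:
    if d == 1:
        return mat
    return np.kron(mat, np.ones((d, d), dtype=mat.dtype))


def _pad(mat: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return mat
    return np.pad(mat, ((0, p), (0, p)))


def compose_layer_strfs(banks: dict[str, DictionaryBank], arch: ArchitectureSpec,
                        layer_id: str) -> list[np.ndarray]:
    """STRFs of every unit in S layer ``layer_id`` (bottom-up composition)."""
    spec = arch[layer_id]
    if spec.kind != "S":
        raise ValueError("compose_layer_strfs expects an S layer")
    target_idx = arch.index(layer_id)
    s_specs = [s for s in arch.layers[: target_idx + 1] if s.kind == "S"]
    c_specs = [s for s in arch.layers[: target_idx + 1] if s.kind == "C"]

    bank1 = banks[s_specs[0].name]
    strfs = [bank1.bases[j, :, :, 0] for j in range(bank1.m)]
    jump = s_specs[0].conv_stride
    for level, sspec in enumerate(s_specs[1:], start=1):
        cspec = c_specs[level - 1]  # pooling layer between the two S layers
        d = jump
        pad = (cspec.pool_size - 1) if cspec.pool_mode != "none" else 0
        bank = banks[sspec.name]
        if bank.u != len(strfs):
            raise ValueError(
                f"bank {sspec.name} expects {bank.u} input maps, have {len(strfs)}"
            )
        new = []
        for j in range(bank.m):
            acc = None
            for c in range(bank.u):
                w = _pad(_nn_expand(bank.bases[j, :, :, c], d), pad)
                term = convolve2d(w, strfs[c], mode="full")
                acc = term if acc is None else acc + term
            new.append(acc)
        strfs = new
        jump *= sspec.conv_stride * (cspec.pool_stride if cspec.pool_mode != "none" else 1)
    return strfs


def compose_strf(results: SHMAXResults, layer_id: str, unit_index: int) -> STRF:
    """STRF of one unit.  C-layer units share the STRF of the preceding
    S-layer unit with the same map index."""
    arch = results.arch
    spec = arch[layer_id]
    if spec.kind == "C":
        s_name = arch.layers[arch.index(layer_id) - 1].name
        m = compose_strf(results, s_name, unit_index).matrix
        return STRF(m, layer_id, unit_index)
    strfs = compose_layer_strfs(results.banks, arch, layer_id)
    if not 0 <= unit_index < len(strfs):
        raise IndexError(f"unit {unit_index} out of range for {layer_id}")
    return STRF(strfs[unit_index], layer_id, unit_index)


def strf_profiles(strf) -> tuple[np.ndarray, np.ndarray, float]:
    """Rank-1 SVD factors of an STRF.

    Returns (spectral_profile, temporal_profile, sigma1): unit-norm singular
    vectors of the first singular value, each sign-fixed so its
    largest-magnitude element is positive.
    """
    mat = strf.matrix if isinstance(strf, STRF) else np.asarray(strf, dtype=float)
    if not np.any(mat):
        raise ValueError("all-zero STRF has no profiles")
    U, s, Vt = np.linalg.svd(mat, full_matrices=False)
    spec_p, temp_p = U[:, 0], Vt[0]
    if spec_p[np.argmax(np.abs(spec_p))] < 0:
        spec_p = -spec_p
    if temp_p[np.argmax(np.abs(temp_p))] < 0:
        temp_p = -temp_p
    return spec_p, temp_p, float(s[0])


def _energy_window(profile: np.ndarray, frac: float = 0.9) -> tuple[int, int]:
    """Smallest contiguous [lo, hi] index window around the energy peak
    holding >= frac of total squared energy; ties expand symmetrically."""
    e = np.asarray(profile, dtype=float) ** 2
    total = e.sum()
    peak = int(np.argmax(e))
    lo = hi = peak
    acc = e[peak]
    while acc < frac * total - 1e-12:
        left = e[lo - 1] if lo > 0 else -np.inf
        right = e[hi + 1] if hi < len(e) - 1 else -np.inf
        if left > right:
            lo -= 1
            acc += left
        elif right > left:
            hi += 1
            acc += right
        else:  # tie: keep the window symmetric around the peak
            if peak - lo <= hi - peak and lo > 0:
                lo -= 1
                acc += left
            else:
                hi += 1
                acc += right
    return lo, hi


def _channel_widths(center_freqs: np.ndarray) -> np.ndarray:
    cf = np.asarray(center_freqs, dtype=float)
    if len(cf) == 1:
        return np.array([1.0])
    w = np.empty_like(cf)
    w[1:-1] = (cf[2:] - cf[:-2]) / 2.0
    w[0] = cf[1] - cf[0]
    w[-1] = cf[-1] - cf[-2]
    return w


def spectral_modulation(spectral_profile: np.ndarray) -> float:
    """Peak of the profile's magnitude spectrum, in cycles per channel span
    (DC excluded)."""
    p = np.asarray(spectral_profile, dtype=float)
    p = p - p.mean()
    mag = np.abs(np.fft.rfft(p))
    if len(mag) <= 1:
        return 0.0
    return float(np.argmax(mag[1:]) + 1)


def strf_parameters(
    profiles: tuple[np.ndarray, np.ndarray] | tuple[np.ndarray, np.ndarray, float],
    center_freqs: np.ndarray,
    frame_step: float = 1.0,
    best_t_mode: str = "peak",
) -> STRFParams:
    """Derive the four scalar STRF descriptors from SVD profiles.

    ``best_t_mode`` 'peak' reports the temporal-profile energy-peak latency
    (ms); 'fourier' reports the temporal modulation frequency at the peak of
    the profile's magnitude spectrum (Hz).
    """
    spec_p, temp_p = profiles[0], profiles[1]
    cf = np.asarray(center_freqs, dtype=float)
    if len(spec_p) != len(cf):
        raise ValueError("spectral profile length must match center_freqs")
    widths = _channel_widths(cf)

    s_peak = int(np.argmax(spec_p**2))
    center_f = float(cf[s_peak])
    lo, hi = _energy_window(spec_p)
    bandwidth = float(widths[lo : hi + 1].sum())

    if best_t_mode == "fourier":
        p = temp_p - temp_p.mean()
        mag = np.abs(np.fft.rfft(p))
        k = int(np.argmax(mag[1:]) + 1) if len(mag) > 1 else 0
        best_t = float(k * 1000.0 / (len(temp_p) * frame_step))  # Hz
    else:
        best_t = float(np.argmax(temp_p**2) * frame_step)  # ms
    tlo, thi = _energy_window(temp_p)
    duration = float((thi - tlo + 1) * frame_step)
    return STRFParams(center_f, bandwidth, best_t, duration,
                      spectral_mod=spectral_modulation(spec_p))


def strf_population_summary(params: list[STRFParams], n_bins: int = 10):
    """Normalized parameter histograms and the (best T, spectral modulation)
    scatter table.

    Each parameter axis is scaled to [0, 1] by its maximum value; histogram
    masses sum to 1.  Returns (histograms dict, scatter DataFrame).
    """
    if not params:
        raise ValueError("need at least one unit")
    table = pd.DataFrame(
        {
            "center_f": [p.center_f for p in params],
            "bandwidth": [p.bandwidth for p in params],
            "best_t": [p.best_t for p in params],
            "duration": [p.duration for p in params],
            "spectral_mod": [p.spectral_mod for p in params],
        }
    )
    hists = {}
    for col in ("best_t", "duration", "center_f", "bandwidth"):
        vals = table[col].to_numpy(dtype=float)
        mx = np.max(np.abs(vals))
        scaled = vals / mx if mx > 0 else np.ones_like(vals)
        counts, edges = np.histogram(scaled, bins=n_bins, range=(0.0, 1.0 + 1e-9))
        hists[col] = (counts / counts.sum(), edges)
    scatter = table[["best_t", "spectral_mod"]].copy()
    return hists, scatter
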