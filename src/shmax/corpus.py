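"""Synthetic formant-speech corpus with ground-truth acoustic parameters.

Generates continuous "speech" as a sequence of labeled phoneme tokens drawn
from a configurable inventory (default 33 phonemes across four classes), by
source-filter synthesis at 16 kHz:

* vowels / nasals: impulse-train excitation at F0 through second-order
  resonators at F1 and F2 (time-varying along the token);
* plosives: a silent voice-onset-time gap followed by a band-shaped burst
  at the spectral peak;
* fricatives: white noise shaped by a resonator at the spectral peak.

Tokens are separated by explicit silence.  Every token's realized (jittered)
parameters are recorded as ground truth: per-frame F0/F1/F2 tracks aligned
to 1-ms cochleogram frames, and per-token VOT and spectral peak.

Vowel and nasal formant targets are snapped to harmonics of the token's F0
so that the formant peak is present in the excitation spectrum and thus
recoverable from the cochleogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "PhonemeSpec",
    "Transcript",
    "GroundTruth",
    "make_inventory",
    "synthesize",
    "phoneme_instances",
    "read_phn",
    "write_phn",
    "write_ground_truth",
]

SAMPLE_RATE = 16000
FRAME_STEP_SAMPLES = 16  # 1 ms at 16 kHz
SILENCE_LABEL = "sil"

PHONEME_CLASSES = ("vowel", "plosive", "fricative", "nasal")

DEFAULT_CLASS_MIX = {"vowel": 0.40, "plosive": 0.20, "fricative": 0.20, "nasal": 0.20}


@dataclass(frozen=True)
class PhonemeSpec:
    """Acoustic recipe for one phoneme.

    ``f1_contour``/``f2_contour`` are Hz values sampled over normalized token
    time (voiced classes only); ``vot`` applies to plosives and
    ``spectral_peak`` to plosives and fricatives.
    """

    label: str
    klass: str
    duration_range: tuple[float, float]  # seconds
    f0: float = float("nan")
    f1_contour: np.ndarray | None = None
    f2_contour: np.ndarray | None = None
    vot: float = float("nan")
    spectral_peak: float = float("nan")

    def __post_init__(self):
        if self.klass not in PHONEME_CLASSES:
            raise ValueError(f"unknown phoneme class {self.klass!r}")
        lo, hi = self.duration_range
        if not (0 < lo <= hi):
            raise ValueError("durations must be positive")
        if self.f1_contour is not None and self.f2_contour is not None:
            if np.any(np.asarray(self.f1_contour) >= np.asarray(self.f2_contour)):
                raise ValueError("f1_contour must lie below f2_contour elementwise")
        if not np.isnan(self.vot) and self.vot < 0:
            raise ValueError("vot must be >= 0")

    @property
    def voiced(self) -> bool:
        return self.klass in ("vowel", "nasal")


@dataclass(frozen=True)
class Transcript:
    """Sorted, non-overlapping half-open [start, end) sample intervals tiling
    the waveform; silence is labeled explicitly."""

    intervals: tuple[tuple[int, int, str], ...]

    def __post_init__(self):
        prev_end = 0
        for s, e, _ in self.intervals:
            if s != prev_end or e <= s:
                raise ValueError("intervals must tile the waveform half-open, sorted")
            prev_end = e

    @property
    def n_samples(self) -> int:
        return self.intervals[-1][1] if self.intervals else 0

    def labels(self) -> set[str]:
        return {lab for _, _, lab in self.intervals}


@dataclass
class GroundTruth:
    """Per-frame F0/F1/F2 tracks (NaN outside voiced spans) plus a per-token
    table with realized VOT and spectral peak."""

    f0: np.ndarray
    f1: np.ndarray
    f2: np.ndarray
    tokens: pd.DataFrame  # columns: label, start, end, klass, vot, spectral_peak

    @property
    def n_frames(self) -> int:
        return len(self.f0)


def _snap_to_harmonic(freq: float, f0: float) -> float:
    """Round freq to the nearest positive multiple of f0."""
    return max(1.0, round(freq / f0)) * f0


def make_inventory(
    n_phonemes: int = 33,
    class_mix: dict[str, float] | None = None,
    seed: int = 0,
) -> list[PhonemeSpec]:
    """Draw a seeded phoneme inventory with class-specific acoustic structure.

    The class mix is converted to integer counts by largest remainder with at
    least one phoneme per requested class.  Vowel formant contours are linear
    ramps with per-phoneme endpoints, so different vowels have distinct
    formant dynamics.
    """
    mix = dict(DEFAULT_CLASS_MIX if class_mix is None else class_mix)
    total = sum(mix.values())
    if total <= 0:
        raise ValueError("class_mix proportions must sum to a positive value")
    mix = {k: v / total for k, v in mix.items() if v > 0}
    if n_phonemes < len(mix):
        raise ValueError(f"n_phonemes={n_phonemes} < {len(mix)} requested classes")
    # largest-remainder apportionment with >= 1 per class
    raw = {k: n_phonemes * v for k, v in mix.items()}
    counts = {k: max(1, int(np.floor(r))) for k, r in raw.items()}
    while sum(counts.values()) > n_phonemes:
        k = max(counts, key=lambda k: counts[k])
        counts[k] -= 1
    rema = sorted(mix, key=lambda k: raw[k] - np.floor(raw[k]), reverse=True)
    i = 0
    while sum(counts.values()) < n_phonemes:
        counts[rema[i % len(rema)]] += 1
        i += 1

    rng = np.random.default_rng(seed)
    inventory: list[PhonemeSpec] = []
    n_ctrl = 5  # contour control points over normalized token time
    for klass in PHONEME_CLASSES:
        for idx in range(counts.get(klass, 0)):
            label = f"{klass[0]}{idx:02d}"
            if klass == "vowel":
                f0 = rng.uniform(95.0, 240.0)
                a, b = rng.uniform(320.0, 850.0, size=2)
                f1 = np.linspace(a, b, n_ctrl)
                c = rng.uniform(f1.max() + 350.0, 2300.0)
                d = rng.uniform(f1.max() + 350.0, 2300.0)
                f2 = np.linspace(c, d, n_ctrl)
                f1 = np.array([_snap_to_harmonic(f, f0) for f in f1])
                f2 = np.array([_snap_to_harmonic(f, f0) for f in f2])
                f2 = np.maximum(f2, f1 + f0)  # keep F1 < F2 after snapping
                inventory.append(
                    PhonemeSpec(label, klass, (0.10, 0.25), f0=f0, f1_contour=f1, f2_contour=f2)
                )
            elif klass == "nasal":
                f0 = rng.uniform(95.0, 200.0)
                f1 = np.full(n_ctrl, _snap_to_harmonic(rng.uniform(200.0, 350.0), f0))
                f2 = np.full(n_ctrl, _snap_to_harmonic(rng.uniform(2000.0, 2600.0), f0))
                inventory.append(
                    PhonemeSpec(label, klass, (0.06, 0.15), f0=f0, f1_contour=f1, f2_contour=f2)
                )
            elif klass == "plosive":
                vot = rng.uniform(0.010, 0.080)
                peak = rng.uniform(1500.0, 6000.0)
                inventory.append(
                    PhonemeSpec(label, klass, (0.06, 0.12), vot=vot, spectral_peak=peak)
                )
            else:  # fricative
                peak = rng.uniform(2000.0, 7000.0)
                inventory.append(
                    PhonemeSpec(label, klass, (0.08, 0.20), spectral_peak=peak)
                )
    return inventory


def _resonator(src: np.ndarray, freq: float, bw: float, fs: float) -> np.ndarray:
    """Second-order all-pole resonator, gain-normalized at resonance."""
    r = np.exp(-np.pi * bw / fs)
    theta = 2.0 * np.pi * freq / fs
    a = [1.0, -2.0 * r * np.cos(theta), r * r]
    b = [(1.0 - r) * np.sqrt(1.0 - 2.0 * r * np.cos(2 * theta) + r * r)]
    return signal.lfilter(b, a, src)


def _voiced_token(spec: PhonemeSpec, n: int, f0: float, f1c: np.ndarray,
                  f2c: np.ndarray, fs: float) -> np.ndarray:
    """Impulse train through time-varying F1/F2 resonators (piecewise const)."""
    src = np.zeros(n)
    period = max(2, int(round(fs / f0)))
    src[::period] = 1.0
    n_seg = max(1, min(8, n // 64))
    bounds = np.linspace(0, n, n_seg + 1).astype(int)
    out = np.zeros(n)
    t_norm = np.arange(len(f1c)) / max(1, len(f1c) - 1)
    for s, e in zip(bounds[:-1], bounds[1:]):
        if e <= s:
            continue
        mid = (s + e) / 2.0 / n
        f1 = float(np.interp(mid, t_norm, f1c))
        f2 = float(np.interp(mid, t_norm, f2c))
        amp2 = 0.15 if spec.klass == "nasal" else 0.4
        out[s:e] = _resonator(src[s:e], f1, 90.0, fs) + amp2 * _resonator(src[s:e], f2, 140.0, fs)
    return out


def synthesize(
    inventory: list[PhonemeSpec],
    n_tokens: int,
    jitter_sd: float = 0.05,
    seed: int = 0,
    silence_range: tuple[float, float] = (0.020, 0.080),
) -> tuple[np.ndarray, Transcript, GroundTruth]:
    """Synthesize a labeled token sequence; returns (waveform, transcript, truth).

    ``jitter_sd`` is the log-sd of per-token multiplicative lognormal jitter
    applied independently to F0, formants, VOT and spectral peak.  With the
    same seed the output is bit-identical.
    """
    if n_tokens < 1:
        raise ValueError("n_tokens must be >= 1")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    rng = np.random.default_rng(seed)
    fs = float(SAMPLE_RATE)

    pieces: list[np.ndarray] = []
    intervals: list[tuple[int, int, str]] = []
    token_rows: list[dict] = []
    track_spans: list[tuple[int, int, float, np.ndarray, np.ndarray]] = []
    pos = 0

    def add_silence():
        nonlocal pos
        n = int(round(rng.uniform(*silence_range) * fs))
        pieces.append(np.zeros(n))
        intervals.append((pos, pos + n, SILENCE_LABEL))
        pos += n

    def jit() -> float:
        return float(np.exp(rng.normal(0.0, jitter_sd))) if jitter_sd > 0 else 1.0

    for _ in range(n_tokens):
        add_silence()
        spec = inventory[rng.integers(len(inventory))]
        dur = rng.uniform(*spec.duration_range)
        row = {"label": spec.label, "klass": spec.klass,
               "vot": np.nan, "spectral_peak": np.nan}
        if spec.klass == "plosive":
            vot = spec.vot * jit()
            peak = spec.spectral_peak * jit()
            dur = max(dur, vot + 0.025)
            n = int(round(dur * fs))
            n_vot = int(round(vot * fs))
            n_burst = min(n - n_vot, int(round(0.020 * fs)))
            tok = np.zeros(n)
            burst = _resonator(rng.standard_normal(n_burst), peak, 500.0, fs)
            tok[n_vot : n_vot + n_burst] = burst
            row.update(vot=vot, spectral_peak=peak)
        elif spec.klass == "fricative":
            peak = spec.spectral_peak * jit()
            n = int(round(dur * fs))
            tok = _resonator(rng.standard_normal(n), peak, 800.0, fs)
            row.update(spectral_peak=peak)
        else:  # voiced
            f0 = spec.f0 * jit()
            f1c = spec.f1_contour * jit()
            f2c = spec.f2_contour * jit()
            f2c = np.maximum(f2c, f1c + 50.0)
            n = int(round(dur * fs))
            tok = _voiced_token(spec, n, f0, f1c, f2c, fs)
            track_spans.append((pos, pos + n, f0, f1c, f2c))
        rms = np.sqrt(np.mean(tok**2))
        if rms > 0:
            tok = tok * (0.1 / rms)
        pieces.append(tok)
        intervals.append((pos, pos + n, spec.label))
        row.update(start=pos, end=pos + n)
        token_rows.append(row)
        pos += n
    add_silence()

    waveform = np.concatenate(pieces)
    transcript = Transcript(tuple(intervals))

    n_frames = waveform.size // FRAME_STEP_SAMPLES
    f0_tr = np.full(n_frames, np.nan)
    f1_tr = np.full(n_frames, np.nan)
    f2_tr = np.full(n_frames, np.nan)
    t_norm_ctrl = None
    for s, e, f0, f1c, f2c in track_spans:
        fr0 = int(np.ceil(s / FRAME_STEP_SAMPLES))
        fr1 = min(n_frames, int(np.ceil(e / FRAME_STEP_SAMPLES)))
        if fr1 <= fr0:
            continue
        centers = np.arange(fr0, fr1) * FRAME_STEP_SAMPLES
        tt = (centers - s) / max(1, e - s)
        if t_norm_ctrl is None or len(t_norm_ctrl) != len(f1c):
            t_norm_ctrl = np.arange(len(f1c)) / max(1, len(f1c) - 1)
        f0_tr[fr0:fr1] = f0
        f1_tr[fr0:fr1] = np.interp(tt, t_norm_ctrl, f1c)
        f2_tr[fr0:fr1] = np.interp(tt, t_norm_ctrl, f2c)

    tokens = pd.DataFrame(
        token_rows, columns=["label", "klass", "start", "end", "vot", "spectral_peak"]
    )
    truth = GroundTruth(f0_tr, f1_tr, f2_tr, tokens)
    return waveform, transcript, truth


def phoneme_instances(transcript: Transcript, label: str) -> list[tuple[int, int]]:
    """All [start, end) sample intervals carrying ``label``, onset-sorted.

    Returns an empty list when the label is absent (not an error).
    """
    return [(s, e) for s, e, lab in transcript.intervals if lab == label]


def read_phn(path) -> Transcript:
    """Read a TIMIT-style .PHN transcript (start end label per line, samples)."""
    ivs = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            s, e, lab = int(parts[0]), int(parts[1]), parts[2]
            ivs.append((s, e, lab))
    return Transcript(tuple(ivs))


def write_phn(path, transcript: Transcript) -> None:
    with open(path, "w") as fh:
        for s, e, lab in transcript.intervals:
            fh.write(f"{s} {e} {lab}\n")


def write_ground_truth(path, truth: GroundTruth) -> None:
    """Write per-frame tracks as TSV (frame, f0, f1, f2) plus a token table."""
    frames = pd.DataFrame(
        {"frame": np.arange(truth.n_frames), "f0": truth.f0, "f1": truth.f1, "f2": truth.f2}
    )
    frames.to_csv(path, sep="\t", index=False)
    truth.tokens.to_csv(str(path) + ".tokens.tsv", sep="\t", index=False)
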