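"""Decoding acoustic parameters (F0, F1, F2, VOT, spectral peak) from unit
response amplitudes with a cross-validated linear model.

Per-instance parameters come from the ground-truth tracks (median over the
instance's frames) and from the cochleogram (spectral peak).  The decoder is
ordinary least squares y = w.x + b; a test prediction counts as correct when
its absolute error is smaller than the root-mean-squared error of the model
on its own training split.  Significance against a uniform random decoder
(sharing the same correctness threshold) is a two-sample t-test over the
per-fold accuracies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import toeplitz

from .cochlea import Cochleogram
from .corpus import FRAME_STEP_SAMPLES, SILENCE_LABEL, GroundTruth, Transcript
from .model import SHMAXResults

__all__ = [
    "DecodingResult",
    "estimate_params",
    "amplitude_matrix",
    "linear_decode_cv",
    "random_decoder_cv",
    "significance",
    "group_decoding",
    "cochleogram_baseline",
    "lpc_formant_track",
]

PARAM_COLUMNS = ("f0", "f1", "f2", "vot", "spectral_peak")


@dataclass
class DecodingResult:
    """Per-fold test accuracies of the linear decoder, its per-fold training
    RMSEs, and (when computed) the random-decoder accuracies and t-test p."""

    accuracies: np.ndarray
    train_rmse: np.ndarray
    random_accuracies: np.ndarray | None = None
    p_value: float = float("nan")
    parameter: str = ""
    unit_subset: str = "all"

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))


def _instance_frames(interval, n_frames):
    f0 = interval[0] // FRAME_STEP_SAMPLES
    f1 = max(f0 + 1, interval[1] // FRAME_STEP_SAMPLES)
    return f0, min(f1, n_frames)


def estimate_params(
    cochleogram: Cochleogram,
    transcript: Transcript,
    ground_truth: GroundTruth | None = None,
) -> pd.DataFrame:
    """Per-instance acoustic parameters, one row per non-silence instance in
    transcript order.

    F0/F1/F2 are the median of the per-frame tracks over the instance
    (NaN for unvoiced instances); the spectral peak is the center frequency
    of the maximum-energy channel within the instance; VOT comes from the
    ground-truth token table.
    """
    rows = []
    tok = ground_truth.tokens.set_index("start") if ground_truth is not None else None
    for s, e, lab in transcript.intervals:
        if lab == SILENCE_LABEL:
            continue
        f0, f1 = _instance_frames((s, e), cochleogram.n_frames)
        row = {"label": lab, "start": s, "end": e,
               "f0": np.nan, "f1": np.nan, "f2": np.nan, "vot": np.nan}
        if ground_truth is not None and f1 > f0:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
                row["f0"] = np.nanmedian(ground_truth.f0[f0:f1])
                row["f1"] = np.nanmedian(ground_truth.f1[f0:f1])
                row["f2"] = np.nanmedian(ground_truth.f2[f0:f1])
        seg = cochleogram.energy[:, f0:f1]
        if seg.size:
            row["spectral_peak"] = float(
                cochleogram.center_freqs[int(np.argmax(seg.max(axis=1)))]
            )
        else:
            row["spectral_peak"] = np.nan
        if tok is not None and s in tok.index:
            row["vot"] = float(tok.loc[s, "vot"])
            row["klass"] = tok.loc[s, "klass"]
        rows.append(row)
    return pd.DataFrame(rows)


def amplitude_matrix(
    results: SHMAXResults, transcript: Transcript, layer_id: str, index: int = 0
) -> tuple[np.ndarray, pd.DataFrame]:
    """Instances x units response-amplitude matrix for one layer, aligned
    with the non-silence instances of the transcript (in order)."""
    jump = results.layer_jump(layer_id)
    resp = results.unit_responses(layer_id, index)
    n_frames = resp.shape[1]
    X_rows, meta = [], []
    for s, e, lab in transcript.intervals:
        if lab == SILENCE_LABEL:
            continue
        lo = int(np.ceil((s // FRAME_STEP_SAMPLES) / jump))
        hi = int(np.ceil((e // FRAME_STEP_SAMPLES) / jump))
        hi = min(hi, n_frames)
        if hi <= lo:
            continue
        X_rows.append(np.abs(resp[:, lo:hi]).max(axis=1))
        meta.append({"label": lab, "start": s, "end": e})
    return np.stack(X_rows), pd.DataFrame(meta)


def _fold_split(n: int, folds: int, seed: int) -> list[np.ndarray]:
    """Seeded shuffle then contiguous blocks; every instance is a test
    sample exactly once."""
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n)
    return np.array_split(idx, folds)


def _ols_fit(X, y):
    A = np.column_stack([X, np.ones(len(X))])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return coef


def _ols_predict(X, coef):
    return np.column_stack([X, np.ones(len(X))]) @ coef


def linear_decode_cv(X, y, folds: int = 20, seed: int = 0,
                     parameter: str = "", unit_subset: str = "all") -> DecodingResult:
    """K-fold linear decoding with the training-RMSE correctness criterion.

    Rows of X/y with non-finite y are dropped.  Rank-deficient designs fall
    back to the minimum-norm least-squares solution.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(y)
    X, y = X[keep], y[keep]
    if len(y) < folds:
        raise ValueError(f"need >= {folds} instances with defined y, have {len(y)}")
    splits = _fold_split(len(y), folds, seed)
    accs, rmses = [], []
    for k in range(folds):
        test = splits[k]
        train = np.concatenate([splits[j] for j in range(folds) if j != k])
        coef = _ols_fit(X[train], y[train])
        rmse = float(np.sqrt(np.mean((_ols_predict(X[train], coef) - y[train]) ** 2)))
        err = np.abs(_ols_predict(X[test], coef) - y[test])
        accs.append(float(np.mean(err < rmse)))
        rmses.append(rmse)
    return DecodingResult(np.array(accs), np.array(rmses),
                          parameter=parameter, unit_subset=unit_subset)


def random_decoder_cv(y, folds: int = 20, seed: int = 0,
                      thresholds: np.ndarray | None = None) -> np.ndarray:
    """Chance-level accuracies: per test sample, draw uniformly between the
    training split's min and max of y and apply the same correctness
    threshold (the linear fit's per-fold training RMSE when provided,
    otherwise the training split's standard deviation)."""
    y = np.asarray(y, dtype=float)
    y = y[np.isfinite(y)]
    if len(y) < folds:
        raise ValueError(f"need >= {folds} instances, have {len(y)}")
    splits = _fold_split(len(y), folds, seed)
    rng = np.random.default_rng(seed + 1)
    accs = []
    for k in range(folds):
        test = splits[k]
        train = np.concatenate([splits[j] for j in range(folds) if j != k])
        lo, hi = y[train].min(), y[train].max()
        if hi == lo:
            warnings.warn("constant target: random decoder accuracy is 1 by construction")
            accs.append(1.0)
            continue
        thr = thresholds[k] if thresholds is not None else float(np.std(y[train]))
        draws = rng.uniform(lo, hi, size=len(test))
        accs.append(float(np.mean(np.abs(draws - y[test]) < thr)))
    return np.array(accs)


def significance(linear_acc, random_acc) -> float:
    """Two-sample Student's t-test p-value comparing the two accuracy sets."""
    a = np.asarray(linear_acc, dtype=float)
    b = np.asarray(random_acc, dtype=float)
    if np.std(a) == 0 and np.std(b) == 0:
        return 1.0 if np.mean(a) == np.mean(b) else 0.0
    p = stats.ttest_ind(a, b).pvalue
    return float(p)


def decode_with_significance(X, y, folds: int = 20, seed: int = 0,
                             parameter: str = "", unit_subset: str = "all") -> DecodingResult:
    """Linear decoding plus the matched random decoder and its t-test."""
    res = linear_decode_cv(X, y, folds=folds, seed=seed, parameter=parameter,
                           unit_subset=unit_subset)
    yy = np.asarray(y, dtype=float)
    yy = yy[np.isfinite(yy)]
    rnd = random_decoder_cv(yy, folds=folds, seed=seed, thresholds=res.train_rmse)
    res.random_accuracies = rnd
    res.p_value = significance(res.accuracies, rnd)
    return res


def group_decoding(X, unit_groups, y, folds: int = 20, seed: int = 0,
                   parameter: str = "") -> pd.DataFrame:
    """Decode restricted to each unit group; one row per non-empty group."""
    unit_groups = np.asarray(unit_groups)
    rows = []
    for g in np.unique(unit_groups):
        cols = np.flatnonzero(unit_groups == g)
        if len(cols) == 0:
            warnings.warn(f"group {g} is empty; skipped")
            continue
        try:
            res = decode_with_significance(X[:, cols], y, folds=folds, seed=seed,
                                           parameter=parameter, unit_subset=str(g))
        except ValueError as exc:
            warnings.warn(f"group {g} skipped: {exc}")
            continue
        rows.append({"group": g, "n_units": len(cols), "parameter": parameter,
                     "mean_accuracy": res.mean_accuracy,
                     "random_accuracy": float(np.mean(res.random_accuracies)),
                     "p_value": res.p_value})
    return pd.DataFrame(rows)


def cochleogram_baseline(
    cochleogram: Cochleogram,
    transcript: Transcript,
    y,
    window_ms: int = 170,
    folds: int = 20,
    seed: int = 0,
    parameter: str = "",
) -> DecodingResult:
    """Decode from onset-aligned raw cochleogram windows (default 170 ms),
    flattened per instance; instances running past the end are zero-padded."""
    step = cochleogram.frame_step
    win = int(round(window_ms / step))
    feats = []
    n_pad = 0
    for s, e, lab in transcript.intervals:
        if lab == SILENCE_LABEL:
            continue
        f0 = s // FRAME_STEP_SAMPLES
        seg = cochleogram.energy[:, f0 : f0 + win]
        if seg.shape[1] < win:
            n_pad += 1
            seg = np.pad(seg, ((0, 0), (0, win - seg.shape[1])))
        feats.append(seg.ravel())
    if n_pad:
        warnings.warn(f"zero-padded {n_pad} instances shorter than the window")
    X = np.stack(feats)
    return decode_with_significance(X, y, folds=folds, seed=seed,
                                    parameter=parameter, unit_subset="cochleogram")


def lpc_formant_track(waveform, fs: int = 16000, order: int = 12,
                      frame_ms: float = 25.0, hop_ms: float = 1.0) -> np.ndarray:
    """LPC-based F1/F2 tracker for real recordings (plumbing; synthetic
    corpora carry exact ground-truth tracks and bypass this).

    Returns an (n_frames, 2) array of formant estimates in Hz (NaN where no
    resonance is found)."""
    x = np.asarray(waveform, dtype=float)
    frame = int(frame_ms * fs / 1000)
    hop = int(hop_ms * fs / 1000)
    n = max(0, (len(x) - frame) // hop + 1)
    out = np.full((n, 2), np.nan)
    w = np.hamming(frame)
    for i in range(n):
        seg = x[i * hop : i * hop + frame] * w
        if np.std(seg) < 1e-8:
            continue
        # autocorrelation method
        r = np.correlate(seg, seg, "full")[frame - 1 : frame + order]
        try:
            a = np.linalg.solve(toeplitz(r[:-1]), -r[1:])
        except np.linalg.LinAlgError:
            continue
        roots = np.roots(np.concatenate([[1.0], a]))
        roots = roots[np.imag(roots) > 0.01]
        freqs = np.sort(np.angle(roots) * fs / (2 * np.pi))
        freqs = freqs[(freqs > 150) & (freqs < 5000)]
        out[i, : min(2, len(freqs))] = freqs[:2]
    return out
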