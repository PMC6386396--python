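"""Temporal variation index (TVI) of phoneme formant contours.

A phoneme's F1 (or F2) contour is the average, over all its instances, of
the per-instance formant track resampled to a common length.  PCA across
phonemes yields a first principal component of contour shape; a phoneme's
TVI is the signed projection of its (centered) contour onto that component.
Correlating a unit's mean responses per phoneme with the TVIs measures how
strongly the unit encodes formant dynamics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .corpus import FRAME_STEP_SAMPLES, SILENCE_LABEL, GroundTruth, Transcript

__all__ = ["ContourSet", "build_contours", "tvi", "tvi_correlation"]


@dataclass
class ContourSet:
    """Per-phoneme averaged F1/F2 contours of common length T."""

    f1: np.ndarray  # (P, T)
    f2: np.ndarray  # (P, T)
    labels: list[str]
    counts: np.ndarray  # instances per phoneme

    @property
    def T(self) -> int:
        return self.f1.shape[1]


def _resample(track: np.ndarray, T: int) -> np.ndarray | None:
    ok = np.isfinite(track)
    if ok.sum() < 2:
        return None
    xs = np.flatnonzero(ok)
    t_new = np.linspace(xs[0], xs[-1], T)
    return np.interp(t_new, xs, track[ok])


def build_contours(
    ground_truth: GroundTruth, transcript: Transcript, T: int = 50
) -> ContourSet:
    """Average per-instance formant tracks (resampled to T points) per
    phoneme.  Phonemes with no voiced frames are excluded with a warning."""
    per_label: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
    for s, e, lab in transcript.intervals:
        if lab == SILENCE_LABEL:
            continue
        f0 = s // FRAME_STEP_SAMPLES
        f1 = min(e // FRAME_STEP_SAMPLES, ground_truth.n_frames)
        if f1 <= f0:
            continue
        c1 = _resample(ground_truth.f1[f0:f1], T)
        c2 = _resample(ground_truth.f2[f0:f1], T)
        if c1 is None or c2 is None:
            continue
        per_label.setdefault(lab, []).append((c1, c2))

    all_labels = sorted(transcript.labels() - {SILENCE_LABEL})
    skipped = [lab for lab in all_labels if lab not in per_label]
    if skipped:
        warnings.warn(f"phonemes without voiced frames excluded: {skipped}")
    labels = sorted(per_label)
    if not labels:
        raise ValueError("no phoneme has voiced frames with defined formants")
    f1 = np.stack([np.mean([c for c, _ in per_label[lab]], axis=0) for lab in labels])
    f2 = np.stack([np.mean([c for _, c in per_label[lab]], axis=0) for lab in labels])
    counts = np.array([len(per_label[lab]) for lab in labels])
    return ContourSet(f1, f2, labels, counts)


def tvi(contours: ContourSet | np.ndarray, formant: str = "F1",
        center: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Project each phoneme's contour onto the first principal component of
    all phonemes' contours.

    Returns (tvis, pc1).  The PC1 sign is fixed so its largest-magnitude
    element is positive; by default contours are mean-centered across
    phonemes before both the PCA and the projection.
    """
    if isinstance(contours, ContourSet):
        X = contours.f1 if formant.upper() == "F1" else contours.f2
    else:
        X = np.asarray(contours, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 phonemes")
    Xc = X - X.mean(axis=0) if center else X
    if not np.any(Xc):
        raise ValueError("zero-variance contours: TVI undefined")
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    pc1 = Vt[0]
    if pc1[np.argmax(np.abs(pc1))] < 0:
        pc1 = -pc1
    return Xc @ pc1, pc1


def tvi_correlation(responses: np.ndarray, tvis: np.ndarray) -> np.ndarray:
    """Pearson correlation between unit responses per phoneme and the TVIs.

    ``responses`` is (n_units, P) or (P,); zero-variance response vectors
    yield NaN with a warning.
    """
    R = np.atleast_2d(np.asarray(responses, dtype=float))
    t = np.asarray(tvis, dtype=float)
    if R.shape[1] != len(t):
        raise ValueError("responses and tvis disagree on phoneme count")
    if R.shape[1] < 3:
        raise ValueError("need at least 3 phonemes")
    out = np.empty(R.shape[0])
    tc = t - t.mean()
    for i, row in enumerate(R):
        rc = row - row.mean()
        denom = np.linalg.norm(rc) * np.linalg.norm(tc)
        if denom == 0:
            warnings.warn(f"unit {i} has zero response variance; correlation NaN")
            out[i] = np.nan
        else:
            out[i] = float(rc @ tc / denom)
    return out
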