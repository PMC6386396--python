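"""Phoneme-selectivity statistics of network units.

A "unit" here is one feature map at the analysis layer; its per-frame
response is the maximum absolute activation over the frequency axis of that
map.  A unit's response amplitude for a phoneme instance is the maximum of
that stream over the frames overlapping the instance.

The phoneme selectivity index (PSI) of a unit for phoneme p counts how many
other phonemes have a statistically smaller median response amplitude
(one-sided rank-sum, p < 0.01); with P phonemes it ranges 0..P-1.  The
F-ratio of a layer is the ratio of between-group to within-group variability
of the active units' PSI vectors:

    F = [sum_j m_j ||pbar_j - pbar||^2 / (n-1)] /
        [sum_j sum_{i in Omega_j} ||p_i - pbar_j||^2 / (m-n)]

Lifetime sparseness of a unit is S = 1 - (E[r])^2 / E[r^2] over its
(rectified) per-frame responses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.stats import mannwhitneyu

from .corpus import FRAME_STEP_SAMPLES, SILENCE_LABEL, Transcript
from .model import SHMAX, ArchitectureSpec, SHMAXResults

__all__ = [
    "ResponseTable",
    "PSIMatrix",
    "rank_sum_greater",
    "response_amplitudes",
    "active_units",
    "psi_vector",
    "psi_matrix",
    "cluster_psi",
    "f_ratio",
    "feature_psi",
    "phoneme_feature_map",
    "lifetime_sparseness",
    "lambda_sweep",
]


@dataclass
class ResponseTable:
    """Per-(unit, phoneme-instance) response amplitudes plus per-unit silence
    and sampled speech frame responses."""

    amplitudes: dict[str, np.ndarray]  # label -> (n_units, n_instances)
    silence: np.ndarray  # (n_units, n_silence_frames)
    speech: np.ndarray  # (n_units, n_sampled_speech_frames)

    @property
    def n_units(self) -> int:
        return self.silence.shape[0]

    @property
    def labels(self) -> list[str]:
        return list(self.amplitudes)


@dataclass
class PSIMatrix:
    """Units x phonemes integer selectivity matrix with optional grouping."""

    values: np.ndarray  # (n_units, P) integers in [0, P-1]
    phoneme_labels: list[str]
    unit_ids: np.ndarray
    groups: np.ndarray | None = None  # per-unit group labels
    phoneme_order: np.ndarray | None = None

    @property
    def n_phonemes(self) -> int:
        return self.values.shape[1]


def rank_sum_greater(x, y, exact_below: int = 20) -> float:
    """One-sided Wilcoxon rank-sum p-value for median(x) > median(y).

    Exact enumeration for small tie-free samples, midrank-corrected normal
    approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0 and y.std() == 0 and len(x) and len(y) and x[0] == y[0]:
        return 1.0
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (max(len(x), len(y)) < exact_below and not has_ties) else "asymptotic"
    return float(mannwhitneyu(x, y, alternative="greater", method=method).pvalue)


def _layer_frames_in(interval: tuple[int, int], jump: int, n_frames: int) -> np.ndarray:
    """Layer-frame indices whose receptive-field onset falls inside the
    half-open sample interval (converted to 1-ms input frames)."""
    f0 = interval[0] // FRAME_STEP_SAMPLES
    f1 = interval[1] // FRAME_STEP_SAMPLES
    lo = int(np.ceil(f0 / jump))
    hi = int(np.ceil(f1 / jump))
    return np.arange(lo, min(hi, n_frames))


def response_amplitudes(
    responses: np.ndarray | SHMAXResults,
    transcript: Transcript,
    layer_id: str | None = None,
    jump: int | None = None,
    index: int = 0,
    n_speech_frames: int = 1000,
    seed: int = 0,
) -> ResponseTable:
    """Build the response table for one layer.

    ``responses`` is either a fitted :class:`SHMAXResults` (``layer_id``
    selects the layer, ``index`` the corpus entry) or an (n_units, n_frames)
    array with ``jump`` giving the layer's temporal down-sampling factor.
    Instances that fall outside the encoded range are skipped with a warning.
    """
    if isinstance(responses, SHMAXResults):
        jump = responses.layer_jump(layer_id)
        resp = responses.unit_responses(layer_id, index)
    else:
        resp = np.asarray(responses)
        if jump is None:
            raise ValueError("jump required when passing a raw response array")
    n_units, n_frames = resp.shape

    amps: dict[str, list[np.ndarray]] = {}
    sil_frames: list[np.ndarray] = []
    speech_frames: list[np.ndarray] = []
    skipped = 0
    for s, e, lab in transcript.intervals:
        fr = _layer_frames_in((s, e), jump, n_frames)
        if lab == SILENCE_LABEL:
            if len(fr):
                sil_frames.append(fr)
            continue
        if len(fr) == 0:
            skipped += 1
            continue
        speech_frames.append(fr)
        amps.setdefault(lab, []).append(np.abs(resp[:, fr]).max(axis=1))
    if skipped:
        warnings.warn(f"skipped {skipped} instances outside the encoded range")

    amplitudes = {lab: np.stack(cols, axis=1) for lab, cols in sorted(amps.items())}
    silence = resp[:, np.concatenate(sil_frames)] if sil_frames else np.empty((n_units, 0))
    if speech_frames:
        pool_idx = np.concatenate(speech_frames)
        rng = np.random.default_rng(seed)
        take = rng.choice(pool_idx, size=min(n_speech_frames, len(pool_idx)), replace=False)
        speech = resp[:, take]
    else:
        speech = np.empty((n_units, 0))
    return ResponseTable(amplitudes, silence, speech)


def active_units(table: ResponseTable, alpha: float = 0.001) -> np.ndarray:
    """Units whose sampled speech-frame responses are statistically larger
    than their silence-frame responses (one-sided rank-sum)."""
    if table.silence.shape[1] < 2:
        raise ValueError(
            "no silence frames in the corpus; regenerate with inter-token silence"
        )
    if table.speech.shape[1] < 2:
        raise ValueError("need at least 2 sampled speech frames")
    keep = [u for u in range(table.n_units)
            if rank_sum_greater(table.speech[u], table.silence[u]) < alpha]
    return np.array(keep, dtype=int)


def psi_vector(table: ResponseTable, unit: int, alpha: float = 0.01) -> np.ndarray:
    """PSI vector of one unit over the table's phonemes (those with >= 2
    instances; others are excluded from both sides of the comparisons)."""
    labels = [lab for lab in table.labels if table.amplitudes[lab].shape[1] >= 2]
    dropped = set(table.labels) - set(labels)
    if dropped:
        warnings.warn(f"phonemes with <2 instances excluded: {sorted(dropped)}")
    out = np.zeros(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        x = table.amplitudes[lab][unit]
        for j, other in enumerate(labels):
            if j == i:
                continue
            if rank_sum_greater(x, table.amplitudes[other][unit]) < alpha:
                out[i] += 1
    return out


def psi_matrix(table: ResponseTable, units: np.ndarray | None = None,
               alpha: float = 0.01, exact_below: int = 20) -> PSIMatrix:
    """Stack PSI vectors of the given units (default: all).

    Equivalent to calling :func:`psi_vector` per unit, but the rank-sum
    tests are vectorized across units per phoneme pair.
    """
    if units is None:
        units = np.arange(table.n_units)
    units = np.asarray(units)
    labels = [lab for lab in table.labels if table.amplitudes[lab].shape[1] >= 2]
    dropped = set(table.labels) - set(labels)
    if dropped:
        warnings.warn(f"phonemes with <2 instances excluded: {sorted(dropped)}")
    P = len(labels)
    vals = np.zeros((len(units), P), dtype=int)
    if len(units) == 0 or P == 0:
        return PSIMatrix(vals, labels, units)
    amps = {lab: table.amplitudes[lab][units] for lab in labels}
    for i, lab in enumerate(labels):
        x = amps[lab]
        for j, other in enumerate(labels):
            if j == i:
                continue
            y = amps[other]
            pooled = np.concatenate([x, y], axis=1)
            has_ties = any(len(np.unique(row)) < pooled.shape[1] for row in pooled)
            n = max(x.shape[1], y.shape[1])
            method = "exact" if (n < exact_below and not has_ties) else "asymptotic"
            p = mannwhitneyu(x, y, alternative="greater", method=method,
                             axis=-1).pvalue
            vals[:, i] += (p < alpha).astype(int)
    return PSIMatrix(vals, labels, units)


def cluster_psi(psi: PSIMatrix, n_groups: int = 6,
                method: str = "ward") -> PSIMatrix:
    """Agglomerative clustering (Euclidean) of units into ``n_groups``;
    also orders the phoneme axis by its dendrogram for heatmap layout.
    Returns a new PSIMatrix with ``groups`` and ``phoneme_order`` set."""
    m = psi.values.shape[0]
    if m < n_groups:
        raise ValueError(f"{m} units < {n_groups} groups")
    Z = linkage(psi.values.astype(float), method=method, metric="euclidean")
    groups = fcluster(Z, t=n_groups, criterion="maxclust")
    if psi.values.shape[1] >= 2:
        Zp = linkage(psi.values.T.astype(float), method=method, metric="euclidean")
        order = leaves_list(Zp)
    else:
        order = np.arange(psi.values.shape[1])
    return replace(psi, groups=np.asarray(groups), phoneme_order=np.asarray(order))


def f_ratio(psi: PSIMatrix | np.ndarray, groups: np.ndarray | None = None) -> float:
    """Between- over within-group variability of PSI vectors.

    Returns ``inf`` when within-group variability is exactly zero while the
    group means differ (the degenerate perfectly-clustered case).
    """
    if isinstance(psi, PSIMatrix):
        values = psi.values.astype(float)
        groups = psi.groups if groups is None else groups
    else:
        values = np.asarray(psi, dtype=float)
    if groups is None:
        raise ValueError("group labels required (run cluster_psi first)")
    groups = np.asarray(groups)
    labels = np.unique(groups)
    m, n = len(values), len(labels)
    if n < 2:
        raise ValueError("need at least 2 groups")
    if m <= n:
        raise ValueError("need more units than groups")
    grand = values.mean(axis=0)
    between = 0.0
    within = 0.0
    for g in labels:
        rows = values[groups == g]
        mu = rows.mean(axis=0)
        between += len(rows) * float(np.sum((mu - grand) ** 2))
        within += float(np.sum((rows - mu) ** 2))
    between /= n - 1
    within /= m - n
    if within == 0.0:
        return np.inf if between > 0 else 0.0
    return between / within


def phoneme_feature_map(inventory) -> dict[str, str]:
    """Map phoneme labels to six articulatory-style features: plosive,
    fricative, nasal, and vowels binned by mean F1/F2 into low-back,
    low-front and high-front."""
    mapping: dict[str, str] = {}
    vowels = [s for s in inventory if s.klass == "vowel"]
    if vowels:
        f1s = np.array([np.mean(s.f1_contour) for s in vowels])
        f2s = np.array([np.mean(s.f2_contour) for s in vowels])
        f1_med, f2_med = np.median(f1s), np.median(f2s)
    for s in inventory:
        if s.klass == "vowel":
            f1, f2 = np.mean(s.f1_contour), np.mean(s.f2_contour)
            if f1 >= f1_med:
                mapping[s.label] = "low_back" if f2 < f2_med else "low_front"
            else:
                mapping[s.label] = "high_front"
        else:
            mapping[s.label] = s.klass
    return mapping


def feature_psi(psi: PSIMatrix, phoneme_to_feature: dict[str, str]) -> pd.DataFrame:
    """Average PSI over phonemes sharing a feature; rows are features,
    columns are units."""
    missing = [lab for lab in psi.phoneme_labels if lab not in phoneme_to_feature]
    if missing:
        raise ValueError(f"unmapped phonemes: {missing}")
    feats = sorted({phoneme_to_feature[lab] for lab in psi.phoneme_labels})
    rows = []
    for f in feats:
        cols = [i for i, lab in enumerate(psi.phoneme_labels)
                if phoneme_to_feature[lab] == f]
        rows.append(psi.values[:, cols].mean(axis=1))
    return pd.DataFrame(np.stack(rows), index=feats,
                        columns=[f"u{int(u)}" for u in psi.unit_ids])


def lifetime_sparseness(responses: np.ndarray) -> float:
    """S = 1 - (E[r])^2 / E[r^2] over a unit's per-frame response sequence."""
    r = np.asarray(responses, dtype=float)
    if r.size == 0:
        raise ValueError("empty response sequence")
    m2 = np.mean(r**2)
    if m2 == 0:
        raise ValueError("all-zero responses: sparseness undefined")
    return float(1.0 - np.mean(r) ** 2 / m2)


def _truncate_arch(arch: ArchitectureSpec, layer_id: str) -> ArchitectureSpec:
    return ArchitectureSpec(arch.layers[: arch.index(layer_id) + 1])


def _code_sparseness(res, arch_t, target_s: str, lam: float,
                     n_sample: int = 800, seed: int = 0) -> float:
    """Mean lifetime sparseness of the target layer's sparse-coding
    responses: solve the lasso codes of the learned bases on a random
    patch sample and apply the moment formula per unit.

    The lasso tolerance is relaxed relative to the reference encoder; the
    moment statistics are insensitive at that precision."""
    from .model import _lasso_codes, sample_patches

    idx = arch_t.index(target_s)
    below = res.outputs[arch_t.layers[idx - 1].name][0] if idx > 0 else res.model.inputs[0]
    bank = res.banks[target_s]
    pats = sample_patches(below, n_sample, bank.kernel, seed=seed).astype(float)
    codes = np.abs(_lasso_codes(pats, bank.matrix, lam, tol=1e-4, max_iter=300))
    vals = []
    for j in range(codes.shape[1]):
        if np.any(codes[:, j]):
            vals.append(lifetime_sparseness(codes[:, j]))
    # every unit silent: maximally sparse by convention
    return float(np.mean(vals)) if vals else 1.0


def lambda_sweep(
    inputs,
    transcript: Transcript,
    arch: ArchitectureSpec,
    layer_id: str,
    lambdas,
    seed: int = 0,
    n_patches: int = 2000,
    epochs: int = 3,
    n_groups: int = 4,
    alpha: float = 0.01,
    lower_banks: dict | None = None,
) -> pd.DataFrame:
    """Retrain the dictionary of the S layer feeding ``layer_id`` at each
    lambda (lower layers fixed at their own lambda), and tabulate the layer's
    mean unit lifetime sparseness against its F-ratio.

    ``lower_banks`` supplies pre-trained dictionaries for the layers below
    the target (e.g. from an existing fit with the same seed), skipping the
    baseline training pass.

    Sparseness is measured on the layer's sparse-coding responses (the lasso
    codes of the retrained bases on a random patch sample), which is the
    quantity lambda directly regularizes; the F-ratio is computed from the
    standard convolutional response amplitudes.

    Returns a DataFrame with one row per lambda: (lam, sparseness, f_ratio).
    """
    arch_t = _truncate_arch(arch, layer_id)
    spec = arch_t[layer_id]
    target_s = layer_id if spec.kind == "S" else arch_t.layers[arch_t.index(layer_id) - 1].name
    if lower_banks is not None:
        lower = {name: bank for name, bank in lower_banks.items() if name != target_s}
    else:
        base = SHMAX(inputs, arch_t).fit(n_patches=n_patches, epochs=epochs, seed=seed,
                                         store_outputs=False)
        lower = {name: bank for name, bank in base.banks.items() if name != target_s}
        del base
    rows = []
    for lam in lambdas:
        if lam <= 0:
            raise ValueError("lambda values must be > 0")
        layers = list(arch_t.layers)
        i = arch_t.index(target_s)
        layers[i] = replace(layers[i], lam=float(lam))
        res = SHMAX(inputs, ArchitectureSpec(tuple(layers))).fit(
            n_patches=n_patches, epochs=epochs, seed=seed, fixed_banks=lower
        )
        spars = _code_sparseness(res, arch_t, target_s, lam, seed=seed)
        table = response_amplitudes(res, transcript, layer_id, seed=seed)
        psi = psi_matrix(table, alpha=alpha)
        psi = cluster_psi(psi, n_groups=min(n_groups, len(psi.values) - 1))
        rows.append({"lam": float(lam), "sparseness": spars,
                     "f_ratio": f_ratio(psi)})
    return pd.DataFrame(rows)
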