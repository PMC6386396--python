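"""Hierarchical sparse-coding network (alternating sparse-coding S layers and
pooling C layers) over cochleograms.

The S layers learn convolutional dictionaries by L1-regularized sparse coding

    minimize_{B, r}  sum_k ||x_k - B r_k||_2^2 + lambda ||r_k||_1
    subject to       ||b_j||_2 <= 1,

on patches sampled from the layer input, then encode the input by correlating
each basis with the input (a convolution without kernel flip):

    r_S(h, t, j) = sum_{p,q,u} x(s*h + p, s*t + q, u) * b_j(p, q, u).

The C layers pool each feature map over small overlapping windows (max by
default; average and pass-through variants are controls).

The public surface follows the model/results idiom: build a :class:`SHMAX`
from input cochleograms and an :class:`ArchitectureSpec`, call ``fit`` to
train the dictionaries bottom-up, and use the returned :class:`SHMAXResults`
to encode inputs, read receptive-field extents, and feed the analysis stages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import h5py
import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.decomposition import MiniBatchDictionaryLearning
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso

from .cochlea import Cochleogram

__all__ = [
    "LayerSpec",
    "ArchitectureSpec",
    "DictionaryBank",
    "FeatureStack",
    "default_architecture",
    "compact_architecture",
    "sample_patches",
    "learn_dictionary",
    "encode_conv",
    "encode_optimize",
    "pool",
    "rf_extent",
    "eq1_objective",
    "SHMAX",
    "SHMAXResults",
]


@dataclass(frozen=True)
class LayerSpec:
    """Configuration of one layer.

    S layers carry ``kernel``, ``n_maps``, ``conv_stride``, ``lam`` and
    ``regularizer``; C layers carry the pooling fields.  ``pool_mode``
    'none' makes the C layer a pass-through (control variant).
    """

    kind: str  # 'S' or 'C'
    name: str
    n_maps: int = 0
    kernel: int = 10
    conv_stride: int = 1
    pool_size: int = 2
    pool_stride: int = 1
    pool_mode: str = "max"  # max | average | none
    lam: float = 1.0
    regularizer: str = "L1"  # L1 | L2

    def __post_init__(self):
        if self.kind not in ("S", "C"):
            raise ValueError("layer kind must be 'S' or 'C'")
        if self.kind == "S":
            if self.conv_stride not in (1, 2):
                raise ValueError("conv_stride must be 1 or 2")
            if self.lam <= 0:
                raise ValueError("lambda must be > 0")
        if self.pool_size < 1 or self.pool_stride < 1:
            raise ValueError("pool_size and pool_stride must be >= 1")
        if self.pool_mode not in ("max", "average", "none"):
            raise ValueError(f"unknown pool_mode {self.pool_mode!r}")

    @property
    def stride(self) -> int:
        """Down-sampling factor this layer applies to the position grid."""
        if self.kind == "S":
            return self.conv_stride
        return self.pool_stride if self.pool_mode != "none" else 1


@dataclass(frozen=True)
class ArchitectureSpec:
    """Ordered alternating S/C layer sequence, first layer S."""

    layers: tuple[LayerSpec, ...]

    def __post_init__(self):
        for i, spec in enumerate(self.layers):
            expected = "S" if i % 2 == 0 else "C"
            if spec.kind != expected:
                raise ValueError("layers must alternate S, C starting with S")

    def index(self, layer_id: str) -> int:
        for i, spec in enumerate(self.layers):
            if spec.name == layer_id:
                return i
        raise KeyError(f"unknown layer {layer_id!r}")

    def __getitem__(self, layer_id: str) -> LayerSpec:
        return self.layers[self.index(layer_id)]

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.layers]


DEFAULT_MAPS = (100, 100, 200, 200, 300, 300, 400, 400, 500, 500, 500, 500)
DEFAULT_CONV_STRIDES = (2, 2, 1, 1, 1, 1)


def default_architecture(
    kernels: tuple[int, ...] | int = 10,
    n_maps: tuple[int, ...] = DEFAULT_MAPS,
    conv_strides: tuple[int, ...] = DEFAULT_CONV_STRIDES,
    pool_mode: str = "max",
    lam: float = 1.0,
    regularizer: str = "L1",
) -> ArchitectureSpec:
    """The 12-layer S1..C6 architecture (kernels 10, conv strides 2,2,1,1,1,1,
    pooling window 2 stride 1 after every S layer)."""
    n_s = len(conv_strides)
    if isinstance(kernels, int):
        kernels = (kernels,) * n_s
    layers = []
    for i in range(n_s):
        layers.append(
            LayerSpec("S", f"S{i + 1}", n_maps=n_maps[2 * i], kernel=kernels[i],
                      conv_stride=conv_strides[i], lam=lam, regularizer=regularizer)
        )
        layers.append(
            LayerSpec("C", f"C{i + 1}", n_maps=n_maps[2 * i + 1], pool_size=2,
                      pool_stride=1, pool_mode=pool_mode)
        )
    return ArchitectureSpec(tuple(layers))


def compact_architecture(pool_mode: str = "max", lam: float = 1.0,
                      regularizer: str = "L1",
                      n_maps: tuple[int, ...] = (32, 32, 48, 48)) -> ArchitectureSpec:
    """Desk-scale 4-layer profile (S1-C1-S2-C2) used by the test pipeline."""
    return default_architecture(
        kernels=(10, 10), n_maps=n_maps, conv_strides=(2, 2),
        pool_mode=pool_mode, lam=lam, regularizer=regularizer,
    )


def rf_extent(arch: ArchitectureSpec, layer_id: str) -> tuple[int, int]:
    """Receptive-field extent (channels, frames) of units in ``layer_id``.

    Composed arithmetic: starting from a single input sample, each S layer
    adds (kernel - 1) * jump, each pooling layer adds (pool_size - 1) * jump,
    and the jump multiplies by every stride passed.  Both axes are treated
    identically (square kernels), so the two returned values are equal.
    """
    idx = arch.index(layer_id)
    size, jump = 1, 1
    for spec in arch.layers[: idx + 1]:
        if spec.kind == "S":
            size += (spec.kernel - 1) * jump
            jump *= spec.conv_stride
        elif spec.pool_mode != "none":
            size += (spec.pool_size - 1) * jump
            jump *= spec.pool_stride
    return size, size


def _layer_jump(arch: ArchitectureSpec, layer_id: str) -> int:
    """Input-grid spacing between adjacent positions of ``layer_id``'s maps."""
    idx = arch.index(layer_id)
    jump = 1
    for spec in arch.layers[: idx + 1]:
        jump *= spec.stride
    return jump


@dataclass
class DictionaryBank:
    """Learned bases of one S layer: ``bases`` has shape (m, k, k, u) and
    every basis has L2 norm <= 1 (== 1 after training)."""

    bases: np.ndarray
    layer_id: str = ""

    @property
    def m(self) -> int:
        return self.bases.shape[0]

    @property
    def kernel(self) -> int:
        return self.bases.shape[1]

    @property
    def u(self) -> int:
        return self.bases.shape[3]

    @property
    def matrix(self) -> np.ndarray:
        """Bases flattened to (m, k*k*u), patch order (p, q, channel)."""
        return self.bases.reshape(self.m, -1)


@dataclass
class FeatureStack:
    """One layer's activations: height x frames x maps."""

    values: np.ndarray
    layer_id: str = ""

    @property
    def shape(self):
        return self.values.shape


def _as_array(stack) -> np.ndarray:
    """Accept Cochleogram, 2-D (channels x frames) or 3-D (h x t x u) input."""
    if isinstance(stack, Cochleogram):
        x = stack.energy[:, :, None]
    elif isinstance(stack, FeatureStack):
        x = stack.values
    else:
        x = np.asarray(stack)
        if x.ndim == 2:
            x = x[:, :, None]
    if x.ndim != 3:
        raise ValueError("input must be 2-D or 3-D")
    return x


def sample_patches(stack, n_patches: int, kernel: int, seed: int = 0) -> np.ndarray:
    """Sample ``n_patches`` k x k x u patches uniformly over valid positions.

    Returns an (n_patches, k*k*u) array, rows flattened in (p, q, channel)
    order.  Deterministic for a fixed seed.
    """
    x = _as_array(stack)
    h, t, u = x.shape
    if h < kernel or t < kernel:
        raise ValueError(f"stack {x.shape[:2]} smaller than kernel {kernel}")
    if n_patches < 1:
        raise ValueError("n_patches must be >= 1")
    rng = np.random.default_rng(seed)
    rows = rng.integers(0, h - kernel + 1, size=n_patches)
    cols = rng.integers(0, t - kernel + 1, size=n_patches)
    out = np.empty((n_patches, kernel * kernel * u), dtype=x.dtype)
    for i, (r, c) in enumerate(zip(rows, cols)):
        out[i] = x[r : r + kernel, c : c + kernel, :].ravel()
    return out


def eq1_objective(patches: np.ndarray, bank_matrix: np.ndarray,
                  codes: np.ndarray, lam: float) -> float:
    """Sparse-coding objective sum_k ||x_k - B r_k||^2 + lam ||r_k||_1."""
    resid = patches - codes @ bank_matrix
    return float(np.sum(resid**2) + lam * np.sum(np.abs(codes)))


def _lasso_codes(patches: np.ndarray, bank_matrix: np.ndarray, lam: float,
                 tol: float = 1e-8, max_iter: int = 5000) -> np.ndarray:
    """Solve the lasso subproblem of the sparse-coding objective for fixed B."""
    n_feat = bank_matrix.shape[1]
    clf = Lasso(alpha=lam / (2.0 * n_feat), fit_intercept=False,
                max_iter=max_iter, tol=tol, precompute=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(bank_matrix.T, patches.T)
    coef = clf.coef_
    if coef.ndim == 1:
        coef = coef[None, :]
    return coef


def learn_dictionary(
    patches: np.ndarray,
    m: int,
    lam: float = 1.0,
    epochs: int = 3,
    seed: int = 0,
    kernel: int | None = None,
    u: int | None = None,
    layer_id: str = "",
    regularizer: str = "L1",
    n_init: int = 3,
) -> DictionaryBank:
    """Learn ``m`` unit-norm bases from flattened patches.

    L1 regularization uses online (mini-batch) dictionary learning, restarted
    ``n_init`` times from different initializations with the solution of
    lowest sparse-coding objective (on a patch subsample) retained — the
    online updates can stall in merged-atom local minima.  The L2 variant
    (control experiment, penalty lam*||r||_2^2) uses alternating ridge coding
    and least-squares dictionary updates.

    ``kernel``/``u`` give the patch geometry for reshaping; when omitted the
    patch is assumed square single-channel.
    """
    patches = np.asarray(patches, dtype=float)
    n_feat = patches.shape[1]
    if kernel is None:
        kernel = int(round(np.sqrt(n_feat if u is None else n_feat // u)))
    if u is None:
        u = n_feat // (kernel * kernel)
    if kernel * kernel * u != n_feat:
        raise ValueError("patch length inconsistent with kernel/u")
    if m < 1:
        raise ValueError("m must be >= 1")

    rng = np.random.default_rng(seed)
    norms = np.linalg.norm(patches, axis=1)
    if np.all(norms == 0):
        warnings.warn("all-zero patches; dictionary left at random init")
        init = rng.standard_normal((m, n_feat))
        init /= np.linalg.norm(init, axis=1, keepdims=True)
        return DictionaryBank(init.reshape(m, kernel, kernel, u), layer_id)

    good = np.flatnonzero(norms > 0)

    def _finalize(comp: np.ndarray) -> np.ndarray:
        # renormalize live atoms; reseed dead ones from random data patches
        cn = np.linalg.norm(comp, axis=1)
        dead = cn < 1e-8
        if np.any(dead):
            pick = rng.choice(good, size=int(dead.sum()),
                              replace=len(good) < int(dead.sum()))
            comp[dead] = patches[pick] / norms[pick][:, None]
            cn = np.linalg.norm(comp, axis=1)
        return comp / cn[:, None]

    if regularizer == "L2":
        pick = rng.choice(good, size=m, replace=len(good) < m)
        init = patches[pick] / norms[pick][:, None]
        comp = _finalize(_learn_dictionary_l2(patches, init, lam, epochs * 5))
        return DictionaryBank(comp.reshape(m, kernel, kernel, u), layer_id)

    eval_idx = rng.choice(len(patches), size=min(500, len(patches)), replace=False)
    best, best_obj = None, np.inf
    restart_seeds = np.random.SeedSequence(seed).generate_state(max(1, n_init)) % (2**31)
    for rs in restart_seeds:
        init_rng = np.random.default_rng(int(rs))
        pick = init_rng.choice(good, size=m, replace=len(good) < m)
        init = patches[pick] / norms[pick][:, None]
        mbdl = MiniBatchDictionaryLearning(
            n_components=m,
            alpha=lam / 2.0,  # sklearn objective has a 1/2 on the quadratic
            max_iter=max(1, epochs),
            batch_size=256,
            dict_init=init,
            shuffle=True,
            random_state=int(rs),
            fit_algorithm="cd",
            transform_algorithm="lasso_cd",
            tol=0.0,
            max_no_improvement=None,  # run the requested epochs in full
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # inner lasso convergence chatter
            mbdl.fit(patches)
        comp = _finalize(mbdl.components_)
        obj = eq1_objective(patches[eval_idx], comp,
                            _lasso_codes(patches[eval_idx], comp, lam,
                                         tol=1e-5, max_iter=500), lam)
        if obj < best_obj:
            best, best_obj = comp, obj
    return DictionaryBank(best.reshape(m, kernel, kernel, u), layer_id)


def _learn_dictionary_l2(patches: np.ndarray, init: np.ndarray, lam: float,
                         n_iter: int) -> np.ndarray:
    """Alternating minimization of sum ||x - Br||^2 + lam ||r||^2 over unit-ball B."""
    B = init.T.copy()  # (n_feat, m)
    m = B.shape[1]
    X = patches.T  # (n_feat, K)
    for _ in range(n_iter):
        G = B.T @ B + lam * np.eye(m)
        R = np.linalg.solve(G, B.T @ X)  # ridge codes
        RRt = R @ R.T
        B = np.linalg.lstsq(RRt.T, (X @ R.T).T, rcond=None)[0].T
        nb = np.linalg.norm(B, axis=0)
        B /= np.maximum(nb, 1.0)[None, :]  # project onto the unit ball
    nb = np.linalg.norm(B, axis=0)
    B = B / np.maximum(nb, 1e-12)[None, :]
    return B.T


def encode_conv(stack, bank: DictionaryBank, s_conv: int = 1,
                chunk: int = 4096) -> FeatureStack:
    """Convolutional (correlation) encoding: each basis slides over the input
    with stride ``s_conv``; output (H, T, m) with
    H = floor((h-k)/s)+1, T = floor((t-k)/s)+1."""
    x = _as_array(stack)
    h, t, u = x.shape
    k = bank.kernel
    if u != bank.u:
        raise ValueError(f"input has {u} channels but bank expects {bank.u}")
    if h < k or t < k:
        raise ValueError("input smaller than kernel")
    H = (h - k) // s_conv + 1
    T = (t - k) // s_conv + 1
    W = bank.matrix.T.astype(x.dtype, copy=False)  # (k*k*u, m)
    win = sliding_window_view(x, (k, k), axis=(0, 1))[:: s_conv, :: s_conv]
    win = win[:H, :T]  # (H, T, u, k, k)
    out = np.empty((H, T, bank.m), dtype=np.result_type(x.dtype, W.dtype))
    step = max(1, chunk // max(1, H))
    for j0 in range(0, T, step):
        j1 = min(T, j0 + step)
        block = win[:, j0:j1].transpose(0, 1, 3, 4, 2).reshape(H * (j1 - j0), -1)
        out[:, j0:j1] = (block @ W).reshape(H, j1 - j0, bank.m)
    return FeatureStack(out, bank.layer_id)


def _corpus_rms(stacks) -> float:
    """Root-mean-square over all entries of all stacks (1.0 if all zero)."""
    total = sum(float(np.sum(np.square(s, dtype=np.float64))) for s in stacks)
    count = sum(s.size for s in stacks)
    rms = float(np.sqrt(total / max(1, count)))
    return rms if rms > 0 else 1.0


def encode_optimize(stack, bank: DictionaryBank, lam: float = 1.0,
                    s_conv: int = 1) -> FeatureStack:
    """Reference encoder: per sliding patch, solve the lasso
    min_r ||x - B r||^2 + lam ||r||_1 with the learned bases fixed.

    With lam -> 0 and an orthonormal complete bank this reduces to basis
    inner products.  Much slower than :func:`encode_conv`; intended for
    small inputs and sparseness comparisons.
    """
    x = _as_array(stack)
    h, t, u = x.shape
    k = bank.kernel
    if u != bank.u:
        raise ValueError(f"input has {u} channels but bank expects {bank.u}")
    H = (h - k) // s_conv + 1
    T = (t - k) // s_conv + 1
    win = sliding_window_view(x, (k, k), axis=(0, 1))[:: s_conv, :: s_conv][:H, :T]
    patches = win.transpose(0, 1, 3, 4, 2).reshape(H * T, -1).astype(float)
    if lam == 0:
        codes = np.linalg.lstsq(bank.matrix.T, patches.T, rcond=None)[0].T
    else:
        codes = _lasso_codes(patches, bank.matrix, lam)
    return FeatureStack(codes.reshape(H, T, bank.m), bank.layer_id)


def pool(stack, mode: str = "max", size: int = 2, stride: int = 1) -> FeatureStack:
    """Pool each feature map over size x size windows with the given stride.

    For size 2 / stride 1 the output has one fewer row and one fewer column
    than the input.  ``mode`` 'none' returns the input unchanged.
    """
    x = _as_array(stack)
    lid = stack.layer_id if isinstance(stack, FeatureStack) else ""
    if mode == "none":
        return FeatureStack(x.copy(), lid)
    h, t, _ = x.shape
    if size > h or size > t:
        raise ValueError(f"pool size {size} exceeds stack dims {(h, t)}")
    win = sliding_window_view(x, (size, size), axis=(0, 1))[::stride, ::stride]
    if mode == "max":
        out = win.max(axis=(-2, -1))
    elif mode == "average":
        out = win.mean(axis=(-2, -1))
    else:
        raise ValueError(f"unknown pool mode {mode!r}")
    return FeatureStack(np.ascontiguousarray(out), lid)


class SHMAX:
    """Hierarchical sparse-coding model over a corpus of cochleograms.

    Parameters
    ----------
    inputs : sequence of Cochleogram or 2-D arrays
        The training corpus, one entry per sentence.
    arch : ArchitectureSpec
        Layer sequence; see :func:`default_architecture`.
    """

    def __init__(self, inputs, arch: ArchitectureSpec):
        if isinstance(inputs, (Cochleogram, np.ndarray)):
            inputs = [inputs]
        if len(inputs) == 0:
            raise ValueError("corpus must be non-empty")
        self.inputs = [_as_array(x).astype(np.float32) for x in inputs]
        self.arch = arch

    def fit(self, n_patches: int = 2000, epochs: int = 3, seed: int = 0,
            store_outputs: bool = True, fixed_banks: dict[str, DictionaryBank] | None = None,
            normalize: bool = True) -> "SHMAXResults":
        """Train dictionaries bottom-up: learn the S-layer dictionary from
        random patches of the current representation, encode the corpus,
        pool, and proceed.  Deterministic for a fixed seed.

        With ``normalize`` (default) the input and every S-layer output are
        rescaled to unit RMS over the corpus, so that a given lambda exerts
        a comparable sparsity pressure at every layer; the scales are stored
        on the results for later encoding.

        ``fixed_banks`` maps layer names to pre-trained banks to reuse
        (used by the lambda sweep and kernel-variant controls).
        """
        ss = np.random.SeedSequence(seed)
        layer_seeds = ss.generate_state(2 * len(self.arch.layers)) % (2**31)
        stacks = list(self.inputs)
        scales: dict[str, float] = {}
        if normalize:
            scales["input"] = _corpus_rms(stacks)
            stacks = [(s / scales["input"]).astype(s.dtype, copy=False) for s in stacks]
        banks: dict[str, DictionaryBank] = {}
        outputs: dict[str, list[np.ndarray]] = {}
        for li, spec in enumerate(self.arch.layers):
            if spec.kind == "S":
                if fixed_banks and spec.name in fixed_banks:
                    bank = replace(fixed_banks[spec.name], layer_id=spec.name)
                else:
                    per = max(1, n_patches // len(stacks))
                    pats = np.concatenate(
                        [sample_patches(s, per, spec.kernel,
                                        seed=int(layer_seeds[2 * li] + i))
                         for i, s in enumerate(stacks)]
                    )
                    u = _as_array(stacks[0]).shape[2]
                    bank = learn_dictionary(
                        pats, spec.n_maps, lam=spec.lam, epochs=epochs,
                        seed=int(layer_seeds[2 * li + 1]), kernel=spec.kernel,
                        u=u, layer_id=spec.name, regularizer=spec.regularizer,
                    )
                banks[spec.name] = bank
                stacks = [encode_conv(s, bank, spec.conv_stride).values for s in stacks]
                if normalize:
                    scales[spec.name] = _corpus_rms(stacks)
                    stacks = [(s / scales[spec.name]).astype(s.dtype, copy=False)
                              for s in stacks]
            else:
                stacks = [pool(s, spec.pool_mode, spec.pool_size, spec.pool_stride).values
                          for s in stacks]
            if store_outputs:
                outputs[spec.name] = stacks
        return SHMAXResults(self, banks, outputs, scales)


class SHMAXResults:
    """Fitted network: per-layer dictionary banks plus (optionally) the
    stored layer activations for the training corpus."""

    def __init__(self, model: SHMAX, banks: dict[str, DictionaryBank],
                 outputs: dict[str, list[np.ndarray]] | None = None,
                 scales: dict[str, float] | None = None):
        self.model = model
        self.arch = model.arch
        self.banks = banks
        self.outputs = outputs or {}
        self.scales = scales or {}

    # -- encoding -----------------------------------------------------------
    def encode(self, x, upto: str | None = None) -> dict[str, FeatureStack]:
        """Run one input through the fitted network (applying the training
        normalization scales); returns activations per layer (optionally
        stopping at layer ``upto``)."""
        cur = _as_array(x) / self.scales.get("input", 1.0)
        res: dict[str, FeatureStack] = {}
        for spec in self.arch.layers:
            if spec.kind == "S":
                fs = encode_conv(cur, self.banks[spec.name], spec.conv_stride)
                fs.values = fs.values / self.scales.get(spec.name, 1.0)
            else:
                fs = pool(cur, spec.pool_mode, spec.pool_size, spec.pool_stride)
            fs.layer_id = spec.name
            res[spec.name] = fs
            cur = fs.values
            if upto is not None and spec.name == upto:
                break
        return res

    def layer_output(self, layer_id: str, index: int = 0) -> FeatureStack:
        """Stored activation of a training input at ``layer_id``."""
        if layer_id not in self.outputs:
            raise KeyError(f"no stored output for layer {layer_id!r}")
        return FeatureStack(self.outputs[layer_id][index], layer_id)

    def unit_responses(self, layer_id: str, index: int = 0) -> np.ndarray:
        """Per-unit response streams (maps x frames): at each frame, the
        maximum absolute activation over the frequency axis of the map."""
        v = self.layer_output(layer_id, index).values
        return np.abs(v).max(axis=0).T  # (m, T)

    # -- geometry -----------------------------------------------------------
    def rf_extent(self, layer_id: str) -> tuple[int, int]:
        return rf_extent(self.arch, layer_id)

    def layer_jump(self, layer_id: str) -> int:
        return _layer_jump(self.arch, layer_id)

    def strf(self, layer_id: str, unit: int):
        from .strf import compose_strf

        return compose_strf(self, layer_id, unit)

    # -- reporting ----------------------------------------------------------
    def summary(self) -> str:
        lines = ["SHMAX fitted model", "=" * 62,
                 f"{'layer':>6} {'kind':>5} {'maps':>5} {'kernel':>7} "
                 f"{'stride':>7} {'rf (frames)':>12} {'|b| range':>14}"]
        for spec in self.arch.layers:
            rf = rf_extent(self.arch, spec.name)[1]
            if spec.kind == "S" and spec.name in self.banks:
                n = np.linalg.norm(self.banks[spec.name].matrix, axis=1)
                nr = f"{n.min():.3f}-{n.max():.3f}"
                maps = self.banks[spec.name].m
            else:
                nr = "-"
                maps = self.banks.get(spec.name, None)
                maps = spec.n_maps or "-"
            stride = spec.conv_stride if spec.kind == "S" else spec.pool_stride
            k = spec.kernel if spec.kind == "S" else spec.pool_size
            lines.append(f"{spec.name:>6} {spec.kind:>5} {maps!s:>5} {k:>7} "
                         f"{stride:>7} {rf:>12} {nr:>14}")
        return "\n".join(lines)

    # -- serialization ------------------------------------------------------
    def save(self, path) -> None:
        with h5py.File(path, "w") as h5:
            for name, bank in self.banks.items():
                g = h5.create_group(name)
                g.create_dataset("bases", data=bank.bases)
            h5.attrs["layers"] = ",".join(self.arch.names)
            for name, scale in self.scales.items():
                h5.attrs[f"scale_{name}"] = scale

    @classmethod
    def load(cls, path, arch: ArchitectureSpec, inputs=None) -> "SHMAXResults":
        banks = {}
        scales = {}
        with h5py.File(path, "r") as h5:
            for name in h5:
                banks[name] = DictionaryBank(h5[name]["bases"][()], name)
            for key, val in h5.attrs.items():
                if key.startswith("scale_"):
                    scales[key[len("scale_"):]] = float(val)
        model = SHMAX(inputs if inputs is not None else [np.zeros((12, 12))], arch)
        return cls(model, banks, scales=scales)
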