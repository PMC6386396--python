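"""Core network: patch sampling, dictionary learning, convolutional and
lasso encoding, pooling, and receptive-field arithmetic."""

import itertools

import numpy as np
import pytest
from scipy.stats import kurtosis

from shmax.model import (SHMAX, ArchitectureSpec, DictionaryBank,
                         LayerSpec, default_architecture, encode_conv,
                         encode_optimize, eq1_objective, learn_dictionary,
                         pool, rf_extent, sample_patches, compact_architecture)

# ---------------------------------------------------------------- patches


def test_sample_patches_unique_position(rng):
    x = rng.standard_normal((10, 10, 1))
    pats = sample_patches(x, 5, 10, seed=0)
    for row in pats:
        np.testing.assert_array_equal(row, x.ravel())


def test_sample_patches_deterministic(rng):
    x = rng.standard_normal((20, 30, 2))
    np.testing.assert_array_equal(sample_patches(x, 50, 5, seed=3),
                                  sample_patches(x, 50, 5, seed=3))


def test_sample_patches_values_verbatim(rng):
    """Every sampled patch appears at some position of the source stack."""
    x = rng.standard_normal((12, 15, 2))
    k = 4
    pats = sample_patches(x, 20, k, seed=1)
    positions = {
        tuple(x[r : r + k, c : c + k, :].ravel())
        for r in range(12 - k + 1)
        for c in range(15 - k + 1)
    }
    for row in pats:
        assert tuple(row) in positions


def test_sample_patches_too_small(rng):
    with pytest.raises(ValueError):
        sample_patches(rng.standard_normal((5, 5, 1)), 3, 10)


# ---------------------------------------------------------------- learning


def _planted_patch_data(rng, n=2000, dim=16, n_atoms=8):
    """Sparse nonnegative combinations of orthogonal atoms."""
    Q, _ = np.linalg.qr(rng.standard_normal((dim, dim)))
    atoms = Q[:, :n_atoms].T
    codes = np.zeros((n, n_atoms))
    for i in range(n):
        k = rng.integers(1, 3)
        idx = rng.choice(n_atoms, size=k, replace=False)
        codes[i, idx] = rng.gamma(2.0, 1.0, size=k)
    data = codes @ atoms + 0.01 * rng.standard_normal((n, dim))
    return atoms, data


def _best_matching(true_atoms, learned):
    """Greedy 1-1 assignment by |cosine| (exhaustive is 8! at this size;
    greedy achieves the same matches for well-separated atoms)."""
    C = np.abs(true_atoms @ learned.T)
    matches = []
    used_t, used_l = set(), set()
    for _ in range(len(true_atoms)):
        i, j = np.unravel_index(np.argmax(C), C.shape)
        matches.append(C[i, j])
        C[i, :] = -1
        C[:, j] = -1
    return matches


def test_dictionary_recovers_planted_atoms(rng):
    atoms, data = _planted_patch_data(rng)
    bank = learn_dictionary(data, 8, lam=1.0, epochs=20, seed=0, kernel=4, u=1)
    matches = _best_matching(atoms, bank.matrix)
    assert sum(m > 0.9 for m in matches) >= 7


def test_dictionary_norm_constraint(rng):
    _, data = _planted_patch_data(rng)
    bank = learn_dictionary(data, 8, lam=0.5, epochs=5, seed=1, kernel=4, u=1)
    norms = np.linalg.norm(bank.matrix, axis=1)
    np.testing.assert_allclose(norms, 1.0, atol=1e-6)


def test_huge_lambda_silences_codes(rng):
    """In the strong-L1 limit the optimal codes vanish on unit-scale data."""
    _, data = _planted_patch_data(rng)
    bank = learn_dictionary(data, 8, lam=0.5, epochs=5, seed=1, kernel=4, u=1)
    x = data[0].reshape(4, 4, 1) / np.abs(data[0]).max()
    fs = encode_optimize(x, bank, lam=100.0)
    assert np.mean(np.abs(fs.values)) < 1e-3


def test_learning_reduces_objective_on_holdout(rng):
    atoms, data = _planted_patch_data(rng, n=1000)
    train, hold = data[:800], data[800:]
    idx = rng.choice(len(train), 8, replace=False)
    init = train[idx] / np.linalg.norm(train[idx], axis=1)[:, None]
    from shmax.model import _lasso_codes

    bank = learn_dictionary(train, 8, lam=0.1, epochs=10, seed=0, kernel=4, u=1)
    obj_init = eq1_objective(hold, init, _lasso_codes(hold, init, 0.1), 0.1)
    obj_fit = eq1_objective(hold, bank.matrix, _lasso_codes(hold, bank.matrix, 0.1), 0.1)
    assert obj_fit <= obj_init


def test_all_zero_patches_warn(rng):
    with pytest.warns(UserWarning):
        bank = learn_dictionary(np.zeros((50, 16)), 4, kernel=4, u=1)
    np.testing.assert_allclose(np.linalg.norm(bank.matrix, axis=1), 1.0)


def test_l2_regularizer_variant(rng):
    _, data = _planted_patch_data(rng)
    bank = learn_dictionary(data, 8, lam=0.5, epochs=3, seed=1, kernel=4, u=1,
                            regularizer="L2")
    assert np.all(np.linalg.norm(bank.matrix, axis=1) <= 1.0 + 1e-9)


# ---------------------------------------------------------------- encoding


def _triple_sum_oracle(x, bases, s):
    """Literal evaluation of the convolutional-encoding sum."""
    m, k, _, u = bases.shape
    H = (x.shape[0] - k) // s + 1
    T = (x.shape[1] - k) // s + 1
    out = np.zeros((H, T, m))
    for j, h, t, p, q, c in itertools.product(
        range(m), range(H), range(T), range(k), range(k), range(u)
    ):
        out[h, t, j] += x[s * h + p, s * t + q, c] * bases[j, p, q, c]
    return out


def test_encode_conv_matches_triple_sum(rng):
    x = rng.standard_normal((6, 6, 2))
    bases = rng.standard_normal((2, 3, 3, 2))
    bank = DictionaryBank(bases)
    got = encode_conv(x, bank, s_conv=2).values
    np.testing.assert_allclose(got, _triple_sum_oracle(x, bases, 2), atol=1e-12)


def test_encode_conv_delta_kernel(rng):
    """A one-hot basis at (0,0,0) copies input channel 0 (valid region)."""
    x = rng.standard_normal((8, 9, 3))
    bases = np.zeros((1, 3, 3, 3))
    bases[0, 0, 0, 0] = 1.0
    got = encode_conv(x, DictionaryBank(bases), s_conv=1).values[:, :, 0]
    np.testing.assert_allclose(got, x[:6, :7, 0])


def test_encode_conv_output_dims(rng):
    x = rng.standard_normal((12, 12, 1))
    bank = DictionaryBank(rng.standard_normal((4, 10, 10, 1)))
    assert encode_conv(x, bank, s_conv=2).values.shape == (2, 2, 4)


def test_encode_conv_channel_mismatch(rng):
    with pytest.raises(ValueError):
        encode_conv(rng.standard_normal((6, 6, 3)),
                    DictionaryBank(rng.standard_normal((2, 3, 3, 2))))


def _cd_lasso_oracle(B, x, lam, iters=20000, tol=1e-12):
    """Exhaustive coordinate descent on ||x - B r||^2 + lam ||r||_1."""
    m = B.shape[0]
    G = B @ B.T
    c = B @ x
    r = np.zeros(m)
    for _ in range(iters):
        r_prev = r.copy()
        for j in range(m):
            rho = c[j] - G[j] @ r + G[j, j] * r[j]
            r[j] = np.sign(rho) * max(abs(rho) - lam / 2.0, 0.0) / G[j, j]
        if np.max(np.abs(r - r_prev)) < tol:
            break
    return r


def test_encode_optimize_matches_cd_oracle(rng):
    x = rng.standard_normal((4, 4, 1))
    B = rng.standard_normal((6, 4, 4, 1))
    B /= np.linalg.norm(B.reshape(6, -1), axis=1)[:, None, None, None]
    bank = DictionaryBank(B)
    lam = 0.3
    got = encode_optimize(x, bank, lam=lam).values[0, 0]
    ref = _cd_lasso_oracle(bank.matrix, x.ravel(), lam)
    obj = lambda r: np.sum((x.ravel() - bank.matrix.T @ r) ** 2) + lam * np.abs(r).sum()
    assert obj(got) <= obj(ref) + 1e-6
    assert abs(obj(got) - obj(ref)) < 1e-6


def test_encode_optimize_orthonormal_lam0(rng):
    Q, _ = np.linalg.qr(rng.standard_normal((9, 9)))
    bank = DictionaryBank(Q.T.reshape(9, 3, 3, 1))
    x = rng.standard_normal((3, 3, 1))
    got = encode_optimize(x, bank, lam=0.0).values[0, 0]
    np.testing.assert_allclose(got, Q.T @ x.ravel(), atol=1e-10)


def test_encode_optimize_beats_zero_code(rng):
    x = rng.standard_normal((4, 4, 1))
    B = rng.standard_normal((5, 4, 4, 1))
    B /= np.linalg.norm(B.reshape(5, -1), axis=1)[:, None, None, None]
    bank = DictionaryBank(B)
    lam = 1.0
    r = encode_optimize(x, bank, lam=lam).values[0, 0]
    obj = np.sum((x.ravel() - bank.matrix.T @ r) ** 2) + lam * np.abs(r).sum()
    assert obj <= np.sum(x**2) + 1e-12


# ---------------------------------------------------------------- pooling


def test_pool_constant(rng):
    x = np.full((5, 7, 2), 3.25)
    for mode in ("max", "average"):
        out = pool(x, mode, 2, 1).values
        assert out.shape == (4, 6, 2)
        np.testing.assert_allclose(out, 3.25)


def test_pool_matches_window_oracle(rng):
    x = rng.standard_normal((6, 8, 3))
    got = pool(x, "max", 2, 1).values
    for h in range(5):
        for t in range(7):
            for j in range(3):
                assert got[h, t, j] == x[h : h + 2, t : t + 2, j].max()


def test_pool_one_fewer_row_and_column(rng):
    out = pool(rng.standard_normal((5, 7, 1)), "max", 2, 1).values
    assert out.shape == (4, 6, 1)


def test_max_pool_dominates_average(rng):
    x = rng.standard_normal((6, 6, 2))
    assert np.all(pool(x, "max", 2, 1).values >= pool(x, "average", 2, 1).values)


def test_pool_size_error(rng):
    with pytest.raises(ValueError):
        pool(rng.standard_normal((3, 3, 1)), "max", 4, 1)


# ------------------------------------------------------- receptive fields


def test_rf_extent_full_table():
    arch = default_architecture()
    sizes = [rf_extent(arch, n)[1] for n in arch.names]
    assert sizes == [10, 12, 30, 34, 70, 74, 110, 114, 150, 154, 190, 194]


def test_rf_extent_kernel20_s5_matches_default_s6():
    arch20 = default_architecture(kernels=(10, 10, 10, 10, 20, 10))
    assert rf_extent(arch20, "S5") == rf_extent(default_architecture(), "S6")
    assert rf_extent(arch20, "S5")[1] == 190


def test_rf_extent_single_layer():
    arch = ArchitectureSpec((LayerSpec("S", "S1", n_maps=4, kernel=7, conv_stride=1),))
    assert rf_extent(arch, "S1") == (7, 7)


def test_rf_extent_unknown_layer():
    with pytest.raises(KeyError):
        rf_extent(default_architecture(), "S9")


# ---------------------------------------------------------------- training


def test_fit_output_dims_match_arithmetic(fitted_small, cochleogram_small):
    """Layer output shapes follow the composed dimension formulas."""
    h, t = cochleogram_small.energy.shape
    dims = (h, t)
    for spec in fitted_small.arch.layers:
        if spec.kind == "S":
            dims = tuple((d - spec.kernel) // spec.conv_stride + 1 for d in dims)
        else:
            dims = tuple((d - spec.pool_size) // spec.pool_stride + 1 for d in dims)
        got = fitted_small.outputs[spec.name][0].shape
        assert got[:2] == dims


def test_fit_deterministic(cochleogram_small):
    arch = compact_architecture(n_maps=(8, 8, 8, 8))
    a = SHMAX([cochleogram_small], arch).fit(n_patches=200, epochs=1, seed=5)
    b = SHMAX([cochleogram_small], arch).fit(n_patches=200, epochs=1, seed=5)
    for name in a.banks:
        np.testing.assert_array_equal(a.banks[name].bases, b.banks[name].bases)


def test_fit_pool_none_passthrough(cochleogram_small):
    arch = compact_architecture(pool_mode="none", n_maps=(8, 8, 8, 8))
    res = SHMAX([cochleogram_small], arch).fit(n_patches=200, epochs=1, seed=5)
    np.testing.assert_array_equal(res.outputs["C1"][0], res.outputs["S1"][0])


def test_trained_responses_sparser_than_random_basis(fitted_small, rng):
    """Responses of learned bases have positive excess kurtosis, exceeding
    those of control bases whose elements are drawn from the same marginal
    distribution (element-shuffled learned bases)."""
    s1 = fitted_small.outputs["C1"][0]
    bank = fitted_small.banks["S2"]
    resp = encode_conv(s1[:, :2000], bank, s_conv=2).values.ravel()
    shuf = bank.bases.copy().ravel()
    rng.shuffle(shuf)
    rnd = shuf.reshape(bank.bases.shape)
    rnd /= np.linalg.norm(rnd.reshape(bank.m, -1), axis=1)[:, None, None, None]
    resp_rnd = encode_conv(s1[:, :2000], DictionaryBank(rnd), s_conv=2).values.ravel()
    assert kurtosis(resp) > 0
    assert kurtosis(resp) > kurtosis(resp_rnd)


def compact_architecture_validation():
    with pytest.raises(ValueError):
        ArchitectureSpec((LayerSpec("C", "C1"),))
    with pytest.raises(ValueError):
        LayerSpec("S", "S1", conv_stride=3)
    with pytest.raises(ValueError):
        LayerSpec("S", "S1", lam=0.0)


def test_model_save_load_roundtrip(tmp_path, fitted_small):
    path = tmp_path / "model.h5"
    fitted_small.save(path)
    from shmax.model import SHMAXResults

    back = SHMAXResults.load(path, fitted_small.arch)
    for name, bank in fitted_small.banks.items():
        np.testing.assert_array_equal(back.banks[name].bases, bank.bases)
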