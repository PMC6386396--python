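"""Selectivity statistics: response amplitudes, active-unit screening, PSI,
clustering, F-ratio, feature averaging, lifetime sparseness."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shmax import corpus as cm
from shmax import selectivity as sel


def _table(amplitudes, silence=None, speech=None):
    n_units = next(iter(amplitudes.values())).shape[0]
    if silence is None:
        silence = np.zeros((n_units, 10))
    if speech is None:
        speech = np.ones((n_units, 10))
    return sel.ResponseTable(amplitudes, silence, speech)


def _transcript(spans):
    return cm.Transcript(tuple(spans))


# ------------------------------------------------------ response amplitudes


def test_amplitudes_zero_stack():
    tr = _transcript([(0, 800, "sil"), (800, 2400, "aa"), (2400, 3200, "sil"),
                      (3200, 4800, "aa"), (4800, 5600, "sil")])
    resp = np.zeros((3, 350))
    table = sel.response_amplitudes(resp, tr, jump=1, seed=0)
    assert np.all(table.amplitudes["aa"] == 0)


def test_amplitude_uses_absolute_maximum():
    tr = _transcript([(0, 160, "sil"), (160, 1760, "aa"), (1760, 1920, "sil")])
    resp = np.zeros((1, 120))
    resp[0, 50] = -3.0
    table = sel.response_amplitudes(resp, tr, jump=1, seed=0)
    assert table.amplitudes["aa"][0, 0] == 3.0


def test_amplitudes_match_bruteforce(rng):
    """Amplitudes equal an explicit per-frame scan (oracle loop)."""
    jump = 4
    tr = _transcript([(0, 800, "sil"), (800, 4000, "x"), (4000, 4800, "sil"),
                      (4800, 8000, "y"), (8000, 8800, "sil")])
    resp = rng.standard_normal((2, 130))
    table = sel.response_amplitudes(resp, tr, jump=jump, seed=0)
    for lab, (s, e) in [("x", (800, 4000)), ("y", (4800, 8000))]:
        f_lo, f_hi = s // 16, e // 16
        frames = [t for t in range(resp.shape[1]) if f_lo <= t * jump < f_hi]
        for u in range(2):
            expected = max(abs(resp[u, t]) for t in frames)
            assert table.amplitudes[lab][u, 0] == pytest.approx(expected)


# ------------------------------------------------------------ active units


def test_active_units_separation_and_null(rng):
    amps = {"aa": rng.random((2, 5))}
    silence = np.zeros((2, 50))
    speech = np.zeros((2, 50))
    speech[0] = 1.0  # unit 0 fully separated; unit 1 identical to silence
    table = _table(amps, silence, speech)
    act = sel.active_units(table)
    assert 0 in act and 1 not in act


def test_active_units_need_silence(rng):
    table = _table({"aa": rng.random((2, 5))}, silence=np.zeros((2, 0)))
    with pytest.raises(ValueError):
        sel.active_units(table)


def _exact_ranksum_p(x, y):
    """Exact one-sided rank-sum p-value by enumeration over all splits."""
    pooled = np.concatenate([x, y])
    ranks = np.argsort(np.argsort(pooled)) + 1
    obs = ranks[: len(x)].sum()
    count = 0
    total = 0
    for comb in itertools.combinations(range(len(pooled)), len(x)):
        total += 1
        if ranks[list(comb)].sum() >= obs:
            count += 1
    return count / total


def test_rank_sum_matches_enumeration(rng):
    """Inclusion decisions agree with an independent exact enumeration of
    the rank-sum null distribution at small n."""
    for _ in range(5):
        x = rng.standard_normal(6) + rng.uniform(0, 2)
        y = rng.standard_normal(5)
        p_impl = sel.rank_sum_greater(x, y)
        p_oracle = _exact_ranksum_p(x, y)
        assert p_impl == pytest.approx(p_oracle, abs=1e-12)


# -------------------------------------------------------------------- PSI


def test_psi_perfect_selectivity_hits_upper_bound(rng):
    """A unit whose amplitudes for one phoneme dominate all 32 others scores
    the maximum PSI of 32."""
    amps = {}
    for i in range(33):
        if i == 0:
            amps[f"p{i:02d}"] = 10.0 + 0.1 * rng.random((1, 30))
        else:
            amps[f"p{i:02d}"] = 0.1 * rng.random((1, 30))
    table = _table(amps)
    vec = sel.psi_vector(table, 0)
    assert vec[0] == 32
    assert vec.max() == 32


def test_psi_identical_distributions_zero(rng):
    base = rng.random(20)
    amps = {f"p{i}": base[None, :].copy() for i in range(5)}
    table = _table(amps)
    assert np.all(sel.psi_vector(table, 0) == 0)


def test_psi_invariant_to_monotone_transform(rng):
    """PSI depends only on amplitude ranks."""
    amps = {f"p{i}": rng.random((2, 12)) for i in range(6)}
    t1 = _table(amps)
    t2 = _table({k: np.exp(3 * v + 1) for k, v in amps.items()})
    for u in range(2):
        np.testing.assert_array_equal(sel.psi_vector(t1, u), sel.psi_vector(t2, u))


def test_psi_matrix_agrees_with_per_unit_vectors(rng):
    """The vectorized matrix path reproduces psi_vector unit by unit."""
    amps = {f"p{i}": rng.random((5, 14)) for i in range(6)}
    table = _table(amps)
    psi = sel.psi_matrix(table)
    for u in range(5):
        np.testing.assert_array_equal(psi.values[u], sel.psi_vector(table, u))


def test_psi_matrix_bounds(rng):
    amps = {f"p{i}": rng.random((3, 8)) for i in range(5)}
    psi = sel.psi_matrix(_table(amps))
    assert psi.values.min() >= 0
    assert psi.values.max() <= psi.n_phonemes - 1


# -------------------------------------------------------------- clustering


def test_cluster_two_clouds(rng):
    a = rng.normal(0, 0.1, size=(10, 4))
    b = rng.normal(10, 0.1, size=(10, 4))
    psi = sel.PSIMatrix(np.vstack([a, b]), [f"p{i}" for i in range(4)],
                        np.arange(20))
    out = sel.cluster_psi(psi, n_groups=2)
    g = out.groups
    assert len(set(g[:10])) == 1 and len(set(g[10:])) == 1 and g[0] != g[-1]


def test_cluster_invariant_to_row_permutation(rng):
    vals = rng.integers(0, 10, size=(15, 6))
    psi = sel.PSIMatrix(vals, [f"p{i}" for i in range(6)], np.arange(15))
    perm = rng.permutation(15)
    psi_p = sel.PSIMatrix(vals[perm], [f"p{i}" for i in range(6)], np.arange(15))
    g1 = sel.cluster_psi(psi, 3).groups
    g2 = sel.cluster_psi(psi_p, 3).groups
    # same partition up to relabeling
    for i in range(15):
        for j in range(15):
            assert (g1[perm[i]] == g1[perm[j]]) == (g2[i] == g2[j])


def test_cluster_linkage_heights_monotone(rng):
    from scipy.cluster.hierarchy import linkage

    vals = rng.random((12, 5))
    Z = linkage(vals, method="ward", metric="euclidean")
    assert np.all(np.diff(Z[:, 2]) >= -1e-12)


def test_cluster_too_few_units(rng):
    psi = sel.PSIMatrix(rng.random((3, 4)), list("abcd"), np.arange(3))
    with pytest.raises(ValueError):
        sel.cluster_psi(psi, n_groups=6)


# ----------------------------------------------------------------- F-ratio


def _f_ratio_oracle(values, groups):
    """Literal two-loop evaluation of the variance-ratio formula."""
    values = np.asarray(values, dtype=float)
    labels = sorted(set(groups))
    m, n = len(values), len(labels)
    grand = values.mean(axis=0)
    num = 0.0
    for g in labels:
        rows = values[[i for i in range(m) if groups[i] == g]]
        num += len(rows) * np.sum((rows.mean(axis=0) - grand) ** 2)
    num /= n - 1
    den = 0.0
    for g in labels:
        rows = values[[i for i in range(m) if groups[i] == g]]
        mu = rows.mean(axis=0)
        for r in rows:
            den += np.sum((r - mu) ** 2)
    den /= m - n
    return num / den


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_f_ratio_matches_literal_formula(seed):
    rng = np.random.default_rng(seed)
    m = rng.integers(6, 20)
    values = rng.random((m, 5)) * 10
    groups = rng.integers(0, 3, size=m)
    groups[:3] = [0, 1, 2]  # ensure all groups populated
    got = sel.f_ratio(values, groups)
    assert got == pytest.approx(_f_ratio_oracle(values, list(groups)), abs=1e-12)


def test_f_ratio_zero_when_groups_equal(rng):
    """Every group containing {row-1, row, row+1} has mean == grand mean,
    so the between-group numerator vanishes."""
    row = rng.random(5)
    values = np.vstack([np.vstack([row - 1, row, row + 1]) for _ in range(3)])
    groups = np.repeat([0, 1, 2], 3)
    assert sel.f_ratio(values, groups) == pytest.approx(0.0, abs=1e-20)


def test_f_ratio_scale_invariance(rng):
    values = rng.random((10, 4))
    groups = rng.integers(0, 2, size=10)
    groups[:2] = [0, 1]
    assert sel.f_ratio(values, groups) == pytest.approx(
        sel.f_ratio(values * 7.3, groups))


def test_f_ratio_infinite_within_zero():
    values = np.repeat(np.array([[0.0, 0], [1, 1]]), 3, axis=0)
    groups = np.repeat([0, 1], 3)
    assert sel.f_ratio(values, groups) == np.inf


# ------------------------------------------------------------- feature PSI


def test_feature_psi_identity_and_mean(rng):
    vals = rng.integers(0, 10, size=(4, 3))
    psi = sel.PSIMatrix(vals, ["a", "b", "c"], np.arange(4))
    out = sel.feature_psi(psi, {"a": "fa", "b": "fb", "c": "fc"})
    np.testing.assert_allclose(out.loc["fa"].to_numpy(), vals[:, 0])
    out2 = sel.feature_psi(psi, {"a": "f", "b": "f", "c": "g"})
    np.testing.assert_allclose(out2.loc["f"].to_numpy(), vals[:, :2].mean(axis=1))


def test_feature_psi_unmapped_errors(rng):
    psi = sel.PSIMatrix(rng.integers(0, 5, (2, 2)), ["a", "b"], np.arange(2))
    with pytest.raises(ValueError):
        sel.feature_psi(psi, {"a": "f"})


def test_feature_map_covers_inventory():
    inv = cm.make_inventory(20, seed=3)
    fmap = sel.phoneme_feature_map(inv)
    assert set(fmap) == {s.label for s in inv}
    assert set(fmap.values()) <= {"plosive", "fricative", "nasal",
                                  "low_back", "low_front", "high_front"}


# ----------------------------------------------------- lifetime sparseness


def test_sparseness_constant_is_zero():
    assert sel.lifetime_sparseness(np.full(50, 2.5)) == pytest.approx(0.0)


@pytest.mark.parametrize("n", [2, 10, 100])
def test_sparseness_one_hot_closed_form(n):
    r = np.zeros(n)
    r[0] = 1.0
    assert sel.lifetime_sparseness(r) == pytest.approx(1.0 - 1.0 / n)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_sparseness_matches_moments(seed):
    rng = np.random.default_rng(seed)
    r = rng.random(rng.integers(2, 50)) + 1e-6
    got = sel.lifetime_sparseness(r)
    expected = 1.0 - (r.mean() ** 2) / np.mean(r**2)
    assert got == pytest.approx(expected, abs=1e-14)
    assert 0.0 <= got < 1.0


def test_sparseness_all_zero_raises():
    with pytest.raises(ValueError):
        sel.lifetime_sparseness(np.zeros(10))
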