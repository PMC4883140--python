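import itertools

import numpy as np
import pytest

from smarttrace.features import (
    DETAIL_ORDER,
    discretize_features,
    dwt3_level,
    extract_window,
    inverse_dwt3_level,
    mrmr_select,
    mutual_information,
    mwr_feature_matrix,
    mwr_features,
)
from smarttrace.io_formats import Image3D

from conftest import random_image


# -- windows ---------------------------------------------------------------


def test_interior_window_constant_and_size():
    img = Image3D(np.full((32, 32, 32), 7, dtype=np.uint8))
    w = extract_window(img, (16, 16, 16), side=16)
    assert w.shape == (16, 16, 16) and w.size == 4096
    assert (w == 7).all()


def test_corner_window_matches_reflection_oracle():
    img = random_image((20, 20, 20), seed=2)
    side = 16
    w = extract_window(img, (1, 2, 18), side=side)
    padded = np.pad(img.data, side, mode="reflect")
    c = np.array([1, 2, 18]) + side
    half = side // 2
    expect = padded[
        c[0] - half : c[0] + half, c[1] - half : c[1] + half, c[2] - half : c[2] + half
    ]
    np.testing.assert_array_equal(w, expect)


def test_window_larger_than_image_rejected():
    img = random_image((4, 4, 4))
    with pytest.raises(ValueError):
        extract_window(img, (2, 2, 2), side=16)


# -- wavelet decomposition -------------------------------------------------


def test_one_level_yields_eight_subbands():
    cube = np.random.default_rng(0).normal(size=(8, 8, 8))
    sub = dwt3_level(cube)
    assert len(sub) == 8
    assert set(sub) == {"LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH"}
    assert all(v.shape == (4, 4, 4) for v in sub.values())


def test_constant_cube_has_zero_details():
    sub = dwt3_level(np.full((8, 8, 8), 3.25))
    for name, band in sub.items():
        if name != "LLL":
            np.testing.assert_allclose(band, 0.0, atol=1e-12)


def test_odd_side_rejected():
    with pytest.raises(ValueError):
        dwt3_level(np.zeros((7, 7, 7)))


@pytest.mark.parametrize("wavelet", ["haar", "db4"])
def test_perfect_reconstruction(wavelet):
    cube = np.random.default_rng(1).normal(size=(16, 16, 16))
    sub = dwt3_level(cube, wavelet=wavelet)
    back = inverse_dwt3_level(sub, wavelet=wavelet)
    assert np.abs(back - cube).max() / np.abs(cube).max() < 1e-8


@pytest.mark.parametrize("side,levels", [(8, 3), (16, 3), (16, 4), (32, 3)])
def test_feature_count_equals_voxel_count(side, levels):
    cube = np.random.default_rng(2).normal(size=(side,) * 3)
    fv = mwr_features(cube, levels=levels)
    assert len(fv.values) == side**3


def test_16cube_3level_block_sizes():
    fv = mwr_features(np.zeros((16, 16, 16)), levels=3)
    sizes = [int(np.prod(s)) for _, _, s in fv.layout]
    assert sizes == [512] * 7 + [64] * 7 + [8] * 7 + [8]
    assert sum(sizes) == 4096


def test_parseval_energy_conservation():
    cube = np.random.default_rng(3).normal(size=(16, 16, 16))
    fv = mwr_features(cube, levels=3, wavelet="haar")
    assert (fv.values**2).sum() == pytest.approx((cube**2).sum(), rel=1e-6)


def test_deterministic_layout_and_batch_consistency():
    rng = np.random.default_rng(4)
    cubes = rng.normal(size=(5, 16, 16, 16))
    M = mwr_feature_matrix(cubes, levels=3)
    for k in range(5):
        np.testing.assert_array_equal(M[k], mwr_features(cubes[k], levels=3).values)


# -- mutual information ----------------------------------------------------


def test_mi_identical_fair_binary_is_one_bit():
    a = np.array([0, 1] * 50)
    assert mutual_information(a, a) == pytest.approx(1.0)


def test_mi_independent_factorial_design_is_zero():
    a = np.repeat([0, 0, 1, 1], 25)
    b = np.tile([0, 1], 50)
    assert mutual_information(a, b) == pytest.approx(0.0, abs=1e-12)


def test_mi_matches_double_loop_oracle():
    rng = np.random.default_rng(7)
    a = rng.integers(0, 3, 200)
    b = rng.integers(0, 4, 200)
    got = mutual_information(a, b)
    expect = 0.0
    n = len(a)
    for va in np.unique(a):
        for vb in np.unique(b):
            pab = ((a == va) & (b == vb)).sum() / n
            if pab > 0:
                pa, pb = (a == va).mean(), (b == vb).mean()
                expect += pab * np.log2(pab / (pa * pb))
    assert got == pytest.approx(expect, rel=1e-12)
    assert got == pytest.approx(mutual_information(b, a), rel=1e-12)
    assert got >= 0


def test_mi_length_mismatch():
    with pytest.raises(ValueError):
        mutual_information([0, 1], [0, 1, 2])


# -- mRMR ------------------------------------------------------------------


def _mrmr_oracle(disc, yi, k):
    """Exhaustive evaluation of the incremental criterion at every step."""
    n_feat = disc.shape[1]
    rel = [mutual_information(yi, disc[:, f]) for f in range(n_feat)]
    selected = []
    for _ in range(k):
        best, best_score = None, -np.inf
        for f in range(n_feat):
            if f in selected:
                continue
            red = (
                np.mean([mutual_information(disc[:, f], disc[:, s]) for s in selected])
                if selected
                else 0.0
            )
            score = rel[f] - red
            if score > best_score + 1e-12:
                best, best_score = f, score
        selected.append(best)
    return selected


def test_planted_relevant_feature_selected_first():
    rng = np.random.default_rng(8)
    y = rng.integers(0, 2, 300)
    X = rng.normal(size=(300, 10))
    X[:, 4] = y * 10.0  # feature 4 carries the label
    res = mrmr_select(X, y, k=3)
    assert res.selected_indices[0] == 4


def test_duplicate_feature_penalized():
    rng = np.random.default_rng(9)
    n = 600
    y = rng.integers(0, 2, n)
    noise = rng.normal(size=(n, 3))
    strong = y * 4.0 + rng.normal(0, 0.5, n)
    weak = y * 4.0 + rng.normal(0, 3.0, n)
    X = np.column_stack([strong, strong.copy(), weak, noise])
    res = mrmr_select(X, y, k=2)
    assert res.selected_indices[0] == 0  # strongest feature
    assert res.selected_indices[1] == 2  # its duplicate (index 1) is penalized


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_greedy_matches_exhaustive_oracle(seed):
    rng = np.random.default_rng(seed)
    n = 120
    y = rng.integers(0, 2, n)
    X = rng.normal(size=(n, 6))
    X[:, 0] += y
    X[:, 3] += 0.5 * y
    res = mrmr_select(X, y, k=3)
    disc, _ = discretize_features(X)
    _, yi = np.unique(y, return_inverse=True)
    assert res.selected_indices == _mrmr_oracle(disc, yi, 3)


def test_permutation_equivariance():
    rng = np.random.default_rng(11)
    n = 200
    y = rng.integers(0, 2, n)
    X = rng.normal(size=(n, 8))
    X[:, 2] += y
    X[:, 5] += 0.7 * y
    perm = np.array([3, 0, 6, 1, 7, 2, 5, 4])
    base = mrmr_select(X, y, k=3).selected_indices
    permuted = mrmr_select(X[:, perm], y, k=3).selected_indices
    assert [perm[i] for i in permuted] == base


def test_mrmr_validations():
    X = np.random.default_rng(0).normal(size=(10, 4))
    with pytest.raises(ValueError):
        mrmr_select(X, np.zeros(10), k=2)  # single class
    with pytest.raises(ValueError):
        mrmr_select(X, np.arange(10) % 2, k=9)  # k too large
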