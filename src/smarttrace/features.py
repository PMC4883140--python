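"""3D multi-resolution wavelet features and mRMR feature selection.

Each sample voxel is described by the full coefficient set of an L-level
separable 3D discrete wavelet transform of the cubic window around it.  One
decomposition level convolves the volume with a low-pass (L) / high-pass (H)
filter pair along z, then y, then x, yielding 8 subbands (LLL ... HHH); the
smooth LLL band is decomposed again at the next level.  With an orthogonal
filter pair and periodic boundary handling the total coefficient count
equals the window voxel count (4096 for a 16^3 window at any level count),
energy is conserved, and the transform inverts exactly.

Feature layout (fixed, documented): level-1 (finest) detail subbands in the
order LLH, LHL, LHH, HLL, HLH, HHL, HHH, each flattened in C order; then
level 2, ... level L; finally the level-L LLL band.

Selection uses minimum-redundancy maximum-relevance (mRMR): greedily pick
the feature with maximal mutual information with the class, then repeatedly
add the feature maximizing

    I(c, f)  -  (1/|S|) * sum_{s in S} I(f, s),

the standard first-order incremental scheme whose per-step work is linear in
the remaining candidates.  Continuous features are discretized into 3 states
at mean +/- one standard deviation before any mutual-information estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .io_formats import Image3D

__all__ = [
    "DETAIL_ORDER",
    "FeatureVector",
    "SelectionResult",
    "extract_window",
    "extract_windows",
    "dwt3_level",
    "mwr_features",
    "mwr_feature_matrix",
    "mutual_information",
    "discretize_features",
    "mrmr_select",
]

# pywt subband keys in (z, y, x) axis order: 'a' = low-pass, 'd' = high-pass.
# Sorted keys give the documented LLH..HHH detail ordering.
DETAIL_ORDER = ("aad", "ada", "add", "daa", "dad", "dda", "ddd")
_KEY_TO_NAME = {k: k.replace("a", "L").replace("d", "H") for k in ("aaa",) + DETAIL_ORDER}


@dataclass
class FeatureVector:
    values: np.ndarray
    layout: list  # (level, subband name, shape) per block, in storage order


@dataclass
class SelectionResult:
    selected_indices: list[int]
    relevance: np.ndarray  # I(c, f) for every feature
    step_scores: list[float]  # incremental criterion value at each pick
    discretization_edges: np.ndarray  # (n_features, 2): mean -/+ std


# -- windows ---------------------------------------------------------------


def _reflect_index(idx: np.ndarray, n: int) -> np.ndarray:
    """Mirror indexing without edge repetition (numpy 'reflect'), any range."""
    if n == 1:
        return np.zeros_like(idx)
    period = 2 * n - 2
    idx = np.abs(idx) % period
    return np.where(idx >= n, period - idx, idx)


def extract_window(img: Image3D, center: tuple[int, int, int], side: int = 16) -> np.ndarray:
    """The side^3 cube around a voxel; out-of-bounds regions mirror-padded.

    The window covers ``[c - side//2, c + side//2)`` along each axis, so the
    center voxel sits at index ``side//2``.
    """
    return extract_windows(img, np.asarray([center]), side)[0]


def extract_windows(img: Image3D, centers: np.ndarray, side: int = 16) -> np.ndarray:
    """Batched :func:`extract_window`: (n, 3) centers -> (n, side^3 cube)."""
    if side < 2:
        raise ValueError("window side must be >= 2")
    shape = img.data.shape
    if all(side > s for s in shape):
        raise ValueError(f"window side {side} exceeds every image dimension {shape}")
    centers = np.asarray(centers, dtype=int)
    half = side // 2
    offs = np.arange(-half, side - half)
    idx = []
    for ax in range(3):
        raw = centers[:, ax][:, None] + offs[None, :]
        idx.append(_reflect_index(raw, shape[ax]))
    return img.data[
        idx[0][:, :, None, None], idx[1][:, None, :, None], idx[2][:, None, None, :]
    ].astype(np.float64)


# -- wavelet transform -----------------------------------------------------


def dwt3_level(cube: np.ndarray, wavelet: str = "haar") -> dict[str, np.ndarray]:
    """One level of separable 3D decomposition: 8 half-size subbands.

    Returns a dict keyed 'LLL', 'LLH', ..., 'HHH' (letters in z, y, x filter
    order).  Uses periodization so subbands are exactly half-size and the
    transform is orthogonal for orthogonal filters.  Odd sides are an error.
    """
    cube = np.asarray(cube, dtype=np.float64)
    if any(s % 2 for s in cube.shape[-3:]):
        raise ValueError(f"even side length required, got {cube.shape}")
    c = pywt.dwtn(cube, wavelet, mode="periodization", axes=(-3, -2, -1))
    return {_KEY_TO_NAME[k]: v for k, v in c.items()}


def inverse_dwt3_level(subbands: dict[str, np.ndarray], wavelet: str = "haar") -> np.ndarray:
    """Inverse of :func:`dwt3_level` (exact for orthogonal filters)."""
    name_to_key = {v: k for k, v in _KEY_TO_NAME.items()}
    return pywt.idwtn(
        {name_to_key[n]: v for n, v in subbands.items()},
        wavelet,
        mode="periodization",
        axes=(-3, -2, -1),
    )


def _mwr_coeffs(batch: np.ndarray, levels: int, wavelet: str):
    side = batch.shape[-1]
    if any(s != side for s in batch.shape[-3:]):
        raise ValueError("cubic windows required")
    if side % (2**levels):
        raise ValueError(f"side {side} not divisible by 2^{levels}")
    coeffs = pywt.wavedecn(
        batch, wavelet, mode="periodization", level=levels, axes=(-3, -2, -1)
    )
    # coeffs = [cA_L, {level L details}, ..., {level 1 details}]
    blocks = []
    layout = []
    for lvl in range(1, levels + 1):
        d = coeffs[levels + 1 - lvl]
        for key in DETAIL_ORDER:
            blocks.append(d[key])
            layout.append((lvl, _KEY_TO_NAME[key], d[key].shape[-3:]))
    blocks.append(coeffs[0])
    layout.append((levels, "LLL", coeffs[0].shape[-3:]))
    return blocks, layout


def mwr_features(cube: np.ndarray, levels: int = 3, wavelet: str = "haar") -> FeatureVector:
    """Full multi-resolution wavelet representation of one cubic window.

    Concatenates the 7 detail subbands of each level (finest first) and the
    final LLL band; the vector length equals the window's voxel count.
    """
    blocks, layout = _mwr_coeffs(np.asarray(cube, dtype=np.float64), levels, wavelet)
    values = np.concatenate([b.ravel() for b in blocks])
    return FeatureVector(values=values, layout=layout)


def mwr_feature_matrix(
    windows: np.ndarray, levels: int = 3, wavelet: str = "haar"
) -> np.ndarray:
    """(n, side^3) feature matrix for a batch of (n, side, side, side) windows."""
    n = windows.shape[0]
    blocks, _ = _mwr_coeffs(np.asarray(windows, dtype=np.float64), levels, wavelet)
    return np.concatenate([b.reshape(n, -1) for b in blocks], axis=1)


# -- mutual information and mRMR ------------------------------------------


def mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in mutual information (bits) of two discrete vectors."""
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.shape != b.shape or len(a) == 0:
        raise ValueError("vectors must be non-empty and equal length")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    na, nb = ai.max() + 1, bi.max() + 1
    joint = np.bincount(ai * nb + bi, minlength=na * nb).reshape(na, nb) / len(a)
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float((joint[nz] * np.log2(joint[nz] / (pa @ pb)[nz])).sum())


def discretize_features(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column 3-state discretization at mean -/+ one standard deviation.

    Returns (int8 state matrix with states {0, 1, 2}, (n_features, 2) edge
    array).  Constant columns land entirely in state 1.
    """
    X = np.asarray(X, dtype=np.float64)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    lo, hi = mu - sd, mu + sd
    disc = np.ones(X.shape, dtype=np.int8)
    disc[X < lo] = 0
    disc[X > hi] = 2
    return disc, np.stack([lo, hi], axis=1)


def _mi_one_vs_many(v: np.ndarray, D: np.ndarray, n_states: int = 3) -> np.ndarray:
    """MI (bits) of one discrete vector against every column of D, vectorized."""
    n, f = D.shape
    joint = np.zeros((n_states, n_states, f))
    for a in range(n_states):
        mask = v == a
        if not mask.any():
            continue
        Dm = D[mask]
        for b in range(n_states):
            joint[a, b] = (Dm == b).sum(axis=0)
    joint /= n
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = joint * np.log2(joint / (pa * pb))
    return np.nansum(term, axis=(0, 1))


def mrmr_select(X: np.ndarray, y: np.ndarray, k: int = 20) -> SelectionResult:
    """Greedy incremental mRMR selection of k features.

    The first pick maximizes relevance I(c, f); each later pick maximizes
    I(c, f) minus the mean mutual information with the already-selected set.
    Ties break to the lowest feature index, so runs are deterministic.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y).ravel()
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("X must be (n_samples, n_features) matching y")
    if k > X.shape[1]:
        raise ValueError(f"k={k} exceeds feature dimension {X.shape[1]}")
    if len(np.unique(y)) < 2:
        raise ValueError("need >= 2 classes for relevance estimation")

    disc, edges = discretize_features(X)
    _, yi = np.unique(y, return_inverse=True)
    n_y = int(yi.max() + 1)
    # relevance uses the class vector (any number of classes) vs 3-state features
    relevance = _mi_one_vs_many(yi.astype(np.int8), disc, n_states=max(3, n_y))

    selected: list[int] = []
    step_scores: list[float] = []
    red_sum = np.zeros(X.shape[1])
    available = np.ones(X.shape[1], dtype=bool)
    for _ in range(k):
        score = relevance - (red_sum / len(selected) if selected else 0.0)
        score = np.where(available, score, -np.inf)
        best = int(np.argmax(score))  # argmax takes the first (lowest) index on ties
        selected.append(best)
        step_scores.append(float(score[best]))
        available[best] = False
        red_sum += _mi_one_vs_many(disc[:, best], disc)
    return SelectionResult(
        selected_indices=selected,
        relevance=relevance,
        step_scores=step_scores,
        discretization_edges=edges,
    )
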