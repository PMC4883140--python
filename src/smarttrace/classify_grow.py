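"""Train the foreground/background classifier and grow the predicted region.

The classifier is a soft-margin RBF-kernel SVM at the standard library
defaults (cost C = 1, kernel width gamma = 1 / feature dimension), fitted on
per-feature standardized inputs — training classes are balanced upstream.

Growth is a front propagation over the voxel grid: foreground-sample voxels
are pre-labeled foreground and seeded; the front marches to adjacent unknown
voxels, classifies each exactly once, and accepted voxels join the front.
The final mask is therefore connected to the seeds by construction, and the
expansion order (FIFO, whole front per sweep) cannot change it — acceptance
depends only on the voxel's own features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .io_formats import Image3D

__all__ = [
    "TrainedClassifier",
    "ForegroundMask",
    "train_classifier",
    "grow_foreground",
    "adjust_image",
    "neighbor_offsets",
]

logger = logging.getLogger(__name__)


@dataclass
class TrainedClassifier:
    svc: SVC
    feature_mean: np.ndarray
    feature_std: np.ndarray
    selected_indices: list[int] | None = None
    training_accuracy: float = float("nan")

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Hard binary labels (1 = foreground) for (n, d) feature rows."""
        X = np.asarray(X, dtype=np.float64)
        Xs = (X - self.feature_mean) / self.feature_std
        return self.svc.predict(Xs).astype(int)


@dataclass
class ForegroundMask:
    mask: np.ndarray  # boolean, image-shaped
    seeds: np.ndarray  # (n, 3) voxels pre-labeled foreground
    stats: dict = field(default_factory=dict)


def train_classifier(
    fg_features: np.ndarray, bg_features: np.ndarray, seed: int = 0
) -> TrainedClassifier:
    """Fit the RBF-SVM on standardized, class-balanced exemplar features."""
    fg = np.asarray(fg_features, dtype=np.float64)
    bg = np.asarray(bg_features, dtype=np.float64)
    if len(fg) == 0 or len(bg) == 0:
        raise ValueError("both classes must be non-empty")
    X = np.vstack([fg, bg])
    y = np.concatenate([np.ones(len(fg), dtype=int), np.zeros(len(bg), dtype=int)])
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    Xs = (X - mean) / std
    # gamma='auto' = 1/d, the classic LIBSVM default kernel width
    svc = SVC(C=1.0, kernel="rbf", gamma="auto", random_state=seed)
    svc.fit(Xs, y)
    acc = float((svc.predict(Xs) == y).mean())
    logger.info("classifier trained: n=%d per class, training accuracy %.3f", len(fg), acc)
    return TrainedClassifier(
        svc=svc, feature_mean=mean, feature_std=std, training_accuracy=acc
    )


def neighbor_offsets(connectivity: int = 26) -> np.ndarray:
    """(k, 3) integer offsets for 6- or 26-connected voxel neighborhoods."""
    if connectivity == 6:
        return np.array(
            [[-1, 0, 0], [1, 0, 0], [0, -1, 0], [0, 1, 0], [0, 0, -1], [0, 0, 1]]
        )
    if connectivity == 26:
        offs = [
            (a, b, c)
            for a in (-1, 0, 1)
            for b in (-1, 0, 1)
            for c in (-1, 0, 1)
            if (a, b, c) != (0, 0, 0)
        ]
        return np.array(offs)
    raise ValueError("connectivity must be 6 or 26")


def grow_foreground(
    img: Image3D,
    seeds: np.ndarray,
    clf: TrainedClassifier,
    feature_fn,
    connectivity: int = 26,
    interior_margin: int = 0,
) -> ForegroundMask:
    """Classifier-gated front propagation from pre-labeled foreground seeds.

    ``feature_fn`` maps an (n, 3) array of (z, y, x) voxels to an (n, d)
    feature matrix matching the classifier.  Each unknown voxel is examined
    and classified exactly once, when the front first reaches it; rejected
    voxels stay background forever, accepted ones extend the front.  Voxels
    the front never reaches are background.

    ``interior_margin`` keeps the front away from the volume border: voxels
    without a fully in-bounds feature window are never examined (mirror
    padding there reflects real structure back into the window, which makes
    border voxels look like continuations of whatever touches the border).
    """
    seeds = np.asarray(seeds, dtype=int)
    if len(seeds) == 0:
        raise ValueError("seeds must be non-empty")
    shape = img.data.shape
    UNKNOWN, FOREGROUND, REJECTED = 0, 1, 2
    status = np.zeros(shape, dtype=np.uint8)
    status[seeds[:, 0], seeds[:, 1], seeds[:, 2]] = FOREGROUND

    offs = neighbor_offsets(connectivity)
    front = np.unique(seeds, axis=0)
    examined = 0
    accepted = 0
    m = interior_margin
    while len(front):
        cand = (front[:, None, :] + offs[None, :, :]).reshape(-1, 3)
        ok = ((cand >= m) & (cand < np.array(shape) - m)).all(axis=1)
        cand = cand[ok]
        cand = cand[status[cand[:, 0], cand[:, 1], cand[:, 2]] == UNKNOWN]
        if len(cand) == 0:
            break
        cand = np.unique(cand, axis=0)  # sorted lexicographically -> deterministic
        pred = clf.predict(feature_fn(cand))
        examined += len(cand)
        fg = cand[pred == 1]
        bg = cand[pred == 0]
        status[bg[:, 0], bg[:, 1], bg[:, 2]] = REJECTED
        status[fg[:, 0], fg[:, 1], fg[:, 2]] = FOREGROUND
        accepted += len(fg)
        front = fg
    return ForegroundMask(
        mask=status == FOREGROUND,
        seeds=seeds,
        stats={
            "examined": examined,
            "accepted": accepted,
            "rejected": examined - accepted,
            "n_seeds": len(seeds),
        },
    )


def adjust_image(img: Image3D, mask: ForegroundMask | np.ndarray, trace_threshold: int) -> Image3D:
    """Prepare the image for re-tracing from the predicted foreground.

    Background voxels are set to 0.  Foreground voxels dimmer than the
    tracer's threshold are raised to the threshold; brighter ones are kept
    unchanged.  Output dtype matches the input.
    """
    m = mask.mask if isinstance(mask, ForegroundMask) else np.asarray(mask, dtype=bool)
    if m.shape != img.data.shape:
        raise ValueError("mask shape must match image shape")
    info = np.iinfo(img.data.dtype)
    if trace_threshold > info.max or trace_threshold < 0:
        raise ValueError(f"trace_threshold {trace_threshold} outside dtype range")
    out = img.data.copy()
    out[~m] = 0
    dim = m & (out < trace_threshold)
    out[dim] = trace_threshold
    return Image3D(out, img.spacing)
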