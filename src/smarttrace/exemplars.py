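"""Turn confident segments into a 4-class label volume and training samples.

Three concentric layers around the confident centerlines define the
exemplars: the *core* layer (skeleton region) provides foreground samples,
the *middle* annulus is uncertain (never trained on), and the *outer*
annulus provides background samples.  The full dilated neighborhood of
uncertain segments is also marked uncertain — it may override background
labels but never the foreground core of a confident segment, so training
never sees contradictory labels.  Everything else is irrelevant.

Voxels within half a feature window of the volume border are demoted to
irrelevant so that every training sample has a full (unpadded) feature
window.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
from scipy.ndimage import distance_transform_edt

from .confidence import ConfidenceReport, _sample_polyline
from .errors import InsufficientExemplarsError
from .io_formats import Image3D
from .morphology import Segment

__all__ = ["Label", "LabelVolume", "build_label_volume", "draw_training_samples"]


class Label(IntEnum):
    IRRELEVANT = 0
    FOREGROUND_SAMPLE = 1
    UNCERTAIN = 2
    BACKGROUND_SAMPLE = 3


@dataclass
class LabelVolume:
    labels: np.ndarray  # uint8 array of Label codes, image-shaped
    layer_radii: tuple[float, float, float]  # (core, middle, outer) distances

    def count(self, label: Label) -> int:
        return int((self.labels == label).sum())

    def voxels(self, label: Label) -> np.ndarray:
        """(n, 3) array of (z, y, x) voxels carrying ``label``, in C order."""
        return np.argwhere(self.labels == label)


def _rasterize_segments(shape, segments: list[Segment]) -> np.ndarray:
    """Boolean volume of nearest-voxel centerline samples of the segments."""
    mask = np.zeros(shape, dtype=bool)
    for seg in segments:
        pts = np.rint(_sample_polyline(seg.coords_zyx(), step=0.5)).astype(int)
        pts = np.clip(pts, 0, np.array(shape) - 1)
        mask[pts[:, 0], pts[:, 1], pts[:, 2]] = True
    return mask


def default_layer_radii(
    tree_segments: list[Segment], window_side: int = 16
) -> tuple[float, float, float]:
    """(core, middle, outer) distances derived from the reconstruction's node
    radii: core = max(1, median radius), middle = core + 2, and outer at
    core plus half the feature window.  Placing the background ring out to
    half a window keeps background exemplars to windows in which the neurite
    appears only peripherally — windows straddling the structure are left
    uncertain rather than taught as background."""
    radii = [
        n.effective_radius() for seg in tree_segments for n in seg.node_path
    ] or [1.0]
    core = max(1.0, float(np.median(radii)))
    return (core, core + 2.0, core + window_side / 2.0)


def build_label_volume(
    img: Image3D,
    report: ConfidenceReport,
    layer_radii: tuple[float, float, float] | None = None,
    border_margin: int = 8,
) -> LabelVolume:
    """Classify every voxel into foreground/background sample, uncertain, or
    irrelevant, from distances to the confident and uncertain centerlines.

    Raises :class:`InsufficientExemplarsError` when the report contains no
    confident segment — the reconstruction offers nothing to learn from.
    """
    confident = report.confident_segments()
    uncertain = report.uncertain_segments()
    if not confident:
        raise InsufficientExemplarsError(
            "no confident segments: cannot harvest training exemplars "
            "(consider relaxing the confidence threshold, supplying a "
            "different initial reconstruction, or running another round)"
        )
    if layer_radii is None:
        layer_radii = default_layer_radii(confident, window_side=2 * border_margin or 16)
    core, middle, outer = layer_radii
    if not 0 < core < middle < outer:
        raise ValueError("layer radii must satisfy 0 < core < middle < outer")

    shape = img.data.shape
    labels = np.full(shape, Label.IRRELEVANT, dtype=np.uint8)

    conf_mask = _rasterize_segments(shape, confident)
    dconf = distance_transform_edt(~conf_mask)
    labels[(dconf > middle) & (dconf <= outer)] = Label.BACKGROUND_SAMPLE
    labels[(dconf > core) & (dconf <= middle)] = Label.UNCERTAIN

    if uncertain:
        unc_mask = _rasterize_segments(shape, uncertain)
        dunc = distance_transform_edt(~unc_mask)
        # surroundings of low-confidence tracing are uncertain too; this may
        # override background but never the confident core (applied below)
        labels[dunc <= outer] = Label.UNCERTAIN

    labels[dconf <= core] = Label.FOREGROUND_SAMPLE

    if border_margin > 0:
        m = border_margin
        interior = np.zeros(shape, dtype=bool)
        interior[m : shape[0] - m, m : shape[1] - m, m : shape[2] - m] = True
        labels[~interior] = Label.IRRELEVANT

    return LabelVolume(labels=labels, layer_radii=tuple(layer_radii))


def draw_training_samples(
    lv: LabelVolume, max_per_class: int = 500, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Class-balanced uniform sample of foreground and background voxels.

    Both classes get ``min(max_per_class, available_fg, available_bg)``
    voxels, drawn uniformly without replacement; the same seed reproduces
    the same sample.  Returns (foreground, background) as (n, 3) arrays of
    (z, y, x).
    """
    fg = lv.voxels(Label.FOREGROUND_SAMPLE)
    bg = lv.voxels(Label.BACKGROUND_SAMPLE)
    if len(fg) == 0 or len(bg) == 0:
        raise InsufficientExemplarsError(
            f"empty sample class (foreground={len(fg)}, background={len(bg)})"
        )
    n = min(max_per_class, len(fg), len(bg))
    rng = np.random.default_rng(seed)
    fg_idx = rng.choice(len(fg), size=n, replace=False)
    bg_idx = rng.choice(len(bg), size=n, replace=False)
    return fg[np.sort(fg_idx)], bg[np.sort(bg_idx)]
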