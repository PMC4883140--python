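"""Per-segment reliability via alternative-path confidence scores.

For a traced segment between endpoints *i* and *j*, mask the image along the
segment (tube around the centerline, endpoints protected), then search for
the cheapest intensity-weighted path L* between *i* and *j* in the masked
image.  The confidence score is

    C = mean intensity along L* / mean intensity along the segment,

both means taken on the *original* image and arc-length weighted.  A segment
with no alternative pathway forces L* through dark background, so C << 1 —
the segment is reliable.  A genuine alternative corridor (e.g. a loop, or a
parallel neurite the tracer could have confused) gives C near 1 — the
segment is uncertain.  The convention assumes bright-on-dark contrast; for
inverted (brightfield) volumes the score is computed on the intensity-
inverted image.

Path costs: node cost c(x) = (1 - I(x)/I_max)^2 + eps, edge cost = Euclidean
step length times the mean of the endpoint node costs.  Bright voxels are
cheap, dark ones expensive; the squared form follows the gray-weighted
distance transforms customary in neuron tracing.  Voxels zeroed by the
masking step carry a large barrier cost: a front marching at speed
proportional to intensity cannot move through zero intensity, so the
alternative path must physically avoid the masked corridor (otherwise the
cheapest route would simply retrace the segment, whose original-image mean
is high, and every segment would score near 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from skimage.graph import route_through_array

from .io_formats import Image3D, NeuronTree
from .morphology import Segment, decompose_segments

__all__ = [
    "EPS_COST",
    "SegmentScore",
    "ConfidenceReport",
    "path_cost_array",
    "mask_segment",
    "alternative_path",
    "mean_path_intensity",
    "score_segments",
]

logger = logging.getLogger(__name__)

EPS_COST = 1e-6  # keeps every voxel reachable even at I = I_max
BARRIER_COST = 1e9  # masked voxels: effectively impassable, never disconnected


def default_mask_radius(node_radius: float) -> float:
    """Masking tube radius for a node: max(SWC radius, 1) + 1 voxel."""
    return max(node_radius, 1.0) + 1.0


@dataclass
class SegmentScore:
    segment_index: int
    mean_intensity: float
    alt_mean_intensity: float
    score: float
    confident: bool
    length: float
    n_nodes: int

    def as_dict(self) -> dict:
        return {
            "segment_index": self.segment_index,
            "mean_intensity": self.mean_intensity,
            "alt_mean_intensity": self.alt_mean_intensity,
            "score": self.score,
            "confident": self.confident,
            "length": self.length,
            "n_nodes": self.n_nodes,
        }


@dataclass
class ConfidenceReport:
    records: list[SegmentScore]
    threshold_used: float
    inverted: bool
    segments: list[Segment] = field(default_factory=list, repr=False)

    def confident_segments(self) -> list[Segment]:
        return [self.segments[r.segment_index] for r in self.records if r.confident]

    def uncertain_segments(self) -> list[Segment]:
        return [self.segments[r.segment_index] for r in self.records if not r.confident]

    def confident_fraction(self) -> float:
        if not self.records:
            return 0.0
        return sum(r.confident for r in self.records) / len(self.records)

    def node_scores(self) -> dict[int, float]:
        """Per-node score (its segment's score) for confidence-colored SWC."""
        out: dict[int, float] = {}
        for r in self.records:
            for n in self.segments[r.segment_index].node_path:
                out[n.id] = r.score
        return out

    def as_dict(self) -> dict:
        return {
            "threshold_used": self.threshold_used,
            "inverted": self.inverted,
            "confident_fraction": self.confident_fraction(),
            "segments": [r.as_dict() for r in self.records],
        }


# -- geometry --------------------------------------------------------------


def _sample_polyline(coords: np.ndarray, step: float = 0.5) -> np.ndarray:
    """Points along a polyline at <= step spacing, keeping all vertices."""
    out = [coords[0]]
    for k in range(len(coords) - 1):
        a, b = coords[k], coords[k + 1]
        seg = float(np.linalg.norm(b - a))
        n = max(int(np.ceil(seg / step)), 1)
        for i in range(1, n + 1):
            out.append(a + (b - a) * (i / n))
    return np.asarray(out)


def segment_tube_mask(
    shape: tuple[int, int, int], seg: Segment, radius_policy=default_mask_radius
) -> np.ndarray:
    """Boolean volume of the segment's masking tube, endpoint spheres excluded.

    A voxel belongs to the tube when its exact distance to some centerline
    edge is within that edge's tube radius (max of the two node radii under
    ``radius_policy``) — unless it lies within the 2-voxel protection sphere
    of either endpoint, which must stay intact for the alternative-path
    search to start and finish on real signal.  Nodes outside the volume are
    clipped with a logged warning.
    """
    shape = np.array(shape)
    mask = np.zeros(tuple(shape), dtype=bool)
    coords = seg.coords_zyx()
    if (coords < 0).any() or (coords > shape - 1).any():
        logger.warning("segment extends outside the image; clipping to bounds")
        coords = np.clip(coords, 0, shape - 1)
    radii = np.array([radius_policy(n.effective_radius()) for n in seg.node_path])
    pa, pb = coords[0], coords[-1]
    for k in range(len(coords) - 1):
        a, b = coords[k], coords[k + 1]
        r = max(radii[k], radii[k + 1])
        lo = np.maximum(np.floor(np.minimum(a, b) - r), 0).astype(int)
        hi = np.minimum(np.ceil(np.maximum(a, b) + r) + 1, shape).astype(int)
        if (hi <= lo).any():
            continue
        zz, yy, xx = np.meshgrid(
            *(np.arange(lo[d], hi[d]) for d in range(3)), indexing="ij"
        )
        p = np.stack([zz, yy, xx], axis=-1).astype(float)
        ab = b - a
        denom = float(ab @ ab)
        t = ((p - a) @ ab) / denom if denom > 0 else np.zeros(p.shape[:-1])
        t = np.clip(t, 0.0, 1.0)[..., None]
        d = np.linalg.norm(p - (a + t * ab), axis=-1)
        protected = (np.linalg.norm(p - pa, axis=-1) <= 2.0) | (
            np.linalg.norm(p - pb, axis=-1) <= 2.0
        )
        sl = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
        mask[sl] |= (d <= r) & ~protected
    return mask


def mask_segment(img: Image3D, seg: Segment, radius_policy=default_mask_radius) -> Image3D:
    """Zero the image inside the segment's masking tube; endpoints protected.

    See :func:`segment_tube_mask` for the geometry.  Returns a copy; the
    input image is untouched.
    """
    out = img.data.copy()
    out[segment_tube_mask(out.shape, seg, radius_policy)] = 0
    return Image3D(out, img.spacing)


# -- path search -----------------------------------------------------------


def path_cost_array(data: np.ndarray, i_max: float) -> np.ndarray:
    """Node cost c(x) = (1 - I(x)/I_max)^2 + eps."""
    return (1.0 - data.astype(np.float64) / float(i_max)) ** 2 + EPS_COST


def alternative_path(
    img_masked: Image3D,
    i: tuple[int, int, int],
    j: tuple[int, int, int],
    i_max: float | None = None,
    margin: int = 16,
    barrier: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Cheapest 26-connected voxel path between i and j in the masked image.

    Returns ``(path, cost)`` where ``path`` is an (n, 3) array of (z, y, x)
    voxels.  ``barrier`` (boolean, image-shaped) marks voxels carrying
    :data:`BARRIER_COST` — the masked corridor, which the path must avoid
    whenever any alternative exists.  The search runs inside the bounding
    box of the two endpoints padded by ``margin`` voxels (paths between
    segment endpoints have no reason to wander far outside it; on small
    volumes the box covers the whole image, where the cost provably equals
    a full-graph Dijkstra).
    """
    i = tuple(int(v) for v in i)
    j = tuple(int(v) for v in j)
    if i == j:
        raise ValueError("alternative_path endpoints must differ")
    shape = img_masked.data.shape
    for p in (i, j):
        if any(not 0 <= p[d] < shape[d] for d in range(3)):
            raise ValueError(f"endpoint {p} outside image {shape}")
    if i_max is None:
        i_max = img_masked.require_positive_max()

    lo = np.maximum(np.minimum(i, j) - margin, 0)
    hi = np.minimum(np.maximum(i, j) + margin + 1, shape)
    sl = tuple(slice(lo[d], hi[d]) for d in range(3))
    cost = path_cost_array(img_masked.data[sl], i_max)
    if barrier is not None:
        cost[barrier[sl]] = BARRIER_COST
    start = tuple(np.array(i) - lo)
    end = tuple(np.array(j) - lo)
    idx, total = route_through_array(
        cost, start, end, fully_connected=True, geometric=True
    )
    path = np.asarray(idx) + lo
    return path, float(total)


def mean_path_intensity(img_original: Image3D, path: np.ndarray) -> float:
    """Arc-length-weighted (trapezoidal) mean intensity along a voxel path.

    Intensities are read from the original (unmasked) image with trilinear
    interpolation, so non-integer path points are valid.
    """
    path = np.asarray(path, dtype=float)
    if path.ndim != 2 or path.shape[1] != 3 or len(path) < 2:
        raise ValueError("path must be an (n>=2, 3) array of (z,y,x) points")
    steps = np.linalg.norm(np.diff(path, axis=0), axis=1)
    if steps.sum() <= 0:
        raise ValueError("zero-length path")
    vals = map_coordinates(
        img_original.data.astype(np.float64), path.T, order=1, mode="nearest"
    )
    seg_means = 0.5 * (vals[:-1] + vals[1:])
    return float((seg_means * steps).sum() / steps.sum())


# -- scoring ---------------------------------------------------------------


def segment_mean_intensity(img: Image3D, seg: Segment, step: float = 0.5) -> float:
    """Mean intensity along the segment's own centerline (Eq.-style integral)."""
    return mean_path_intensity(img, _sample_polyline(seg.coords_zyx(), step=step))


def score_segments(
    img: Image3D,
    tree: NeuronTree,
    threshold: float = 0.5,
    invert: bool = False,
    margin: int = 16,
    min_nodes: int = 3,
    min_length: float = 5.0,
    radius_policy=default_mask_radius,
) -> ConfidenceReport:
    """Score every segment of a reconstruction; C <= threshold is confident.

    ``invert=True`` scores on the intensity-inverted image (I_max - I), the
    appropriate reading of "invert the score" for inverted-contrast
    (brightfield) volumes — it keeps the cost function's bright-is-cheap
    semantics.  Segments too short to score meaningfully (< ``min_nodes``
    nodes or < ``min_length`` voxels) inherit the label of their upstream
    neighbor segment; with no upstream neighbor they default to confident.
    A segment whose own mean intensity is 0 gets score +inf and is labeled
    uncertain with a warning.
    """
    work = img
    if invert:
        work = Image3D(
            (img.max_intensity - img.data.astype(np.int64)).astype(img.data.dtype),
            img.spacing,
        )
    i_max = work.require_positive_max()
    segments = decompose_segments(tree)
    records: list[SegmentScore] = []
    # upstream segment of segment s: the one whose downstream endpoint is
    # s's upstream endpoint (used only for short-segment label inheritance)
    end_node_to_idx = {s.node_path[-1].id: k for k, s in enumerate(segments)}

    scores: list[float] = []
    labels: list[bool | None] = []
    short: list[bool] = []
    for k, seg in enumerate(segments):
        length = seg.length()
        is_short = len(seg.node_path) < min_nodes or length < min_length
        mean_i = segment_mean_intensity(work, seg)
        if mean_i <= 0:
            logger.warning("segment %d has zero mean intensity; labeled uncertain", k)
            scores.append(float("inf"))
            labels.append(False)
            short.append(False)
            continue
        tube = segment_tube_mask(work.data.shape, seg, radius_policy=radius_policy)
        masked = Image3D(np.where(tube, 0, work.data).astype(work.data.dtype), work.spacing)
        a = seg.node_path[0].zyx()
        b = seg.node_path[-1].zyx()
        if a == b:
            # degenerate (closed or single-voxel) segment: nothing to compare
            scores.append(float("inf"))
            labels.append(False)
            short.append(is_short)
            continue
        alt, _ = alternative_path(masked, a, b, i_max=i_max, margin=margin, barrier=tube)
        alt_mean = mean_path_intensity(work, alt)
        c = alt_mean / mean_i
        scores.append(c)
        labels.append(None if is_short else c <= threshold)
        short.append(is_short)

    # resolve short-segment labels by walking upstream
    def resolve(k: int, hops: int = 0) -> bool:
        if labels[k] is not None:
            return labels[k]
        up = end_node_to_idx.get(segments[k].node_path[0].id)
        if up is None or hops > len(segments):
            return True  # isolated short segment: keep it as an exemplar source
        labels[k] = resolve(up, hops + 1)
        return labels[k]

    for k, seg in enumerate(segments):
        confident = resolve(k)
        mean_i = segment_mean_intensity(work, seg) if np.isfinite(scores[k]) else 0.0
        alt_mean = scores[k] * mean_i if np.isfinite(scores[k]) else 0.0
        records.append(
            SegmentScore(
                segment_index=k,
                mean_intensity=mean_i,
                alt_mean_intensity=alt_mean,
                score=scores[k],
                confident=bool(confident),
                length=seg.length(),
                n_nodes=len(seg.node_path),
            )
        )
    return ConfidenceReport(
        records=records, threshold_used=threshold, inverted=invert, segments=segments
    )
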