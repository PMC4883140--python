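"""Synthetic 3D neuron-like volumes with ground-truth centerline trees.

The generator emulates the kind of data the method targets: sparse bright
tubular neurites of configurable radius on a dark background, with branch
points, signal gaps of configurable width (the dropout that makes
component-based tracers stop), smooth intensity inhomogeneity, and additive
Gaussian noise.  Every phantom comes with an exact ground-truth centerline
as a :class:`~smarttrace.io_formats.NeuronTree`.

Geometry is defined by polylines in (z, y, x) voxel coordinates.  A voxel at
exact distance ``d`` from the nearest (non-gapped) centerline gets intensity

    background + (foreground - background) * falloff(d)

with ``falloff = 1`` for ``d <= tube_radius`` and a linear 1-voxel ramp to 0
at ``tube_radius + 1`` — the soft edge is what makes the "uncertain" middle
exemplar layer meaningful.  Distances are exact point-to-segment distances,
so rendered geometry matches analytic expectations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np

from .errors import PhantomSpecError
from .io_formats import Image3D, NeuronTree, SwcNode

__all__ = [
    "PhantomSpec",
    "generate_phantom",
    "make_loop_phantom",
    "straight_tube_polyline",
    "y_tree_polylines",
]


@dataclass
class PhantomSpec:
    """Declarative description of a synthetic tubular volume.

    Parameters
    ----------
    shape
        Volume dimensions (z, y, x).
    branches
        One polyline per branch: an (n, 3) array of (z, y, x) control points.
        The first polyline starts the tree; a later polyline whose first
        point lies within 2 voxels of an existing ground-truth node attaches
        there (branch point), otherwise it starts a new root.
    tube_radius
        Neurite radius in voxels.
    foreground_intensity, background_intensity
        Plateau intensities; foreground must exceed background (fluorescence
        convention) unless ``brightfield`` is set, which inverts the volume.
    noise_sigma
        Additive Gaussian noise, clipped to the dtype range.
    gaps
        List of ``(branch_index, start_fraction, length_voxels)``: along that
        branch's arc length, signal is dropped (rendered at background) from
        ``start_fraction * branch_length`` for ``length_voxels``.  Ground
        truth keeps the full centerline — the gap is signal dropout, not
        missing anatomy.
    intensity_gradient
        Optional per-axis multiplicative ramp amplitudes (g_z, g_y, g_x): the
        multiplier varies linearly from ``1 - g/2`` to ``1 + g/2`` along each
        axis, emulating uneven illumination.
    """

    shape: tuple[int, int, int] = (96, 128, 128)
    branches: list = field(default_factory=list)
    tube_radius: float = 2.0
    foreground_intensity: float = 200.0
    background_intensity: float = 10.0
    noise_sigma: float = 5.0
    gaps: list = field(default_factory=list)
    intensity_gradient: tuple[float, float, float] | None = None
    brightfield: bool = False
    dtype_bits: int = 8
    seed: int = 0

    def validate(self) -> None:
        if self.dtype_bits not in (8, 16):
            raise PhantomSpecError("dtype_bits must be 8 or 16")
        if not self.branches:
            raise PhantomSpecError("at least one branch polyline required")
        if self.foreground_intensity <= self.background_intensity:
            raise PhantomSpecError(
                "foreground_intensity must exceed background_intensity "
                "(use brightfield=True for inverted-contrast volumes)"
            )
        if self.tube_radius <= 0:
            raise PhantomSpecError("tube_radius must be positive")
        shape = np.array(self.shape, dtype=float)
        for b, pts in enumerate(self.branches):
            pts = np.asarray(pts, dtype=float)
            if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
                raise PhantomSpecError(f"branch {b}: need an (n>=2, 3) polyline")
            if (pts - self.tube_radius < 0).any() or (
                pts + self.tube_radius > shape - 1
            ).any():
                raise PhantomSpecError(f"branch {b}: tube extends out of bounds")
        for g, (bi, frac, length) in enumerate(self.gaps):
            if not 0 <= bi < len(self.branches):
                raise PhantomSpecError(f"gap {g}: branch index {bi} out of range")
            if not 0.0 <= frac < 1.0:
                raise PhantomSpecError(f"gap {g}: start fraction must be in [0, 1)")
            blen = _polyline_length(np.asarray(self.branches[bi], dtype=float))
            if length <= 0 or length >= blen:
                raise PhantomSpecError(
                    f"gap {g}: length {length} must be in (0, branch length {blen:.1f})"
                )

    def to_json(self) -> str:
        d = {
            "shape": list(self.shape),
            "branches": [np.asarray(b, dtype=float).tolist() for b in self.branches],
            "tube_radius": self.tube_radius,
            "foreground_intensity": self.foreground_intensity,
            "background_intensity": self.background_intensity,
            "noise_sigma": self.noise_sigma,
            "gaps": [list(g) for g in self.gaps],
            "intensity_gradient": list(self.intensity_gradient)
            if self.intensity_gradient
            else None,
            "brightfield": self.brightfield,
            "dtype_bits": self.dtype_bits,
            "seed": self.seed,
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        d = json.loads(text)
        d["shape"] = tuple(d["shape"])
        if d.get("intensity_gradient"):
            d["intensity_gradient"] = tuple(d["intensity_gradient"])
        d["gaps"] = [tuple(g) for g in d.get("gaps", [])]
        return cls(**d)


# -- geometry helpers ------------------------------------------------------


def _polyline_length(pts: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def _split_by_arclength(pts: np.ndarray, remove: list[tuple[float, float]]):
    """Split a polyline into kept sub-polylines, removing arc-length intervals.

    Interval endpoints are interpolated exactly, so kept geometry is a subset
    of the original curve.
    """
    seglen = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    total = cum[-1]

    def point_at(s: float) -> np.ndarray:
        s = min(max(s, 0.0), total)
        k = int(np.searchsorted(cum, s, side="right") - 1)
        k = min(k, len(seglen) - 1)
        t = (s - cum[k]) / seglen[k] if seglen[k] > 0 else 0.0
        return pts[k] + t * (pts[k + 1] - pts[k])

    # kept intervals = complement of the union of removed intervals
    removed = sorted((max(a, 0.0), min(b, total)) for a, b in remove)
    kept: list[tuple[float, float]] = []
    pos = 0.0
    for a, b in removed:
        if a > pos:
            kept.append((pos, a))
        pos = max(pos, b)
    if pos < total:
        kept.append((pos, total))

    out = []
    for a, b in kept:
        if b - a <= 1e-9:
            continue
        inner = pts[(cum > a + 1e-9) & (cum < b - 1e-9)]
        sub = np.vstack([point_at(a)[None], inner, point_at(b)[None]])
        out.append(sub)
    return out


def _distance_to_polyline(shape, pts: np.ndarray, reach: float) -> np.ndarray:
    """Exact distance from every voxel center to a polyline, capped at ``reach``.

    Computed per segment inside the segment's bounding box (plus margin) to
    stay fast on sparse scenes; voxels farther than ``reach`` hold +inf.
    """
    dist = np.full(shape, np.inf, dtype=np.float32)
    for k in range(len(pts) - 1):
        a, b = pts[k], pts[k + 1]
        lo = np.maximum(np.floor(np.minimum(a, b) - reach), 0).astype(int)
        hi = np.minimum(np.ceil(np.maximum(a, b) + reach) + 1, shape).astype(int)
        if (hi <= lo).any():
            continue
        zz, yy, xx = np.meshgrid(
            np.arange(lo[0], hi[0]),
            np.arange(lo[1], hi[1]),
            np.arange(lo[2], hi[2]),
            indexing="ij",
        )
        p = np.stack([zz, yy, xx], axis=-1).astype(np.float32)
        ab = b - a
        denom = float(ab @ ab)
        t = ((p - a) @ ab) / denom if denom > 0 else np.zeros(p.shape[:-1])
        t = np.clip(t, 0.0, 1.0)[..., None]
        d = np.linalg.norm(p - (a + t * ab), axis=-1)
        sl = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
        np.minimum(dist[sl], d, out=dist[sl])
    return dist


def _resample_polyline(pts: np.ndarray, step: float = 1.0) -> np.ndarray:
    """Points on the polyline at <= ``step`` spacing, keeping every vertex.

    All returned points lie exactly on the curve, so the chord-length sum of
    the result equals the analytic polyline length.
    """
    out = [pts[0]]
    for k in range(len(pts) - 1):
        a, b = pts[k], pts[k + 1]
        seg = np.linalg.norm(b - a)
        n = max(int(np.ceil(seg / step)), 1)
        for i in range(1, n + 1):
            out.append(a + (b - a) * (i / n))
    return np.asarray(out)


def _ground_truth_tree(branches, radius: float) -> NeuronTree:
    """Build the centerline tree: branch polylines resampled at ~1 voxel."""
    nodes: list[SwcNode] = []
    coords: list[np.ndarray] = []  # (z,y,x) of accepted nodes, parallel to nodes
    next_id = 1
    for pts in branches:
        pts = np.asarray(pts, dtype=float)
        samples = _resample_polyline(pts, step=1.0)
        parent = -1
        start = 0
        if coords:
            d = np.linalg.norm(np.asarray(coords) - samples[0], axis=1)
            j = int(np.argmin(d))
            if d[j] <= 2.0:
                parent = nodes[j].id
                start = 1  # attach: skip duplicate first point
        for p in samples[start:]:
            nodes.append(
                SwcNode(
                    id=next_id,
                    type_code=3 if parent != -1 else 1,
                    x=float(p[2]),
                    y=float(p[1]),
                    z=float(p[0]),
                    radius=radius,
                    parent_id=parent,
                )
            )
            coords.append(p)
            parent = next_id
            next_id += 1
    return NeuronTree(nodes=nodes, provenance="phantom ground truth")


# -- generators ------------------------------------------------------------


def generate_phantom(spec: PhantomSpec) -> tuple[Image3D, NeuronTree]:
    """Render a phantom volume and its ground-truth centerline tree.

    Deterministic: the same spec (including seed) yields bit-identical
    output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    reach = spec.tube_radius + 1.0

    dist = np.full(shape, np.inf, dtype=np.float32)
    gaps_by_branch: dict[int, list[tuple[float, float]]] = {}
    for bi, frac, length in spec.gaps:
        blen = _polyline_length(np.asarray(spec.branches[bi], dtype=float))
        s0 = frac * blen
        # widen by the tube reach so the rounded end caps of the kept pieces
        # do not refill the slot: the centerline sits at background level for
        # exactly the requested gap length
        gaps_by_branch.setdefault(bi, []).append((s0 - reach, s0 + length + reach))
    for bi, pts in enumerate(spec.branches):
        pts = np.asarray(pts, dtype=float)
        pieces = (
            _split_by_arclength(pts, gaps_by_branch[bi])
            if bi in gaps_by_branch
            else [pts]
        )
        for piece in pieces:
            np.minimum(dist, _distance_to_polyline(shape, piece, reach), out=dist)

    falloff = np.clip(spec.tube_radius + 1.0 - dist, 0.0, 1.0)
    img = spec.background_intensity + (
        spec.foreground_intensity - spec.background_intensity
    ) * falloff.astype(np.float64)

    if spec.intensity_gradient is not None:
        for ax, g in enumerate(spec.intensity_gradient):
            if g == 0:
                continue
            n = shape[ax]
            ramp = 1.0 + g * (np.arange(n) / max(n - 1, 1) - 0.5)
            sl = [None, None, None]
            sl[ax] = slice(None)
            img = img * ramp[tuple(sl)]

    dtype = np.uint8 if spec.dtype_bits == 8 else np.uint16
    vmax = float(np.iinfo(dtype).max)
    if spec.brightfield:
        img = vmax - img
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=shape)
    img = np.clip(np.rint(img), 0, vmax).astype(dtype)

    tree = _ground_truth_tree(spec.branches, spec.tube_radius)
    return Image3D(img), tree


def make_loop_phantom(
    spec: PhantomSpec, loop_radius: float | None = None, n_points: int = 64
) -> tuple[Image3D, NeuronTree]:
    """Phantom containing a closed bright ring; ground truth covers half of it.

    The rendered image holds the full circle (in the central z-plane), while
    the returned tree traces only one semicircle — so the traced segment has
    a genuine equal-intensity alternative pathway along the other half.
    ``spec.branches`` and ``spec.gaps`` are ignored; other fields apply.
    """
    shape = tuple(spec.shape)
    if loop_radius is None:
        loop_radius = min(shape[1], shape[2]) / 4.0
    if loop_radius <= spec.tube_radius:
        raise PhantomSpecError(
            f"degenerate loop: loop_radius {loop_radius} must exceed tube_radius"
        )
    cz, cy, cx = shape[0] / 2.0, shape[1] / 2.0, shape[2] / 2.0
    theta = np.linspace(0.0, 2.0 * np.pi, n_points + 1)
    circle = np.stack(
        [
            np.full_like(theta, cz),
            cy + loop_radius * np.sin(theta),
            cx + loop_radius * np.cos(theta),
        ],
        axis=1,
    )
    half = circle[: n_points // 2 + 1]

    render_spec = PhantomSpec(
        shape=shape,
        branches=[circle],
        tube_radius=spec.tube_radius,
        foreground_intensity=spec.foreground_intensity,
        background_intensity=spec.background_intensity,
        noise_sigma=spec.noise_sigma,
        gaps=[],
        intensity_gradient=spec.intensity_gradient,
        brightfield=spec.brightfield,
        dtype_bits=spec.dtype_bits,
        seed=spec.seed,
    )
    img, _ = generate_phantom(render_spec)
    tree = _ground_truth_tree([half], spec.tube_radius)
    return img, tree


# -- convenience geometry --------------------------------------------------


def straight_tube_polyline(shape, axis: int = 2, margin: float = 8.0) -> np.ndarray:
    """A straight centerline through the volume center along one axis."""
    c = np.array(shape, dtype=float) / 2.0
    a, b = c.copy(), c.copy()
    a[axis] = margin
    b[axis] = shape[axis] - 1 - margin
    return np.stack([a, b])


def y_tree_polylines(shape, margin: float = 8.0):
    """Stem plus two diverging arms meeting at a single branch point."""
    z, y, x = (s / 2.0 for s in shape)
    stem = np.array([[z, y, margin], [z, y, x]])
    arm1 = np.array([[z, y, x], [z, margin, shape[2] - 1 - margin]])
    arm2 = np.array([[z, y, x], [z, shape[1] - 1 - margin, shape[2] - 1 - margin]])
    return [stem, arm1, arm2]
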