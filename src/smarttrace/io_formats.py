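"""Readers/writers for the two formats the tool touches: SWC trees and TIFF stacks.

Coordinate convention
---------------------
SWC ``x, y, z`` are 0-based voxel coordinates in (x, y, z) order; image arrays
are indexed ``(z, y, x)``.  Non-integer SWC coordinates are allowed; rounding
to the nearest voxel happens only where voxel access is required
(:meth:`SwcNode.zyx`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

from .errors import ImageFormatError, SwcParseError, SwcStructureError

__all__ = [
    "Image3D",
    "SwcNode",
    "NeuronTree",
    "read_swc",
    "write_swc",
    "read_image",
    "write_image",
]


@dataclass
class Image3D:
    """A 3D scalar intensity volume, indexed (z, y, x).

    Parameters
    ----------
    data
        3D unsigned-integer array (uint8 or uint16).
    spacing
        Per-axis voxel size in (z, y, x) order.  Informational only: path
        costs and distances are computed in voxel units.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Image3D requires a 3D array, got ndim={self.data.ndim}")
        if self.data.dtype not in (np.dtype(np.uint8), np.dtype(np.uint16)):
            raise ValueError(
                f"Image3D requires uint8 or uint16 data, got {self.data.dtype}"
            )
        if any(s < 1 for s in self.data.shape):
            raise ValueError(f"all dimensions must be >= 1, got {self.data.shape}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def dtype_bits(self) -> int:
        return int(self.data.dtype.itemsize * 8)

    @property
    def max_intensity(self) -> int:
        return int(self.data.max())

    def require_positive_max(self) -> int:
        """Return I_max, the global maximum used to normalize intensities."""
        m = self.max_intensity
        if m <= 0:
            raise ValueError("operation requires max intensity > 0")
        return m

    def copy(self) -> "Image3D":
        return Image3D(self.data.copy(), self.spacing)


@dataclass(frozen=True)
class SwcNode:
    """One record of an SWC file: id, type, x, y, z, radius, parent."""

    id: int
    type_code: int
    x: float
    y: float
    z: float
    radius: float
    parent_id: int

    def zyx(self) -> tuple[int, int, int]:
        """Nearest-voxel (z, y, x) index of this node."""
        return (int(round(self.z)), int(round(self.y)), int(round(self.x)))

    def zyx_float(self) -> np.ndarray:
        return np.array([self.z, self.y, self.x], dtype=float)

    def effective_radius(self) -> float:
        """Radius with the convention that missing/zero radius means 1 voxel."""
        return self.radius if self.radius > 0 else 1.0


@dataclass
class NeuronTree:
    """An SWC-backed rooted tree (or forest).

    Invariants (enforced by :meth:`validate`): node ids are unique and
    positive, every non-root parent refers to an existing node, at least one
    root exists and there are no cycles.
    """

    nodes: list[SwcNode]
    comments: list[str] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------
    def validate(self) -> None:
        ids = [n.id for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise SwcStructureError("duplicate node ids")
        if any(i <= 0 for i in ids):
            raise SwcStructureError("node ids must be positive integers")
        idset = set(ids)
        roots = [n for n in self.nodes if n.parent_id == -1]
        for n in self.nodes:
            if n.parent_id != -1 and n.parent_id not in idset:
                raise SwcStructureError(
                    f"node {n.id} has dangling parent {n.parent_id}"
                )
        if self.nodes and not roots:
            raise SwcStructureError("tree has no root (parent_id == -1)")
        # cycle check: every node must be reachable from a root
        children = self.children_map()
        seen: set[int] = set()
        stack = [r.id for r in roots]
        while stack:
            i = stack.pop()
            if i in seen:
                raise SwcStructureError("cycle detected")
            seen.add(i)
            stack.extend(children.get(i, []))
        if len(seen) != len(self.nodes):
            raise SwcStructureError("cycle detected (nodes unreachable from any root)")

    def node_by_id(self) -> dict[int, SwcNode]:
        return {n.id: n for n in self.nodes}

    def children_map(self) -> dict[int, list[int]]:
        """Map node id -> child ids, children ordered by id."""
        out: dict[int, list[int]] = {n.id: [] for n in self.nodes}
        for n in sorted(self.nodes, key=lambda m: m.id):
            if n.parent_id != -1:
                out[n.parent_id].append(n.id)
        return out

    def roots(self) -> list[SwcNode]:
        return [n for n in self.nodes if n.parent_id == -1]

    def __len__(self) -> int:
        return len(self.nodes)


# -- SWC ------------------------------------------------------------------


def read_swc(path) -> NeuronTree:
    """Parse an SWC file into a validated :class:`NeuronTree`.

    Lines starting with ``#`` are preserved as comments for round-tripping.
    A malformed line raises :class:`SwcParseError` with its line number; a
    dangling parent or a cycle raises :class:`SwcStructureError`.
    """
    nodes: list[SwcNode] = []
    comments: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                comments.append(line)
                continue
            fields = line.split()
            if len(fields) != 7:
                raise SwcParseError(
                    f"{path}:{lineno}: expected 7 fields, got {len(fields)}"
                )
            try:
                nodes.append(
                    SwcNode(
                        id=int(fields[0]),
                        type_code=int(fields[1]),
                        x=float(fields[2]),
                        y=float(fields[3]),
                        z=float(fields[4]),
                        radius=float(fields[5]),
                        parent_id=int(fields[6]),
                    )
                )
            except ValueError as exc:
                raise SwcParseError(f"{path}:{lineno}: {exc}") from exc
    return NeuronTree(nodes=nodes, comments=comments, provenance=str(path))


def _fmt(v: float) -> str:
    return f"{v:.10g}"


def write_swc(tree: NeuronTree, path, color_scores: dict[int, float] | None = None):
    """Write a standard 7-column SWC file, nodes ordered by id.

    When ``color_scores`` maps node ids to scalars (e.g. per-segment
    confidence scores), a sidecar TSV ``<path>.scores.tsv`` with one
    ``id<TAB>score`` line per node is written alongside.
    """
    tree.validate()
    path = str(path)
    with open(path, "w") as fh:
        for c in tree.comments:
            fh.write(c + "\n")
        for n in sorted(tree.nodes, key=lambda m: m.id):
            fh.write(
                f"{n.id} {n.type_code} {_fmt(n.x)} {_fmt(n.y)} {_fmt(n.z)} "
                f"{_fmt(n.radius)} {n.parent_id}\n"
            )
    if color_scores is not None:
        with open(path + ".scores.tsv", "w") as fh:
            for n in sorted(tree.nodes, key=lambda m: m.id):
                fh.write(f"{n.id}\t{_fmt(color_scores.get(n.id, float('nan')))}\n")
    return path


# -- TIFF -----------------------------------------------------------------


def read_image(path, convert: bool = False) -> Image3D:
    """Read a grayscale TIFF stack as a (z, y, x) :class:`Image3D`.

    2D images become single-slice volumes.  RGB or float input raises
    :class:`ImageFormatError` unless ``convert=True``, in which case RGB is
    collapsed by channel mean and floats are min-max rescaled to uint16.
    """
    with tifffile.TiffFile(str(path)) as tif:
        rgb = tif.pages[0].samplesperpixel > 1
        arr = tif.asarray()
    if rgb:
        if not convert:
            raise ImageFormatError(
                f"{path}: RGB(A) input; pass convert=True to collapse channels"
            )
        arr = arr[..., :3].mean(axis=-1)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.ndim != 3:
        raise ImageFormatError(f"{path}: expected 2D or 3D grayscale, got {arr.shape}")
    if arr.dtype == np.uint8 or arr.dtype == np.uint16:
        return Image3D(arr)
    if not convert:
        raise ImageFormatError(
            f"{path}: dtype {arr.dtype} unsupported; pass convert=True to rescale"
        )
    arr = arr.astype(np.float64)
    lo, hi = arr.min(), arr.max()
    scale = 65535.0 / (hi - lo) if hi > lo else 0.0
    return Image3D(((arr - lo) * scale).round().astype(np.uint16))


def write_image(img: Image3D, path):
    """Write an :class:`Image3D` as a multi-page grayscale TIFF."""
    tifffile.imwrite(str(path), img.data, photometric="minisblack")
    return str(path)
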