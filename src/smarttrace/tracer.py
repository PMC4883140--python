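"""A minimal shortest-path-tree tracer (plus an adapter for external SWC).

This baseline tracer provides the initial and final tracing stages around
the learning loop.  It is deliberately simple and deliberately *gap
limited*: it thresholds the image, keeps only the foreground component
containing the soma seed, builds an intensity-weighted shortest-path tree
from the seed over that component, and extracts a centerline tree by
repeatedly tracing back from the farthest uncovered voxel, pruning branches
shorter than ``min_branch_length``.  Because tracing never leaves the
seed's connected component, it stops at any signal gap — recovering what
lies beyond a gap is the job of the learned foreground prediction, not of
the tracer.

Reconstructions from any external tracer are accepted as SWC files through
:func:`trace_adapter`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.ndimage import distance_transform_edt, label as cc_label
from scipy.sparse.csgraph import dijkstra
from skimage.filters import threshold_otsu

from .classify_grow import neighbor_offsets
from .confidence import path_cost_array
from .errors import SmartTraceError
from .io_formats import Image3D, NeuronTree, SwcNode

__all__ = ["TracerConfig", "baseline_trace", "trace_adapter"]

logger = logging.getLogger(__name__)


@dataclass
class TracerConfig:
    """Settings of the baseline tracer.

    ``background_threshold`` may be a number (voxels >= threshold are
    foreground) or ``"auto"`` (Otsu).  ``soma_seed`` is a (z, y, x) voxel or
    ``"auto"`` (global intensity maximum).  Branches shorter than
    ``min_branch_length`` voxels are pruned.
    """

    background_threshold: float | str = "auto"
    soma_seed: tuple[int, int, int] | str = "auto"
    min_branch_length: float = 8.0

    def resolve_threshold(self, img: Image3D) -> float:
        if self.background_threshold == "auto":
            return float(threshold_otsu(img.data))
        t = float(self.background_threshold)
        if t < 0:
            raise ValueError("background threshold must be >= 0")
        return t


def _component_of_seed(fg: np.ndarray, seed: tuple[int, int, int]) -> np.ndarray:
    structure = np.ones((3, 3, 3), dtype=bool)
    labels, _ = cc_label(fg, structure=structure)
    lab = labels[seed]
    if lab == 0:
        raise SmartTraceError(f"soma seed {seed} is below the background threshold")
    return labels == lab


def _dijkstra_tree(data: np.ndarray, comp: np.ndarray, seed_flat: int, edt: np.ndarray):
    """Intensity-weighted shortest-path tree over one foreground component.

    The node cost is the confidence module's intensity cost divided by
    (1 + distance-to-background), which pulls paths onto the medial axis of
    plateau-intensity tubes instead of hugging their edges.  Returns (flat
    voxel indices, predecessor compact ids, geodesic Euclidean path length
    per voxel along the tree, compact-id lookup, voxel coords).
    """
    shape = comp.shape
    flat = np.flatnonzero(comp)
    ids = np.full(comp.size, -1, dtype=np.int64)
    ids[flat] = np.arange(len(flat))
    cost = path_cost_array(data, max(float(data.max()), 1.0)).ravel()
    # medial-axis pull plus a small per-length charge: background stays far
    # more expensive than foreground, but within a bright plateau the charge
    # dominates noise fluctuations, so centerline paths stay straight
    cost = cost / (1.0 + edt.ravel()) + 0.05

    coords = np.stack(np.unravel_index(flat, shape), axis=1)
    rows, cols, weights, steps = [], [], [], []
    for off in neighbor_offsets(26):
        nb = coords + off
        ok = ((nb >= 0) & (nb < np.array(shape))).all(axis=1)
        nb_flat = np.ravel_multi_index(nb[ok].T, shape)
        valid = ids[nb_flat] >= 0
        src = np.arange(len(flat))[ok][valid]
        dst = ids[nb_flat[valid]]
        step = float(np.linalg.norm(off))
        rows.append(src)
        cols.append(dst)
        weights.append(step * 0.5 * (cost[flat[src]] + cost[flat[dst]]))
        steps.append(np.full(len(src), step))
    graph = sparse.csr_matrix(
        (np.concatenate(weights), (np.concatenate(rows), np.concatenate(cols))),
        shape=(len(flat), len(flat)),
    )
    dist, pred = dijkstra(
        graph, directed=False, indices=ids[seed_flat], return_predecessors=True
    )
    # Euclidean length along each traceback path, accumulated in distance order
    plen = np.zeros(len(flat))
    order = np.argsort(dist)
    pcoords = coords.astype(float)
    for v in order:
        p = pred[v]
        if p < 0:
            continue
        plen[v] = plen[p] + float(np.linalg.norm(pcoords[v] - pcoords[p]))
    plen[~np.isfinite(dist)] = -1.0
    return flat, pred, plen, ids, coords


def _mark_covered(covered: np.ndarray, voxels: np.ndarray, radii: np.ndarray) -> None:
    shape = np.array(covered.shape)
    for (z, y, x), r in zip(voxels, radii):
        r = int(np.ceil(r))
        lo = np.maximum([z - r, y - r, x - r], 0)
        hi = np.minimum([z + r + 1, y + r + 1, x + r + 1], shape)
        covered[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = True


def baseline_trace(img: Image3D, cfg: TracerConfig | None = None) -> NeuronTree:
    """Trace a centerline tree from the brightest connected structure.

    Steps: threshold; keep the seed's 26-connected foreground component;
    intensity-weighted shortest-path tree from the seed; extract centerlines
    by tracing back from the farthest-by-path-length voxel not yet covered
    by the tree's tubes, until every remaining candidate path is shorter
    than ``min_branch_length``; per-node radius is the distance to
    background.
    """
    cfg = cfg or TracerConfig()
    thr = cfg.resolve_threshold(img)
    fg = img.data >= thr
    if not fg.any():
        raise SmartTraceError(f"nothing above background threshold {thr}")

    if cfg.soma_seed == "auto":
        seed = np.unravel_index(int(np.argmax(img.data)), img.data.shape)
    else:
        seed = tuple(int(v) for v in cfg.soma_seed)
        if not fg[seed]:
            # snap to the nearest foreground voxel (re-tracing may hand us a
            # seed that the new threshold just excluded)
            cand = np.argwhere(fg)
            seed = tuple(cand[np.argmin(np.linalg.norm(cand - np.array(seed), axis=1))])
    comp = _component_of_seed(fg, seed)
    edt = distance_transform_edt(comp)

    # re-center the seed on the medial axis: take the deepest foreground
    # voxel within a small neighborhood (intensity plateaus make the raw
    # argmax land on an arbitrary plateau corner)
    z, y, x = seed
    lo = np.maximum([z - 4, y - 4, x - 4], 0)
    hi = np.minimum([z + 5, y + 5, x + 5], comp.shape)
    sub = edt[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    seed = tuple(np.array(np.unravel_index(int(np.argmax(sub)), sub.shape)) + lo)

    seed_flat = int(np.ravel_multi_index(seed, comp.shape))
    flat, pred, plen, ids, coords = _dijkstra_tree(img.data, comp, seed_flat, edt)

    covered = ~comp
    node_of: dict[int, int] = {}  # compact voxel id -> SWC node id
    nodes: list[SwcNode] = []

    def add_node(cid: int, parent: int) -> int:
        z, y, x = coords[cid]
        nid = len(nodes) + 1
        nodes.append(
            SwcNode(
                id=nid,
                type_code=1 if parent == -1 else 3,
                x=float(x),
                y=float(y),
                z=float(z),
                radius=max(float(edt[z, y, x]), 0.5),
                parent_id=parent,
            )
        )
        node_of[cid] = nid
        return nid

    node_coords: list[np.ndarray] = []  # parallel to nodes, (z,y,x)

    reachable = plen >= 0
    for _ in range(10000):
        cand_len = np.where(reachable & ~covered[tuple(coords.T)], plen, -np.inf)
        tip = int(np.argmax(cand_len))
        if not np.isfinite(cand_len[tip]):
            break
        # trace back toward the seed, stopping at the existing tree: either
        # an exact tree voxel or the first voxel its tubes already cover
        # (parallel predecessor wires inside one tube must merge, not
        # duplicate the centerline)
        chain: list[int] = []
        v = tip
        attach = -1
        while True:
            if v in node_of:
                attach = node_of[v]
                break
            if nodes and covered[tuple(coords[v])]:
                d = np.linalg.norm(np.asarray(node_coords) - coords[v], axis=1)
                attach = nodes[int(np.argmin(d))].id
                break
            chain.append(v)
            p = int(pred[v])
            if p < 0:
                break
            v = p
        chain.reverse()  # from tree side outward to tip
        if not chain:
            covered[tuple(coords[tip])] = True
            continue
        xyz = coords[chain].astype(float)
        new_len = float(np.linalg.norm(np.diff(xyz, axis=0), axis=1).sum())
        if attach != -1:
            new_len += float(
                np.linalg.norm(node_coords[attach - 1] - xyz[0])
            )
        radii = np.maximum(edt[tuple(coords[chain].T)], 1.0) + 2.0
        if new_len < cfg.min_branch_length and nodes:
            _mark_covered(covered, coords[chain], radii)
            continue
        parent = attach
        for cid in chain:
            parent = add_node(cid, parent)
            node_coords.append(coords[cid].astype(float))
        _mark_covered(covered, coords[chain], radii)
    if not nodes:
        raise SmartTraceError("tracing produced no nodes")
    tree = NeuronTree(nodes=nodes, provenance=f"baseline_trace(threshold={thr:g})")
    logger.info(
        "baseline trace: threshold %.3g, %d nodes, seed %s", thr, len(nodes), seed
    )
    return tree


def trace_adapter(path) -> NeuronTree:
    """Load an external tracer's SWC output as the initial reconstruction."""
    from .io_formats import read_swc

    tree = read_swc(path)
    tree.provenance = f"external:{path}"
    return tree
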