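import numpy as np
import pytest

from smarttrace.io_formats import Image3D, NeuronTree, SwcNode
from smarttrace.phantoms import (
    PhantomSpec,
    generate_phantom,
    straight_tube_polyline,
    y_tree_polylines,
)


def chain_tree(points_xyz, radius=1.0):
    """Build an unbranched tree through the given (x, y, z) points."""
    nodes = []
    for k, (x, y, z) in enumerate(points_xyz, start=1):
        nodes.append(
            SwcNode(id=k, type_code=3, x=x, y=y, z=z, radius=radius,
                    parent_id=k - 1 if k > 1 else -1)
        )
    return NeuronTree(nodes=nodes)


def y_tree():
    """Root - stem - bifurcation - two arms; coordinates in (x, y, z)."""
    pts = {
        1: (0, 0, 0, -1),
        2: (5, 0, 0, 1),
        3: (10, 0, 0, 2),
        4: (15, 5, 0, 3),
        5: (20, 10, 0, 4),
        6: (15, -5, 0, 3),
        7: (20, -10, 0, 6),
    }
    nodes = [
        SwcNode(id=i, type_code=3, x=v[0], y=v[1], z=v[2], radius=1.0, parent_id=v[3])
        for i, v in pts.items()
    ]
    return NeuronTree(nodes=nodes)


@pytest.fixture
def straight_tube():
    """Noise-free straight tube with ground truth, small volume."""
    spec = PhantomSpec(
        shape=(32, 48, 48),
        branches=[straight_tube_polyline((32, 48, 48))],
        noise_sigma=0.0,
    )
    return generate_phantom(spec) + (spec,)


@pytest.fixture
def noisy_tube():
    spec = PhantomSpec(
        shape=(32, 48, 80),
        branches=[straight_tube_polyline((32, 48, 80))],
        noise_sigma=5.0,
    )
    return generate_phantom(spec) + (spec,)


@pytest.fixture
def y_phantom():
    shape = (48, 96, 96)
    spec = PhantomSpec(shape=shape, branches=y_tree_polylines(shape), noise_sigma=0.0)
    return generate_phantom(spec) + (spec,)


def random_image(shape, seed=0, bits=8):
    rng = np.random.default_rng(seed)
    dtype = np.uint8 if bits == 8 else np.uint16
    hi = np.iinfo(dtype).max
    return Image3D(rng.integers(0, hi + 1, size=shape, dtype=dtype))
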