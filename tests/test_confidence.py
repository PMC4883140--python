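import heapq

import numpy as np
import pytest

from smarttrace.confidence import (
    BARRIER_COST,
    EPS_COST,
    alternative_path,
    mask_segment,
    mean_path_intensity,
    score_segments,
    segment_tube_mask,
)
from smarttrace.io_formats import Image3D
from smarttrace.morphology import decompose_segments
from smarttrace.phantoms import (
    PhantomSpec,
    _ground_truth_tree,
    generate_phantom,
    make_loop_phantom,
    straight_tube_polyline,
)

from conftest import chain_tree, random_image


def dijkstra_oracle(cost, start, end):
    """Brute-force Dijkstra over the full 26-connected voxel graph."""
    shape = cost.shape
    offs = [
        (a, b, c)
        for a in (-1, 0, 1)
        for b in (-1, 0, 1)
        for c in (-1, 0, 1)
        if (a, b, c) != (0, 0, 0)
    ]
    dist = {start: 0.0}
    pq = [(0.0, start)]
    done = set()
    while pq:
        d0, u = heapq.heappop(pq)
        if u in done:
            continue
        done.add(u)
        if u == end:
            return d0
        for o in offs:
            v = (u[0] + o[0], u[1] + o[1], u[2] + o[2])
            if any(not 0 <= v[k] < shape[k] for k in range(3)):
                continue
            step = (o[0] ** 2 + o[1] ** 2 + o[2] ** 2) ** 0.5
            nd = d0 + step * 0.5 * (cost[u] + cost[v])
            if nd < dist.get(v, np.inf) - 1e-12:
                dist[v] = nd
                heapq.heappush(pq, (nd, v))
    raise AssertionError("unreachable")


# -- masking ---------------------------------------------------------------


def test_mask_zeroes_centerline_but_not_endpoints(straight_tube):
    img, gt, spec = straight_tube
    seg = decompose_segments(gt)[0]
    masked = mask_segment(img, seg)
    coords = np.rint(seg.coords_zyx()).astype(int)
    interior = coords[5:-5]
    assert (masked.data[tuple(interior.T)] == 0).all()
    assert masked.data[tuple(coords[0])] > 0  # protection sphere intact
    assert img.data[tuple(interior[0])] > 0  # input untouched


def test_mask_idempotent(straight_tube):
    img, gt, _ = straight_tube
    seg = decompose_segments(gt)[0]
    once = mask_segment(img, seg)
    twice = mask_segment(once, seg)
    np.testing.assert_array_equal(once.data, twice.data)


def test_masked_voxel_count_matches_bruteforce():
    img = random_image((32, 32, 32), seed=1)
    tree = chain_tree([(6, 6, 6), (25, 12, 20)], radius=1.5)
    seg = decompose_segments(tree)[0]
    mask = segment_tube_mask(img.shape, seg)

    a = np.array([6.0, 6.0, 6.0])[::-1]  # (z,y,x)
    b = np.array([25.0, 12.0, 20.0])[::-1]
    r = max(1.5, 1.0) + 1.0
    count = 0
    for z in range(32):
        for y in range(32):
            for x in range(32):
                p = np.array([z, y, x], dtype=float)
                ab = b - a
                t = np.clip((p - a) @ ab / (ab @ ab), 0, 1)
                d = np.linalg.norm(p - (a + t * ab))
                if d <= r and np.linalg.norm(p - a) > 2 and np.linalg.norm(p - b) > 2:
                    count += 1
    assert int(mask.sum()) == count


# -- alternative path ------------------------------------------------------


def test_uniform_image_path_is_straight_geodesic():
    img = Image3D(np.full((12, 12, 12), 100, dtype=np.uint8))
    path, cost = alternative_path(img, (2, 2, 2), (2, 2, 9))
    c = EPS_COST  # (1 - 100/100)^2 + eps
    assert cost == pytest.approx(7 * c, rel=1e-9)
    assert len(path) == 8


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_path_cost_equals_dijkstra_oracle(seed):
    img = random_image((14, 15, 16), seed=seed)
    masked = img.data.copy()
    masked[5:9, :, :] = 0  # a masked slab as barrier
    m = Image3D(masked)
    barrier = np.zeros(img.shape, dtype=bool)
    barrier[5:9, :, :] = True
    barrier[2, 3, 4] = barrier[12, 12, 12] = False
    i, j = (2, 3, 4), (12, 12, 12)
    path, cost = alternative_path(m, i, j, barrier=barrier)
    c = (1.0 - m.data.astype(float) / m.data.max()) ** 2 + EPS_COST
    c[barrier] = BARRIER_COST
    assert cost == pytest.approx(dijkstra_oracle(c, i, j), rel=1e-9)
    assert tuple(path[0]) == i and tuple(path[-1]) == j


def test_loop_alternative_path_follows_bright_half():
    shape = (24, 64, 64)
    spec = PhantomSpec(shape=shape, branches=[straight_tube_polyline(shape)],
                       noise_sigma=0.0)
    img, half = make_loop_phantom(spec)
    seg = decompose_segments(half)[0]
    tube = segment_tube_mask(img.shape, seg)
    masked = Image3D(np.where(tube, 0, img.data).astype(np.uint8))
    a, b = seg.node_path[0].zyx(), seg.node_path[-1].zyx()
    path, _ = alternative_path(masked, a, b, margin=40, barrier=tube)
    vals = img.data[tuple(np.asarray(path).T)]
    assert (vals > spec.background_intensity + 3 * 5).mean() >= 0.9


# -- mean intensity --------------------------------------------------------


def test_mean_intensity_constant_and_two_point():
    img = Image3D(np.full((8, 8, 8), 100, dtype=np.uint8))
    assert mean_path_intensity(img, [(1, 1, 1), (1, 1, 5)]) == pytest.approx(100.0)
    data = np.zeros((4, 4, 4), dtype=np.uint8)
    data[1, 1, 1], data[1, 1, 2] = 10, 30
    assert mean_path_intensity(Image3D(data), [(1, 1, 1), (1, 1, 2)]) == pytest.approx(20.0)


def test_mean_intensity_matches_trapezoid_oracle():
    img = random_image((10, 10, 10), seed=5)
    rng = np.random.default_rng(6)
    path = rng.integers(1, 9, size=(7, 3))
    got = mean_path_intensity(img, path)
    vals = img.data[tuple(path.T)].astype(float)
    steps = np.linalg.norm(np.diff(path.astype(float), axis=0), axis=1)
    expect = (0.5 * (vals[:-1] + vals[1:]) * steps).sum() / steps.sum()
    assert got == pytest.approx(expect, rel=1e-12)


def test_mean_intensity_rejects_degenerate():
    img = Image3D(np.full((4, 4, 4), 9, dtype=np.uint8))
    with pytest.raises(ValueError):
        mean_path_intensity(img, [(1, 1, 1)])
    with pytest.raises(ValueError):
        mean_path_intensity(img, [(1, 1, 1), (1, 1, 1)])


# -- scoring ---------------------------------------------------------------


def test_isolated_tube_scores_low(straight_tube):
    img, gt, _ = straight_tube
    rep = score_segments(img, gt)
    assert len(rep.records) == 1
    assert rep.records[0].score <= 0.3
    assert rep.records[0].confident


def test_loop_scores_high():
    shape = (24, 64, 64)
    spec = PhantomSpec(shape=shape, branches=[straight_tube_polyline(shape)],
                       noise_sigma=0.0)
    img, half = make_loop_phantom(spec)
    rep = score_segments(img, half, margin=40)
    assert rep.records[0].score >= 0.8
    assert not rep.records[0].confident


def test_parallel_duplicate_scores_near_one():
    shape = (32, 48, 48)
    b1 = np.array([[16.0, 22, 8], [16, 22, 39]])
    b2 = np.array([[16.0, 26, 8], [16, 26, 39]])
    spec = PhantomSpec(shape=shape, branches=[b1, b2], noise_sigma=0.0)
    img, _ = generate_phantom(spec)
    traced = _ground_truth_tree([b1], spec.tube_radius)
    rep = score_segments(img, traced, margin=20)
    assert 0.9 <= rep.records[0].score <= 1.1


def test_score_invariant_under_intensity_scaling(straight_tube):
    img, gt, _ = straight_tube
    s1 = score_segments(img, gt).records[0].score
    scaled = Image3D((img.data.astype(np.uint16) * 37))
    s2 = score_segments(scaled, gt).records[0].score
    assert s2 == pytest.approx(s1, rel=1e-6)


def test_brightfield_inversion_recovers_low_score(straight_tube):
    """A dark tube on bright background scores confident once inverted."""
    img, gt, _ = straight_tube
    inverted = Image3D((255 - img.data.astype(np.int16)).astype(np.uint8))
    without = score_segments(inverted, gt).records[0]
    with_inv = score_segments(inverted, gt, invert=True).records[0]
    assert with_inv.confident and with_inv.score <= 0.3
    assert without.score > with_inv.score  # un-inverted scoring is misled


def test_loop_monotonicity_in_corridor_brightness():
    """Brightening the alternative corridor never decreases the score."""
    shape = (24, 64, 64)
    scores = []
    for fg2 in (60, 120, 200):
        spec = PhantomSpec(shape=shape, branches=[straight_tube_polyline(shape)],
                           noise_sigma=0.0)
        img, half = make_loop_phantom(spec)
        # dim the un-traced half to fg2
        data = img.data.copy().astype(float)
        lower = np.zeros(shape, dtype=bool)
        lower[:, : shape[1] // 2 - 3, :] = True
        data[lower] = np.minimum(data[lower], fg2)
        img2 = Image3D(np.clip(data, 0, 255).astype(np.uint8))
        scores.append(score_segments(img2, half, margin=40).records[0].score)
    assert scores[0] <= scores[1] <= scores[2] + 1e-9


def test_zero_intensity_segment_flagged_uncertain():
    data = np.zeros((16, 16, 16), dtype=np.uint8)
    data[2, 2, 2] = 50  # give the image a positive max away from the segment
    img = Image3D(data)
    tree = chain_tree([(4, 8, 8), (12, 8, 8)])
    rep = score_segments(img, tree)
    assert np.isinf(rep.records[0].score)
    assert not rep.records[0].confident


def test_short_segment_inherits_upstream_label(straight_tube):
    img, gt, _ = straight_tube
    # hang a 1-edge stub off a mid node: a segment too short to score alone
    from smarttrace.io_formats import NeuronTree, SwcNode

    mid = gt.nodes[len(gt.nodes) // 2]
    stub = SwcNode(len(gt.nodes) + 1, 3, mid.x, mid.y + 2, mid.z, 1.0, mid.id)
    tree = NeuronTree(nodes=gt.nodes + [stub])
    rep = score_segments(img, tree)
    assert len(rep.records) == 3
    short = min(rep.records, key=lambda r: r.length)
    upstream = next(
        r for r in rep.records
        if rep.segments[r.segment_index].node_path[-1].id == mid.id
    )
    assert short.confident == upstream.confident
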