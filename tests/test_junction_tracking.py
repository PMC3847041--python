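"""Tracking pipeline: projections, thresholds, (x,y,t) watershed identity,
pair segmentation vs brute force, and track statistics."""
import numpy as np
import pytest

from junctionkit.errors import (
    DegenerateDataError,
    InsufficientCellsError,
    InvalidParameterError,
    NoContrastError,
)
from junctionkit.junction_tracking import (
    JunctionTrack,
    assembly_curve,
    central_projection,
    distance_mask,
    extract_junctions,
    junction_intensity_trace,
    junction_lifetime,
    segment_cells_xyt,
    threshold_mask,
    track_movie,
    two_closest_neighbor_map,
)
from junctionkit.stack_io import FrameStack
from junctionkit.synthetic_data import AssemblyParams, generate_assembly_movie


# ---------------------------------------------------------------------------
# central projection
# ---------------------------------------------------------------------------

def test_central_projection_uses_two_central_planes():
    data = np.zeros((1, 6, 1, 4, 4), np.float32)
    for z in range(6):
        data[0, z, 0] = z
    stack = FrameStack(data)
    # planes 2 and 3 (0-based) are the two central ones of six
    assert np.all(central_projection(stack)[0] == 3)


def test_central_projection_of_equal_planes_is_identity():
    plane = np.random.default_rng(0).random((8, 8)).astype(np.float32)
    data = np.stack([plane, plane])[None, :, None]
    assert np.allclose(central_projection(FrameStack(data))[0], plane)


def test_central_projection_z2_is_max_of_both():
    data = np.zeros((1, 2, 1, 2, 2), np.float32)
    data[0, 0, 0] = 1.0
    data[0, 1, 0] = 2.0
    assert np.all(central_projection(FrameStack(data))[0] == 2.0)


# ---------------------------------------------------------------------------
# thresholding
# ---------------------------------------------------------------------------

def test_threshold_mask_recovers_bright_square():
    img = np.full((32, 32), 5.0)
    img[8:20, 8:20] = 100.0
    mask = threshold_mask(img)
    expected = np.zeros((32, 32), bool)
    expected[8:20, 8:20] = True
    assert np.array_equal(mask, expected)


def test_threshold_mask_constant_image_rejected():
    with pytest.raises(NoContrastError):
        threshold_mask(np.full((16, 16), 3.0))


def brute_force_otsu(image: np.ndarray) -> int:
    """Exhaustive between-class-variance search over grey levels."""
    img = image.astype(int)
    best_t, best_var = 0, -1.0
    for t in range(img.min(), img.max()):
        lo, hi = img[img <= t], img[img > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size, hi.size
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


def test_otsu_matches_exhaustive_between_class_variance(rng):
    from skimage.filters import threshold_otsu

    img = np.concatenate(
        [rng.normal(60, 8, 3000), rng.normal(160, 12, 2000)]
    ).clip(0, 255).astype(np.uint8).reshape(50, 100)
    assert abs(threshold_otsu(img) - brute_force_otsu(img)) <= 2


# ---------------------------------------------------------------------------
# (x, y, t) cell segmentation
# ---------------------------------------------------------------------------

def _blob_movie(paths, n_frames=5, shape=(64, 64), sigma=3.0):
    """paths: list of per-frame (y, x) centers, one list entry per blob."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    vol = np.zeros((n_frames, *shape), np.float32)
    for path in paths:
        for f, (cy, cx) in enumerate(path):
            vol[f] += 100.0 * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))
    return vol


def test_two_stationary_blobs_keep_two_constant_ids():
    vol = _blob_movie([[(20, 20)] * 5, [(44, 44)] * 5])
    centers = segment_cells_xyt(vol)
    assert len(centers.ids()) == 2
    for frame in centers.frames:
        assert set(frame.keys()) == centers.ids()
        for cid, (cy, cx) in frame.items():
            ref = centers.frames[0][cid]
            assert abs(cy - ref[0]) < 1.5 and abs(cx - ref[1]) < 1.5


def test_drifting_blob_keeps_single_id():
    path = [(20 + 2 * f, 20 + 2 * f) for f in range(8)]
    vol = _blob_movie([path], n_frames=8)
    centers = segment_cells_xyt(vol)
    assert len(centers.ids()) == 1
    cid = next(iter(centers.ids()))
    # brute-force overlap tracking oracle: the centroid follows the path
    for f, (cy, cx) in enumerate(path):
        gy, gx = centers.frames[f][cid]
        assert abs(gy - cy) < 2.5 and abs(gx - cx) < 2.5


def test_merging_blobs_are_flagged():
    a = [(20, 20 + 2 * f) for f in range(8)]  # drifts right
    b = [(20, 44 - 2 * f) for f in range(8)]  # drifts left, meets a
    vol = _blob_movie([a, b], n_frames=8)
    centers = segment_cells_xyt(vol)
    # the merged tube collapses to one id and is flagged for exclusion
    assert len(centers.ids()) == 1
    assert centers.flagged_ids == centers.ids()


# ---------------------------------------------------------------------------
# pair maps and distance gating
# ---------------------------------------------------------------------------

def brute_force_pair(centers: dict, y: int, x: int) -> tuple[int, int]:
    dists = sorted(
        ((np.hypot(y - cy, x - cx), cid) for cid, (cy, cx) in centers.items())
    )
    pair = sorted([dists[0][1], dists[1][1]])
    return (pair[0], pair[1])


def test_two_cells_label_whole_frame_with_one_pair():
    centers = {3: (5.0, 5.0), 9: (20.0, 25.0)}
    pm = two_closest_neighbor_map(centers, (32, 32))
    assert pm.pairs == [(3, 9)]
    assert np.all(pm.index_map == 0)


def test_three_collinear_cells_brute_force_instance():
    centers = {0: (0.0, 0.0), 1: (0.0, 10.0), 2: (0.0, 20.0)}
    pm = two_closest_neighbor_map(centers, (1, 25))
    assert pm.pair_at(0, 4) == (0, 1)
    assert pm.pair_at(0, 16) == (1, 2)


def test_equidistant_pixel_takes_two_lowest_ids():
    # pixel (10, 10) is equidistant to all three centers
    centers = {5: (0.0, 10.0), 2: (10.0, 0.0), 8: (20.0, 10.0)}
    pm = two_closest_neighbor_map(centers, (21, 21))
    assert pm.pair_at(10, 10) == (2, 5)


def test_pair_map_matches_brute_force_everywhere(rng):
    shape = (128, 128)
    centers = {int(i): (float(rng.uniform(0, 127)), float(rng.uniform(0, 127))) for i in range(5)}
    pm = two_closest_neighbor_map(centers, shape)
    for y in range(0, 128, 7):
        for x in range(0, 128, 7):
            assert pm.pair_at(y, x) == brute_force_pair(centers, y, x)


def test_distance_mask_limits():
    centers = {0: (32.0, 32.0)}
    assert distance_mask(centers, (64, 64), max_dist_um=1e9).all()
    disk_mask = distance_mask(centers, (64, 64), max_dist_um=10.0)
    yy, xx = np.mgrid[0:64, 0:64]
    expected = np.hypot(yy - 32, xx - 32) <= 10.0
    assert np.array_equal(disk_mask, expected)


def test_distance_mask_matches_brute_force(rng):
    centers = {i: (float(rng.uniform(0, 63)), float(rng.uniform(0, 63))) for i in range(4)}
    mask = distance_mask(centers, (64, 64), max_dist_um=9.0, pixel_size=0.5)
    for y in range(0, 64, 5):
        for x in range(0, 64, 5):
            d = min(np.hypot(y - cy, x - cx) for cy, cx in centers.values()) * 0.5
            assert mask[y, x] == (d <= 9.0)


# ---------------------------------------------------------------------------
# track extraction and statistics
# ---------------------------------------------------------------------------

def _two_cell_setup(present_frames, n_frames=4, shape=(32, 32)):
    centers = {0: (16.0, 8.0), 1: (16.0, 24.0)}
    masks, pms, dms, images = [], [], [], []
    for f in range(n_frames):
        m = np.zeros(shape, bool)
        if f in present_frames:
            m[10:22, 15:17] = True
        masks.append(m)
        pms.append(two_closest_neighbor_map(centers, shape))
        dms.append(np.ones(shape, bool))
        images.append(np.where(m, 50.0, 5.0))
    return masks, pms, dms, images


def test_bright_interface_yields_single_track():
    masks, pms, dms, images = _two_cell_setup({0, 1, 2, 3})
    tracks = extract_junctions(masks, pms, dms, images=images)
    assert len(tracks) == 1
    assert tracks[0].junction_id == (0, 1)
    assert tracks[0].presence.all()


def test_track_identity_survives_temporal_gap():
    masks, pms, dms, images = _two_cell_setup({0, 1, 3})  # absent at frame 2
    tracks = extract_junctions(masks, pms, dms, images=images)
    assert len(tracks) == 1
    assert list(tracks[0].presence) == [True, True, False, True]


def test_no_suprathreshold_pixels_yields_no_tracks():
    masks, pms, dms, _ = _two_cell_setup(set())
    assert extract_junctions(masks, pms, dms) == []


def test_assembly_curve_counts_presence():
    masks, pms, dms, images = _two_cell_setup({1, 2, 3})
    tracks = extract_junctions(masks, pms, dms, images=images)
    assert list(assembly_curve(tracks, 4)) == [0, 1, 1, 1]
    assert list(assembly_curve([], 4)) == [0, 0, 0, 0]


def _track_with_presence(present, frame_interval=1.0):
    px = np.array([[0, 0], [0, 1], [1, 0], [1, 1], [2, 0]])
    pixels = [px if p else np.empty((0, 2), int) for p in present]
    return JunctionTrack(
        junction_id=(0, 1),
        pixels=pixels,
        mean_intensity=np.full(len(present), np.nan),
        frame_interval=frame_interval,
        min_area=5,
    )


def test_lifetime_percentages():
    always = _track_with_presence([True] * 50)
    assert junction_lifetime(always, 0, 49) == 100.0
    partial = _track_with_presence([True] * 41 + [False] * 9)
    assert junction_lifetime(partial, 0, 49) == pytest.approx(82.0)
    mostly_absent = _track_with_presence([True] + [False] * 49)
    assert junction_lifetime(mostly_absent, 10, 49) == 0.0


def test_lifetime_empty_window_rejected():
    with pytest.raises(InvalidParameterError):
        junction_lifetime(_track_with_presence([True] * 5), 100, 200)


def test_intensity_trace_constant_image():
    track = _track_with_presence([True] * 4)
    images = [np.full((4, 4), 7.0)] * 4
    trace = junction_intensity_trace(track, images)
    assert np.allclose(trace.values, 7.0)


def test_intensity_trace_holdover_uses_last_pixels():
    track = _track_with_presence([True, True, False, False])
    images = [np.full((4, 4), v) for v in (10.0, 20.0, 30.0, 40.0)]
    trace = junction_intensity_trace(track, images)
    # frames 2-3 reuse frame 1's pixel set but sample the current image
    assert list(trace.values) == [10.0, 20.0, 30.0, 40.0]


def test_intensity_trace_requires_some_pixels():
    with pytest.raises(DegenerateDataError):
        junction_intensity_trace(_track_with_presence([False] * 3), [np.zeros((4, 4))] * 3)


def test_insufficient_cells_rejected():
    with pytest.raises(InsufficientCellsError):
        two_closest_neighbor_map({0: (1.0, 1.0)}, (8, 8))


# ---------------------------------------------------------------------------
# pipeline recovery on a synthetic assembly movie
# ---------------------------------------------------------------------------

def test_pipeline_recovers_birth_times_and_counts():
    params = AssemblyParams(rate_true=0.203, seed=42, noise_sd=0.02)
    movie, truth = generate_assembly_movie(params)
    tracks, counts, centers = track_movie(movie)

    # per-frame counts within +/-1 of the ground truth
    assert np.all(np.abs(counts - truth.counts()) <= 1)

    # map watershed cell ids onto ground-truth cells by nearest center
    def truth_cell(center):
        return min(
            truth.cell_centers,
            key=lambda cid: np.hypot(
                center[0] - truth.cell_centers[cid][0],
                center[1] - truth.cell_centers[cid][1],
            ),
        )

    id_map = {wid: truth_cell(c) for wid, c in centers.frames[0].items()}
    assert len(set(id_map.values())) == params.n_cells  # one basin per cell

    # birth frames within +/-1 frame for at least 90 % of junctions
    true_births = {j.pair: j.birth_frame for j in truth.junctions}
    detected = {
        tuple(sorted((id_map[t.junction_id[0]], id_map[t.junction_id[1]]))): t.birth_frame
        for t in tracks
        if not t.excluded
    }
    hits = sum(
        1
        for pair, bf in true_births.items()
        if pair in detected and abs(detected[pair] - bf) <= 1
    )
    assert hits >= 0.9 * len(true_births)

    # pair-key identity: at most C(n_cells, 2) distinct ids
    n = params.n_cells
    assert len({t.junction_id for t in tracks}) <= n * (n - 1) // 2
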