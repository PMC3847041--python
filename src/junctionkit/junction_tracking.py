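"""Junction detection and identity-preserving tracking.

A junction is the interface between a *pair* of cells.  Cells are
segmented by a watershed computed on the full (x, y, t) volume so that a
cell keeps a single identity across the movie; each pixel of a frame is
then labelled with the unordered pair of its two closest cell centers.
Junction pixels are the suprathreshold pixels of a pair's region (within a
distance gate from the nearest center), and a junction's identity is the
pair key itself — so a junction that vanishes for a few frames, or is
spatially discontinuous, still maps back to the same track.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import h_maxima
from skimage.segmentation import watershed

from .errors import (
    DegenerateDataError,
    InsufficientCellsError,
    InvalidParameterError,
    NoCellsError,
    NoContrastError,
)
from .kinetics import IntensityTrace
from .stack_io import FrameStack

logger = logging.getLogger(__name__)

DEFAULT_MIN_AREA = 5  # px; a pair is "present" when it holds at least this many
DEFAULT_MAX_DIST_UM = 30.0
DEFAULT_SIGMA_PX = 2.0


@dataclass
class CellCenters:
    """Per-frame centers of persistently-identified cells.

    ``frames[f]`` maps a persistent ``cell_id`` to its (row, col) centroid in
    frame ``f``.  ``flagged_ids`` are cells whose basin footprint was
    multi-component in some frame (e.g. two cells whose basins merged);
    junctions touching them are excluded downstream.
    """

    frames: list[dict[int, tuple[float, float]]]
    flagged_ids: set[int] = field(default_factory=set)
    labels: np.ndarray | None = None  # (T, Y, X) basin label volume, for QC

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def ids(self) -> set[int]:
        out: set[int] = set()
        for f in self.frames:
            out.update(f.keys())
        return out


@dataclass
class PairLabelMap:
    """Pixel-wise assignment of the two-closest-cell pair for one frame."""

    index_map: np.ndarray  # (Y, X) int, index into ``pairs``; -1 where undefined
    pairs: list[tuple[int, int]]  # unordered pairs as sorted (id_a, id_b)

    def pair_at(self, row: int, col: int) -> tuple[int, int]:
        idx = int(self.index_map[row, col])
        if idx < 0:
            raise KeyError("no pair defined at this pixel")
        return self.pairs[idx]


@dataclass
class JunctionTrack:
    """A persistent junction identity: the unordered cell-pair key plus its
    per-frame pixel sets and mean intensities."""

    junction_id: tuple[int, int]
    pixels: list[np.ndarray]  # per frame, (k, 2) row/col arrays
    mean_intensity: np.ndarray  # per frame, NaN where never measured
    frame_interval: float = 1.0
    min_area: int = DEFAULT_MIN_AREA
    excluded: bool = False
    exclusion_reason: str = ""

    @property
    def n_frames(self) -> int:
        return len(self.pixels)

    @property
    def presence(self) -> np.ndarray:
        return np.array([px.shape[0] >= self.min_area for px in self.pixels])

    @property
    def birth_frame(self) -> int | None:
        hits = np.flatnonzero(self.presence)
        return int(hits[0]) if hits.size else None

    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


# ---------------------------------------------------------------------------
# Per-frame image operations
# ---------------------------------------------------------------------------

def central_projection(stack: FrameStack, channel: int | str = 0) -> np.ndarray:
    """Per-frame maximum-intensity projection of the two central z-planes.

    Returns a (T, Y, X) array.  With a single plane the data passes through
    with a warning.
    """
    sub = stack.channel(channel)  # (T, Z, Y, X)
    z = sub.shape[1]
    if z == 1:
        logger.warning("central_projection: single z-plane, passing through")
        return sub[:, 0]
    lo = int(np.floor((z - 1) / 2.0))
    hi = int(np.ceil((z - 1) / 2.0))
    if hi == lo:
        hi = lo + 1
    return np.maximum(sub[:, lo], sub[:, hi])


def stack_threshold(images: np.ndarray) -> float:
    """Otsu threshold pooled over all frames of a (T, Y, X) projection.

    Pooling keeps the threshold meaningful on frames that contain no
    suprathreshold structure yet (e.g. before the first junction forms).
    """
    flat = np.asarray(images).ravel()
    if flat.max() - flat.min() < 1e-12:
        raise NoContrastError("stack has no intensity contrast")
    return float(threshold_otsu(flat))


def _drop_small_components(labels: np.ndarray, min_size: int) -> np.ndarray:
    """Zero out labelled components with fewer than ``min_size`` voxels."""
    counts = np.bincount(labels.ravel())
    kill = np.flatnonzero(counts < min_size)
    out = labels.copy()
    out[np.isin(labels, kill)] = 0
    return out


def threshold_mask(
    image: np.ndarray,
    min_area: int = DEFAULT_MIN_AREA,
    threshold: float | None = None,
) -> np.ndarray:
    """Otsu threshold (or an explicit one) plus small-object removal."""
    image = np.asarray(image)
    if image.max() - image.min() < 1e-12:
        raise NoContrastError("image has no intensity contrast")
    if threshold is None:
        threshold = threshold_otsu(image)
    mask = image > threshold
    return _drop_small_components(cc_label(mask), min_area) > 0


# ---------------------------------------------------------------------------
# Cell segmentation in (x, y, t)
# ---------------------------------------------------------------------------

def segment_cells_xyt(
    marker_stack: FrameStack | np.ndarray,
    channel: int | str = 0,
    sigma_px: float = DEFAULT_SIGMA_PX,
    sigma_t: float = 1.0,
    time_scale: float = 1.0,
    h_depth: float = 1.0,
    min_seed_voxels: int | None = None,
) -> CellCenters:
    """Watershed the marker channel as a 3D (t, y, x) volume.

    The smoothed volume is thresholded (Otsu), a Euclidean distance
    transform is computed with the time axis scaled by ``time_scale`` pixels
    per frame, and seeds are the connected h-maxima plateaus of that
    distance map — one connected seed per cell tube, so every cell keeps a
    single id across the whole series.  The inverted distance map is then
    flooded over the full volume, tiling each frame into per-cell basins.
    """
    if isinstance(marker_stack, FrameStack):
        vol = central_projection(marker_stack, channel)
    else:
        vol = np.asarray(marker_stack, float)
        if vol.ndim == 2:
            vol = vol[np.newaxis]
    sm = gaussian(vol.astype(float), sigma=(sigma_t, sigma_px, sigma_px), preserve_range=True)
    if sm.max() - sm.min() < 1e-12:
        raise NoCellsError("marker volume has no contrast")
    mask = sm > threshold_otsu(sm)
    if not mask.any():
        raise NoCellsError("no foreground voxels in marker volume")
    if min_seed_voxels is None:
        # a persistent cell's seed ridge spans most frames; noise blobs do not
        min_seed_voxels = max(2, min(8, vol.shape[0] // 2))
    dist = ndi.distance_transform_edt(mask, sampling=(time_scale, 1.0, 1.0))
    seeds_bool = h_maxima(dist, h_depth).astype(bool)
    # one marker per connected marker-mask tube that carries distance-ridge
    # maxima: the maxima locate the cells, the tube keeps a moving cell's
    # seed connected through time (a cell drifting a few px/frame still
    # overlaps itself between consecutive frames)
    conn = np.ones((3, 3, 3), int)
    tubes, n_tubes = ndi.label(mask, structure=conn)
    if n_tubes == 0:
        raise NoCellsError("no watershed seeds found")
    ridge_counts = np.bincount(tubes[seeds_bool], minlength=n_tubes + 1)
    tube_sizes = np.bincount(tubes.ravel(), minlength=n_tubes + 1)
    keep = (ridge_counts >= 1) & (tube_sizes >= min_seed_voxels)
    keep[0] = False
    markers = np.where(keep[tubes], tubes, 0)
    markers, n_cells = ndi.label(markers > 0, structure=conn)
    if n_cells == 0:
        raise NoCellsError("no watershed seeds found")
    labels = watershed(-dist, markers)

    frames: list[dict[int, tuple[float, float]]] = []
    flagged: set[int] = set()
    for f in range(labels.shape[0]):
        frame_labels = labels[f]
        centers: dict[int, tuple[float, float]] = {}
        for cid in range(1, n_cells + 1):
            sel = frame_labels == cid
            if not sel.any():
                continue
            # a basin whose in-frame footprint intersects multiple marker
            # blobs indicates merged cells -> flag the id
            blob = mask[f] & sel
            n_blobs = cc_label(blob).max()
            if n_blobs > 1:
                flagged.add(cid)
            # the cell center is the marker (nucleus) centroid, not the
            # basin centroid — basins tile the whole frame
            cy, cx = ndi.center_of_mass(blob if blob.any() else sel)
            centers[cid] = (float(cy), float(cx))
        frames.append(centers)
    return CellCenters(frames=frames, flagged_ids=flagged, labels=labels)


# ---------------------------------------------------------------------------
# Pair segmentation
# ---------------------------------------------------------------------------

def two_closest_neighbor_map(
    centers: dict[int, tuple[float, float]], shape: tuple[int, int]
) -> PairLabelMap:
    """Label every pixel with the unordered pair of its two nearest centers.

    Ties are broken deterministically by ascending cell id: distances are
    sorted with a stable sort on (distance, id).
    """
    if len(centers) < 2:
        raise InsufficientCellsError("need at least 2 cells for pair segmentation")
    ids = np.array(sorted(centers.keys()))
    pts = np.array([centers[i] for i in ids], float)  # (K, 2), ascending id
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    d2 = (yy[..., None] - pts[:, 0]) ** 2 + (xx[..., None] - pts[:, 1]) ** 2
    # stable argsort over the id-ascending axis implements the tie rule
    nearest = np.argsort(d2, axis=-1, kind="stable")[..., :2]
    a = np.minimum(nearest[..., 0], nearest[..., 1])
    b = np.maximum(nearest[..., 0], nearest[..., 1])
    key = a * len(ids) + b
    uniq, index_map = np.unique(key, return_inverse=True)
    pairs = [(int(ids[k // len(ids)]), int(ids[k % len(ids)])) for k in uniq]
    return PairLabelMap(index_map=index_map.reshape(shape).astype(np.int32), pairs=pairs)


def distance_mask(
    centers: dict[int, tuple[float, float]],
    shape: tuple[int, int],
    max_dist_um: float = DEFAULT_MAX_DIST_UM,
    pixel_size: float = 1.0,
) -> np.ndarray:
    """Keep pixels within ``max_dist_um`` of the nearest cell center."""
    if max_dist_um <= 0:
        raise InvalidParameterError("max_dist must be positive")
    if not centers:
        return np.zeros(shape, bool)
    pts = np.array(list(centers.values()), float)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    d2 = (yy[..., None] - pts[:, 0]) ** 2 + (xx[..., None] - pts[:, 1]) ** 2
    return np.sqrt(d2.min(axis=-1)) * pixel_size <= max_dist_um


# ---------------------------------------------------------------------------
# Track extraction and statistics
# ---------------------------------------------------------------------------

def extract_junctions(
    threshold_masks: Sequence[np.ndarray],
    pair_maps: Sequence[PairLabelMap],
    distance_masks: Sequence[np.ndarray],
    images: Sequence[np.ndarray] | None = None,
    min_area: int = DEFAULT_MIN_AREA,
    frame_interval: float = 1.0,
    flagged_ids: set[int] | None = None,
    exclude_border: bool = True,
) -> list[JunctionTrack]:
    """Combine the masks into identity-preserving junction tracks.

    Per frame, the pixels of junction ``{a, b}`` are the suprathreshold
    pixels inside the distance gate whose pair label is ``{a, b}``.  A pair
    becomes a track once it holds at least ``min_area`` pixels in some
    frame; its identity is the pair key, so spatial or temporal gaps never
    split a track.  Tracks touching the border or involving flagged cells
    are marked excluded (the automated stand-in for manual curation).
    """
    n = len(threshold_masks)
    if not (len(pair_maps) == len(distance_masks) == n):
        raise InvalidParameterError("mask sequences must have equal length")
    flagged_ids = flagged_ids or set()
    shape = np.asarray(threshold_masks[0]).shape

    per_pair_pixels: dict[tuple[int, int], list[np.ndarray]] = {}
    empty = np.empty((0, 2), int)
    for f in range(n):
        valid = np.asarray(threshold_masks[f], bool) & np.asarray(distance_masks[f], bool)
        idx = pair_maps[f].index_map
        sel = valid & (idx >= 0)
        rows, cols = np.nonzero(sel)
        keys = idx[rows, cols]
        order = np.argsort(keys, kind="stable")
        rows, cols, keys = rows[order], cols[order], keys[order]
        bounds = np.searchsorted(keys, np.arange(len(pair_maps[f].pairs) + 1))
        for k, pair in enumerate(pair_maps[f].pairs):
            lo, hi = bounds[k], bounds[k + 1]
            if hi <= lo:
                continue
            px = np.stack([rows[lo:hi], cols[lo:hi]], axis=1)
            per_pair_pixels.setdefault(pair, [empty] * f if f else []).append(px)
        for pair, lst in per_pair_pixels.items():
            while len(lst) < f + 1:
                lst.append(empty)

    tracks: list[JunctionTrack] = []
    for pair, px_list in sorted(per_pair_pixels.items()):
        while len(px_list) < n:
            px_list.append(empty)
        counts = np.array([p.shape[0] for p in px_list])
        if counts.max() < min_area:
            continue
        mean_int = np.full(n, np.nan)
        if images is not None:
            for f, px in enumerate(px_list):
                if px.shape[0]:
                    mean_int[f] = float(np.asarray(images[f])[px[:, 0], px[:, 1]].mean())
        track = JunctionTrack(
            junction_id=pair,
            pixels=px_list,
            mean_intensity=mean_int,
            frame_interval=frame_interval,
            min_area=min_area,
        )
        if pair[0] in flagged_ids or pair[1] in flagged_ids:
            track.excluded, track.exclusion_reason = True, "merged-cell pair"
        elif exclude_border:
            for px in px_list:
                if px.shape[0] and (
                    px[:, 0].min() == 0
                    or px[:, 1].min() == 0
                    or px[:, 0].max() == shape[0] - 1
                    or px[:, 1].max() == shape[1] - 1
                ):
                    track.excluded, track.exclusion_reason = True, "touches border"
                    break
        tracks.append(track)
    return tracks


def assembly_curve(tracks: Sequence[JunctionTrack], n_frames: int | None = None) -> np.ndarray:
    """Number of present (non-excluded) junctions per frame."""
    live = [t for t in tracks if not t.excluded]
    if not live:
        return np.zeros(n_frames or 0, int)
    n = n_frames or live[0].n_frames
    counts = np.zeros(n, int)
    for t in live:
        counts += t.presence[:n].astype(int)
    return counts


def junction_lifetime(
    track: JunctionTrack, window_start: float, window_end: float
) -> float:
    """Percent of window frames in which the junction is present."""
    times = track.frame_times()
    sel = (times >= window_start) & (times <= window_end)
    if not sel.any():
        raise InvalidParameterError("window selects no frames")
    birth = track.birth_frame
    if birth is None or times[birth] > window_end:
        raise InvalidParameterError("track is not born before window_end")
    return 100.0 * float(track.presence[sel].sum()) / float(sel.sum())


def junction_intensity_trace(
    track: JunctionTrack, images: Sequence[np.ndarray]
) -> IntensityTrace:
    """Per-frame mean intensity over the track's pixels.

    Frames where the junction is absent fall back to the most recent known
    pixel set (holdover), so the trace stays defined through gaps — the
    behaviour needed to follow a junction through its own disassembly.
    """
    n = track.n_frames
    if len(images) != n:
        raise InvalidParameterError("images and track length mismatch")
    if all(px.shape[0] == 0 for px in track.pixels):
        raise DegenerateDataError("track has no pixels in any frame")
    values = np.empty(n)
    last_px = None
    for f in range(n):
        px = track.pixels[f]
        if px.shape[0] == 0:
            px = last_px
        else:
            last_px = px
        if px is None:
            # before first appearance: use the first known pixel set
            px = next(p for p in track.pixels if p.shape[0])
        values[f] = float(np.asarray(images[f])[px[:, 0], px[:, 1]].mean())
    return IntensityTrace(times=track.frame_times(), values=values)


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

def track_movie(
    movie: FrameStack,
    junction_channel: int | str = 0,
    marker_channel: int | str = 1,
    min_area: int = DEFAULT_MIN_AREA,
    max_dist_um: float = DEFAULT_MAX_DIST_UM,
    **segment_kwargs,
) -> tuple[list[JunctionTrack], np.ndarray, CellCenters]:
    """Full tracking pipeline on a two-channel movie.

    Projection of junction and marker channels, pooled-Otsu threshold of
    the junction channel, (x, y, t) watershed of the marker channel,
    two-closest-neighbor pair maps and distance gating, then track
    extraction.  Returns (tracks, per-frame junction counts, cell centers).
    """
    proj = central_projection(movie, junction_channel)
    thr = stack_threshold(proj)
    masks = [threshold_mask(proj[f], min_area=min_area, threshold=thr) for f in range(proj.shape[0])]
    centers = segment_cells_xyt(movie, channel=marker_channel, **segment_kwargs)
    pair_maps, dist_masks = [], []
    for f in range(proj.shape[0]):
        pair_maps.append(two_closest_neighbor_map(centers.frames[f], proj.shape[1:]))
        dist_masks.append(
            distance_mask(centers.frames[f], proj.shape[1:], max_dist_um, movie.pixel_size)
        )
    tracks = extract_junctions(
        masks,
        pair_maps,
        dist_masks,
        images=proj,
        min_area=min_area,
        frame_interval=movie.frame_interval,
        flagged_ids=centers.flagged_ids,
    )
    return tracks, assembly_curve(tracks, proj.shape[0]), centers
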