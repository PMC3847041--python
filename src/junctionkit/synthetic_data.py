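"""Synthetic microscopy with known ground truth.

Every estimator in the package has a generative counterpart here so that
parameter recovery can be verified end to end without raw microscope data:

* two-cell junction scenes imaged as spectral ("lambda") stacks, with a
  controllable trans-interaction FRET ratio and an acceptor-bleach step;
* ratiometric time series in which the acceptor/donor ratio at the junction
  drops after a chelator event;
* multi-cell assembly movies whose junction birth times follow a
  baseline-then-linear cumulative count;
* disassembly movies whose junction intensity decays exponentially (with an
  optional post-event lag) toward a plateau;
* spheroid aggregation movies whose mask roundness follows a constant
  baseline plus a double-exponential approach to a plateau;
* two-channel cryo-section images (junction lattice + peripheral laminin
  ring), optionally with a hollow core.

Emission spectra are modelled as Gaussians over the detection bands
(donor peak 475 nm, acceptor peak 528 nm, sd 25 nm).  Camera noise is
Gaussian with standard deviation ``noise_sd * signal`` plus a constant
read-noise floor.  All generators are deterministic given their seed.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.draw import ellipse as draw_ellipse
from skimage.morphology import dilation, erosion, disk

from .errors import InvalidParameterError
from .stack_io import FrameStack, SpectralStack

DONOR_PEAK_NM = 475.0
ACCEPTOR_PEAK_NM = 528.0
SPECTRUM_SD_NM = 25.0
BAND_START_NM = 473.0
BAND_WIDTH_NM = 8.7


def default_band_centers(n_bands: int = 12) -> np.ndarray:
    """Detection band centers: 473 nm upward in 8.7 nm steps."""
    return BAND_START_NM + BAND_WIDTH_NM * np.arange(n_bands)


def gaussian_spectrum(band_centers: np.ndarray, peak_nm: float, sd_nm: float = SPECTRUM_SD_NM) -> np.ndarray:
    """Unit-L2 Gaussian emission fingerprint sampled at the band centers."""
    w = np.exp(-0.5 * ((np.asarray(band_centers, float) - peak_nm) / sd_nm) ** 2)
    return w / np.linalg.norm(w)


def _camera_noise(rng: np.random.Generator, clean: np.ndarray, noise_sd: float, read_noise: float) -> np.ndarray:
    if noise_sd == 0 and read_noise == 0:
        return clean
    sd = noise_sd * np.abs(clean) + read_noise
    return clean + rng.normal(0.0, 1.0, clean.shape) * sd


# ---------------------------------------------------------------------------
# FRET scenes (acceptor bleach + ratiometric)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SceneParams:
    """Parameters of a two-cell spectral junction scene.

    ``fret_ratio_true`` is the acceptor-bleach ratio the scene should yield:
    at the junction the donor is quenched to ``(1 - fret_ratio_true)`` of its
    unquenched brightness and the acceptor gains the transferred quanta.
    """

    image_shape: tuple[int, int] = (96, 96)
    pixel_size: float = 0.207  # µm/px
    n_channels_lambda: int = 12
    band_centers: tuple[float, ...] | None = None
    donor_peak: float = DONOR_PEAK_NM
    acceptor_peak: float = ACCEPTOR_PEAK_NM
    fret_ratio_true: float = 0.199
    noise_sd: float = 0.02  # fraction of signal
    read_noise: float = 0.5
    background: float = 2.0  # constant offset in every band
    cell_intensity: float = 60.0
    junction_intensity: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fret_ratio_true < 1.0:
            raise InvalidParameterError("fret_ratio_true must be in [0, 1)")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        bands = self.resolved_band_centers()
        if bands.size < 3:
            raise InvalidParameterError("need at least 3 spectral bands")
        if not np.all(np.diff(bands) > 0):
            raise InvalidParameterError("band_centers must be strictly increasing")

    def resolved_band_centers(self) -> np.ndarray:
        if self.band_centers is not None:
            return np.asarray(self.band_centers, float)
        return default_band_centers(self.n_channels_lambda)


@dataclass
class FretScene:
    """An acceptor-bleach experiment with its ground truth."""

    pre_bleach: SpectralStack
    post_bleach: SpectralStack
    junction_mask: np.ndarray  # bool, junction pixels
    donor_roi: np.ndarray  # bool, pure-donor reference region
    acceptor_roi: np.ndarray  # bool, pure-acceptor reference region
    bleach_roi: np.ndarray  # bool, region bleached at 514 nm
    params: SceneParams


def _scene_geometry(shape: tuple[int, int]) -> dict[str, np.ndarray]:
    """Two abutting rectangular cells with a shared vertical junction."""
    ny, nx = shape
    mid = nx // 2
    masks = {k: np.zeros(shape, bool) for k in ("cell_a", "cell_b", "junction", "donor_roi", "acceptor_roi", "bleach_roi")}
    r0, r1 = ny // 5, ny - ny // 5
    masks["cell_a"][r0:r1, nx // 8 : mid] = True
    masks["cell_b"][r0:r1, mid : nx - nx // 8] = True
    jr0, jr1 = ny * 3 // 10, ny * 7 // 10
    half_w = max(2, nx // 32)
    masks["junction"][jr0:jr1, mid - half_w : mid + half_w] = True
    masks["donor_roi"][r0 + 8 : r1 - 8, nx // 8 + 4 : mid - 3 * half_w] = True
    masks["acceptor_roi"][r0 + 8 : r1 - 8, mid + 3 * half_w : nx - nx // 8 - 4] = True
    masks["bleach_roi"][jr0 - 4 : jr1 + 4, mid - 2 * half_w : mid + 2 * half_w] = True
    return masks


def _render_spectral(
    donor_map: np.ndarray,
    acceptor_map: np.ndarray,
    params: SceneParams,
    rng: np.random.Generator,
) -> SpectralStack:
    bands = params.resolved_band_centers()
    s_d = gaussian_spectrum(bands, params.donor_peak)
    s_a = gaussian_spectrum(bands, params.acceptor_peak)
    clean = (
        donor_map[..., None] * s_d[None, None, :]
        + acceptor_map[..., None] * s_a[None, None, :]
        + params.background
    )
    noisy = _camera_noise(rng, clean, params.noise_sd, params.read_noise)
    return SpectralStack(noisy.astype(np.float64), bands)


def generate_fret_scene(params: SceneParams) -> FretScene:
    """Simulate an acceptor-bleach experiment on a two-cell junction.

    At the junction both fluorophores are enriched; pre-bleach, the donor is
    quenched by the factor ``1 - E`` (``E = fret_ratio_true``) and the
    acceptor receives the transferred intensity.  Post-bleach, the acceptor
    abundance inside the bleach ROI is zeroed and the donor dequenches, so
    the acceptor-bleach estimator recovers ``E`` exactly in the noiseless
    limit.
    """
    geo = _scene_geometry(params.image_shape)
    E = params.fret_ratio_true
    d0 = np.where(geo["cell_a"], params.cell_intensity, 0.0)
    a0 = np.where(geo["cell_b"], params.cell_intensity, 0.0)
    j = geo["junction"]
    d0[j] = params.junction_intensity
    a0[j] = params.junction_intensity

    donor_pre = d0.copy()
    acceptor_pre = a0.copy()
    donor_pre[j] = d0[j] * (1.0 - E)
    acceptor_pre[j] = a0[j] + E * d0[j]

    donor_post = donor_pre.copy()
    acceptor_post = acceptor_pre.copy()
    bleach = geo["bleach_roi"]
    donor_post[bleach & j] = d0[bleach & j]  # dequenched
    acceptor_post[bleach] = 0.0  # acceptor photodestroyed

    rng = np.random.default_rng(params.seed)
    pre = _render_spectral(donor_pre, acceptor_pre, params, rng)
    post = _render_spectral(donor_post, acceptor_post, params, rng)
    return FretScene(
        pre_bleach=pre,
        post_bleach=post,
        junction_mask=j,
        donor_roi=geo["donor_roi"],
        acceptor_roi=geo["acceptor_roi"],
        bleach_roi=bleach,
        params=params,
    )


@dataclass
class RatiometricSeries:
    """A chelator-challenge spectral time series with its ground truth."""

    stacks: list[SpectralStack]
    times: np.ndarray  # same unit as event_time/duration
    junction_mask: np.ndarray
    donor_roi: np.ndarray
    acceptor_roi: np.ndarray
    event_time: float
    fret_before_true: float  # percent of baseline
    fret_after_true: float  # percent of baseline
    params: SceneParams


def generate_ratiometric_series(
    params: SceneParams,
    drop_fraction: float,
    event_time: float,
    duration: float,
    frame_interval: float = 1.0,
    tau_relax: float = 1.5,
) -> RatiometricSeries:
    """Acceptor/donor ratio constant at baseline, relaxing to
    ``(1 - drop_fraction)`` of baseline after the chelator event.

    The relaxation is exponential with time constant ``tau_relax`` so the
    trace is smooth; ground truth ``FRET_after`` refers to the fully relaxed
    level ``100 * (1 - drop_fraction)`` percent.
    """
    if not 0.0 <= drop_fraction <= 1.0:
        raise InvalidParameterError("drop_fraction must be in [0, 1]")
    if not 0.0 < event_time < duration:
        raise InvalidParameterError("event_time must fall inside the series")
    geo = _scene_geometry(params.image_shape)
    j = geo["junction"]
    d_map = np.where(geo["cell_a"], params.cell_intensity, 0.0)
    a_base = np.where(geo["cell_b"], params.cell_intensity, 0.0)
    d_map[j] = params.junction_intensity
    a_base[j] = params.junction_intensity

    times = np.arange(0.0, duration + 1e-9, frame_interval)
    rng = np.random.default_rng(params.seed)
    stacks = []
    for t in times:
        if t <= event_time:
            r = 1.0
        else:
            r = 1.0 - drop_fraction * (1.0 - np.exp(-(t - event_time) / tau_relax))
        a_map = a_base.copy()
        a_map[j] = a_base[j] * r
        stacks.append(_render_spectral(d_map, a_map, params, rng))
    return RatiometricSeries(
        stacks=stacks,
        times=times,
        junction_mask=j,
        donor_roi=geo["donor_roi"],
        acceptor_roi=geo["acceptor_roi"],
        event_time=event_time,
        fret_before_true=100.0,
        fret_after_true=100.0 * (1.0 - drop_fraction),
        params=params,
    )


# ---------------------------------------------------------------------------
# Junction assembly movies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssemblyParams:
    """Conditions of a junction-assembly time lapse.

    Defaults mirror the 2D assembly assay: one frame every 2 minutes for
    2 hours, junction births following a constant baseline followed by
    linear growth at ``rate_true`` junctions/min.
    """

    n_cells: int = 25
    rate_true: float = 0.203  # junctions per minute after the baseline
    baseline_min: float = 15.0
    frame_interval: float = 2.0  # min
    duration: float = 120.0  # min
    presence_fraction: float = 1.0  # per-frame presence after birth
    cell_size_px: int = 20
    margin_px: int = 6
    pixel_size: float = 1.0  # µm/px
    z_planes: int = 2
    background: float = 8.0
    membrane_intensity: float = 20.0
    junction_intensity: float = 160.0
    nucleus_intensity: float = 120.0
    noise_sd: float = 0.02
    read_noise: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate_true < 0:
            raise InvalidParameterError("rate_true must be >= 0")
        if not 0.0 <= self.presence_fraction <= 1.0:
            raise InvalidParameterError("presence_fraction must be in [0, 1]")
        if self.n_cells < 2:
            raise InvalidParameterError("need at least 2 cells")


@dataclass
class JunctionTruth:
    pair: tuple[int, int]  # the two persistent cell ids
    birth_time: float  # min
    birth_frame: int
    presence: np.ndarray  # bool per frame
    pixels: np.ndarray  # (k, 2) row/col of the rendered interface


@dataclass
class AssemblyTruth:
    cell_centers: dict[int, tuple[float, float]]
    junctions: list[JunctionTruth]
    frame_times: np.ndarray

    def counts(self) -> np.ndarray:
        """Ground-truth junction count per frame."""
        n = self.frame_times.size
        out = np.zeros(n, int)
        for j in self.junctions:
            out += j.presence.astype(int)
        return out


def _grid_layout(params: AssemblyParams) -> tuple[dict[int, tuple[float, float]], list[tuple[int, int]], tuple[int, int]]:
    side = int(np.ceil(np.sqrt(params.n_cells)))
    cs, m = params.cell_size_px, params.margin_px
    centers: dict[int, tuple[float, float]] = {}
    grid_pos: dict[int, tuple[int, int]] = {}
    for i in range(params.n_cells):
        r, c = divmod(i, side)
        centers[i] = (m + cs * r + cs / 2.0, m + cs * c + cs / 2.0)
        grid_pos[i] = (r, c)
    pairs = []
    pos_to_id = {v: k for k, v in grid_pos.items()}
    for i, (r, c) in grid_pos.items():
        for dr, dc in ((0, 1), (1, 0)):
            nb = pos_to_id.get((r + dr, c + dc))
            if nb is not None:
                pairs.append((i, nb))
    n_rows = int(np.ceil(params.n_cells / side))
    shape = (2 * m + cs * n_rows, 2 * m + cs * side)
    return centers, pairs, shape


def _interface_pixels(
    a: tuple[float, float], b: tuple[float, float], cell_size: int, shape: tuple[int, int]
) -> np.ndarray:
    """Pixels of a thick stripe along the shared edge between two cells."""
    ay, ax = a
    by, bx = b
    my, mx = (ay + by) / 2.0, (ax + bx) / 2.0
    length = int(round(0.6 * cell_size))
    half_t = 2  # stripe half-thickness in px
    rows, cols = [], []
    if abs(ax - bx) > abs(ay - by):  # vertical interface
        for r in range(int(my) - length // 2, int(my) + length // 2):
            for c in range(int(round(mx)) - half_t, int(round(mx)) + half_t):
                rows.append(r)
                cols.append(c)
    else:  # horizontal interface
        for c in range(int(mx) - length // 2, int(mx) + length // 2):
            for r in range(int(round(my)) - half_t, int(round(my)) + half_t):
                rows.append(r)
                cols.append(c)
    px = np.array([rows, cols]).T
    keep = (px[:, 0] >= 0) & (px[:, 0] < shape[0]) & (px[:, 1] >= 0) & (px[:, 1] < shape[1])
    return px[keep]


def sample_birth_times(params: AssemblyParams, rng: np.random.Generator) -> np.ndarray:
    """Junction birth times: an (inhomogeneous) Poisson draw whose expected
    cumulative count is 0 until ``baseline_min`` and then linear with slope
    ``rate_true`` — a Poisson count of events placed uniformly on the
    growth window."""
    window = params.duration - params.baseline_min
    n_births = rng.poisson(params.rate_true * window)
    return np.sort(rng.uniform(params.baseline_min, params.duration, n_births))


def generate_assembly_movie(params: AssemblyParams) -> tuple[FrameStack, AssemblyTruth]:
    """Render a membrane-labelled field of cells forming junctions.

    Channel 0 is the junction marker (membrane label), channel 1 a nuclear
    stain used to seed the cell tracker.  Births are a Poisson draw whose
    expected cumulative count is zero until ``baseline_min`` and then linear
    with slope ``rate_true``; each birth occupies a distinct adjacent cell
    pair.
    """
    if params.duration < params.baseline_min:
        raise InvalidParameterError("duration must be at least baseline_min")
    rng = np.random.default_rng(params.seed)
    centers, pairs, shape = _grid_layout(params)
    frame_times = np.arange(0.0, params.duration + 1e-9, params.frame_interval)
    n_frames = frame_times.size

    birth_times = sample_birth_times(params, rng)
    order = rng.permutation(len(pairs))
    junctions: list[JunctionTruth] = []
    for k, t_birth in enumerate(birth_times):
        if k >= len(pairs):
            break  # field saturated; extra births are dropped
        pair = pairs[order[k]]
        birth_frame = int(np.searchsorted(frame_times, t_birth))
        presence = np.zeros(n_frames, bool)
        if birth_frame < n_frames:
            if params.presence_fraction >= 1.0:
                presence[birth_frame:] = True
            else:
                presence[birth_frame:] = rng.random(n_frames - birth_frame) < params.presence_fraction
                presence[birth_frame] = True
        px = _interface_pixels(centers[pair[0]], centers[pair[1]], params.cell_size_px, shape)
        junctions.append(JunctionTruth(tuple(sorted(pair)), t_birth, birth_frame, presence, px))

    # static scenery: membrane outlines (inset from tile edges) and nuclei
    membrane = np.zeros(shape)
    nuclei = np.zeros(shape)
    cs = params.cell_size_px
    for (cy, cx) in centers.values():
        r0, r1 = int(cy - cs / 2) + 2, int(cy + cs / 2) - 2
        c0, c1 = int(cx - cs / 2) + 2, int(cx + cs / 2) - 2
        membrane[r0:r1, c0] = params.membrane_intensity
        membrane[r0:r1, c1 - 1] = params.membrane_intensity
        membrane[r0, c0:c1] = params.membrane_intensity
        membrane[r1 - 1, c0:c1] = params.membrane_intensity
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for (cy, cx) in centers.values():
        nuclei += params.nucleus_intensity * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * 3.0**2))

    data = np.empty((n_frames, params.z_planes, 2, *shape), np.float32)
    for f in range(n_frames):
        venus = membrane + params.background
        for j in junctions:
            if j.presence[f]:
                venus[j.pixels[:, 0], j.pixels[:, 1]] = params.junction_intensity
        nuc = nuclei + params.background
        for z in range(params.z_planes):
            data[f, z, 0] = _camera_noise(rng, venus, params.noise_sd, params.read_noise)
            data[f, z, 1] = _camera_noise(rng, nuc, params.noise_sd, params.read_noise)

    movie = FrameStack(
        data,
        frame_interval=params.frame_interval,
        pixel_size=params.pixel_size,
        channel_names=["junction", "nuclei"],
    )
    return movie, AssemblyTruth(centers, junctions, frame_times)


def generate_presence_tracks(
    n_junctions: int,
    presence_fraction: float,
    n_frames: int = 61,
    frame_interval: float = 2.0,
    pixels_per_junction: int = 36,
    seed: int = 0,
):
    """Synthetic :class:`~junctionkit.junction_tracking.JunctionTrack` objects
    whose per-frame presence is Bernoulli(``presence_fraction``).

    Used to validate the lifetime statistic in isolation from image
    processing; each present frame carries a fixed-size pixel set so the
    tracker's presence rule (pixel count >= min_area) applies unchanged.
    """
    from .junction_tracking import JunctionTrack

    if not 0.0 <= presence_fraction <= 1.0:
        raise InvalidParameterError("presence_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    base_px = np.array([[r, c] for r in range(6) for c in range(pixels_per_junction // 6)])
    tracks = []
    for i in range(n_junctions):
        present = rng.random(n_frames) < presence_fraction
        present[0] = True  # born at frame 0
        pixels = [base_px if p else np.empty((0, 2), int) for p in present]
        tracks.append(
            JunctionTrack(
                junction_id=(i, i + n_junctions),
                pixels=pixels,
                mean_intensity=np.full(n_frames, np.nan),
                frame_interval=frame_interval,
            )
        )
    return tracks


# ---------------------------------------------------------------------------
# Junction disassembly movies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DisassemblyParams:
    """Conditions of a chelator-induced junction disassembly time lapse.

    Defaults mirror the disassembly assay: one frame every 5 minutes,
    a 15 minute baseline before the chelator event, then exponential decay
    of junction intensity toward ``plateau_fraction`` of baseline.
    """

    tau_true: float = 2.63  # min
    lag_true: float = 0.0  # min of constant intensity after the event
    event_time: float = 15.0  # min
    plateau_fraction: float = 0.9
    frame_interval: float = 5.0  # min
    duration: float = 75.0  # min
    image_shape: tuple[int, int] = (64, 64)
    cell_size_px: int = 24
    pixel_size: float = 0.5
    z_planes: int = 2
    background: float = 8.0
    membrane_intensity: float = 20.0
    junction_intensity: float = 160.0
    nucleus_intensity: float = 120.0
    noise_sd: float = 0.02
    read_noise: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau_true <= 0:
            raise InvalidParameterError("tau_true must be positive")
        if self.lag_true < 0:
            raise InvalidParameterError("lag_true must be >= 0")
        if not 0.0 <= self.plateau_fraction <= 1.0:
            raise InvalidParameterError("plateau_fraction must be in [0, 1]")


def disassembly_intensity(times: np.ndarray, params: DisassemblyParams) -> np.ndarray:
    """Closed-form junction intensity: constant until ``event + lag``, then
    ``I_plateau + (I0 - I_plateau) * exp(-(t - t0 - lag)/tau)``.
    """
    t = np.asarray(times, float)
    i0 = params.junction_intensity
    i_inf = params.plateau_fraction * i0
    t_start = params.event_time + params.lag_true
    out = np.full(t.shape, i0, float)
    late = t > t_start
    out[late] = i_inf + (i0 - i_inf) * np.exp(-(t[late] - t_start) / params.tau_true)
    return out


@dataclass
class DisassemblyTruth:
    junction_mask: np.ndarray
    trace: np.ndarray  # noiseless closed-form junction intensity per frame
    frame_times: np.ndarray
    event_time: float
    params: DisassemblyParams


def generate_disassembly_movie(params: DisassemblyParams) -> tuple[FrameStack, DisassemblyTruth]:
    """Two pre-established cells whose shared junction decays after the event."""
    rng = np.random.default_rng(params.seed)
    shape = params.image_shape
    cy, half = shape[0] // 2, params.cell_size_px // 2
    mid = shape[1] // 2
    centers = {0: (float(cy), float(mid - half)), 1: (float(cy), float(mid + half))}
    px = _interface_pixels(centers[0], centers[1], params.cell_size_px, shape)
    jmask = np.zeros(shape, bool)
    jmask[px[:, 0], px[:, 1]] = True

    membrane = np.zeros(shape)
    nuclei = np.zeros(shape)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for (ccy, ccx) in centers.values():
        r0, r1 = int(ccy - half) + 2, int(ccy + half) - 2
        c0, c1 = int(ccx - half) + 2, int(ccx + half) - 2
        membrane[r0:r1, [c0, c1 - 1]] = params.membrane_intensity
        membrane[[r0, r1 - 1], c0:c1] = params.membrane_intensity
        nuclei += params.nucleus_intensity * np.exp(-((yy - ccy) ** 2 + (xx - ccx) ** 2) / (2 * 3.0**2))

    frame_times = np.arange(0.0, params.duration + 1e-9, params.frame_interval)
    trace = disassembly_intensity(frame_times, params)
    # float64: the noiseless rendering must match the closed form to 1e-9
    data = np.empty((frame_times.size, params.z_planes, 2, *shape), np.float64)
    for f in range(frame_times.size):
        venus = membrane + params.background
        venus[jmask] = trace[f]
        nuc = nuclei + params.background
        for z in range(params.z_planes):
            data[f, z, 0] = _camera_noise(rng, venus, params.noise_sd, params.read_noise)
            data[f, z, 1] = _camera_noise(rng, nuc, params.noise_sd, params.read_noise)
    movie = FrameStack(
        data,
        frame_interval=params.frame_interval,
        pixel_size=params.pixel_size,
        channel_names=["junction", "nuclei"],
    )
    return movie, DisassemblyTruth(jmask, trace, frame_times, params.event_time, params)


# ---------------------------------------------------------------------------
# Spheroid movies
# ---------------------------------------------------------------------------

def ca_roundness_plateau(
    ca_ext_mM: float,
    r_lo: float = 0.012,
    r_hi: float = 0.623,
    ca50: float = 0.029,
    slope: float = 0.25,
) -> float:
    """Declared logistic map from external Ca2+ (mM) to the roundness plateau.

    The default constants were fit once to the wild-type dose-response
    levels in the fixture registry and are stored there as well.
    """
    return r_lo + (r_hi - r_lo) / (1.0 + np.exp(-(ca_ext_mM - ca50) / slope))


@dataclass(frozen=True)
class SpheroidParams:
    """Conditions of a spheroid-compaction time lapse.

    Roundness follows a constant baseline ``roundness_start`` for
    ``baseline_h`` hours and then relaxes to ``roundness_plateau`` as a sum
    of a fast and a slow exponential.  If ``ca_ext`` is given, the plateau
    is taken from the declared logistic dose map instead.
    """

    roundness_start: float = 0.30
    roundness_plateau: float = 0.68
    tau_fast: float = 0.5  # h
    tau_slow: float = 20.0  # h
    fast_fraction: float = 0.68  # share of the total amplitude on tau_fast
    baseline_h: float = 2.0
    ca_ext: float | None = None  # mM; overrides roundness_plateau when set
    frame_interval: float = 5.0  # min
    duration_h: float = 48.0
    image_shape: tuple[int, int] = (160, 160)
    equiv_radius_px: float = 30.0
    pixel_size: float = 2.0  # µm/px
    intensity: float = 150.0
    background: float = 10.0
    noise_sd: float = 0.02
    read_noise: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for v, name in ((self.roundness_start, "roundness_start"), (self.effective_plateau(), "roundness_plateau")):
            if not 0.0 < v <= 1.0:
                raise InvalidParameterError(f"{name} must be in (0, 1], got {v}")
        if self.tau_fast >= self.tau_slow:
            raise InvalidParameterError("tau_fast must be smaller than tau_slow")
        if not 0.0 <= self.fast_fraction <= 1.0:
            raise InvalidParameterError("fast_fraction must be in [0, 1]")

    def effective_plateau(self) -> float:
        if self.ca_ext is not None:
            return float(ca_roundness_plateau(self.ca_ext))
        return self.roundness_plateau


def spheroid_roundness_truth(times_h: np.ndarray, params: SpheroidParams) -> np.ndarray:
    """Closed-form roundness trajectory (baseline + double exponential)."""
    t = np.asarray(times_h, float)
    r0 = params.roundness_start
    r_inf = params.effective_plateau()
    amp = r_inf - r0
    a_f = params.fast_fraction * amp
    a_s = amp - a_f
    out = np.full(t.shape, r0, float)
    late = t > params.baseline_h
    dt = t[late] - params.baseline_h
    out[late] = r_inf - a_f * np.exp(-dt / params.tau_fast) - a_s * np.exp(-dt / params.tau_slow)
    return out


@dataclass
class SpheroidTruth:
    frame_times_h: np.ndarray
    roundness: np.ndarray
    params: SpheroidParams


def generate_spheroid_movie(params: SpheroidParams) -> tuple[FrameStack, SpheroidTruth]:
    """Bright-on-dark aggregate rendered as an ellipse of fixed area whose
    axis ratio equals the target roundness at every frame.

    Under the moment-ellipse roundness definition (4A / pi a^2) an ellipse
    with semi-axes (a, b) has roundness b/a, so axis ratio is the exact
    control variable for the trajectory.
    """
    frame_times_h = np.arange(0.0, params.duration_h + 1e-9, params.frame_interval / 60.0)
    target = spheroid_roundness_truth(frame_times_h, params)
    rng = np.random.default_rng(params.seed)
    theta = rng.uniform(0, np.pi)
    cy, cx = params.image_shape[0] / 2.0, params.image_shape[1] / 2.0
    data = np.empty((frame_times_h.size, 1, 1, *params.image_shape), np.float32)
    for f, r in enumerate(target):
        a = params.equiv_radius_px / np.sqrt(r)
        b = params.equiv_radius_px * np.sqrt(r)
        frame = np.full(params.image_shape, params.background)
        rr, cc = draw_ellipse(cy, cx, b, a, shape=params.image_shape, rotation=theta)
        frame[rr, cc] = params.intensity
        data[f, 0, 0] = _camera_noise(rng, frame, params.noise_sd, params.read_noise)
    movie = FrameStack(
        data,
        frame_interval=params.frame_interval,
        pixel_size=params.pixel_size,
        channel_names=["transmitted"],
    )
    return movie, SpheroidTruth(frame_times_h, target, params)


# ---------------------------------------------------------------------------
# Cryo-section images
# ---------------------------------------------------------------------------

@dataclass
class SectionTruth:
    section_mask: np.ndarray  # actual tissue pixels (annulus when hollow)
    filled_mask: np.ndarray
    laminin_ring: np.ndarray
    laminin_level: float
    hollow: bool


def generate_section_image(
    hollow: bool,
    laminin_level: float,
    seed: int = 0,
    image_shape: tuple[int, int] = (200, 200),
    section_radius_px: int = 72,
    hole_radius_px: int = 52,
    ring_halfwidth_px: int = 3,
    lattice_spacing_px: int = 12,
    fill_intensity: float = 20.0,
    lattice_intensity: float = 120.0,
    background: float = 5.0,
    noise_sd: float = 0.0,
    read_noise: float = 0.0,
) -> tuple[FrameStack, SectionTruth]:
    """Two-channel cryo-section: a junction lattice filling a disk (annulus
    when ``hollow``) and a peripheral laminin ring of mean ``laminin_level``.

    The laminin ring is painted on exactly the morphological boundary band
    (disk dilated minus eroded with radius ``ring_halfwidth_px``) so the
    periphery estimator is exact on noiseless images.
    """
    if laminin_level < 0:
        raise InvalidParameterError("laminin_level must be >= 0")
    ny, nx = image_shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = ny / 2.0, nx / 2.0
    r2 = (yy - cy) ** 2 + (xx - cx) ** 2
    filled = r2 <= section_radius_px**2
    section = filled & ~(r2 <= hole_radius_px**2) if hollow else filled

    junction = np.full(image_shape, background)
    junction[section] = fill_intensity
    lattice = ((yy % lattice_spacing_px) < 2) | ((xx % lattice_spacing_px) < 2)
    junction[section & lattice] = lattice_intensity

    selem = disk(ring_halfwidth_px)
    ring = dilation(filled, selem) & ~erosion(filled, selem)
    laminin = np.full(image_shape, background)
    laminin[ring] = background + laminin_level

    rng = np.random.default_rng(seed)
    data = np.stack(
        [
            _camera_noise(rng, junction, noise_sd, read_noise),
            _camera_noise(rng, laminin, noise_sd, read_noise),
        ]
    )[np.newaxis, np.newaxis].astype(np.float32)
    image = FrameStack(data, channel_names=["junction", "laminin"])
    return image, SectionTruth(section, filled, ring, laminin_level, hollow)
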