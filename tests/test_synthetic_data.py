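"""Generator-level properties: determinism, parameter validation, and the
closed-form ground truths each generator promises."""
import numpy as np
import pytest

from junctionkit.errors import InvalidParameterError
from junctionkit.synthetic_data import (
    AssemblyParams,
    DisassemblyParams,
    SceneParams,
    SpheroidParams,
    ca_roundness_plateau,
    disassembly_intensity,
    generate_assembly_movie,
    generate_disassembly_movie,
    generate_fret_scene,
    generate_presence_tracks,
    generate_ratiometric_series,
    generate_section_image,
    generate_spheroid_movie,
    sample_birth_times,
    spheroid_roundness_truth,
)
from junctionkit.spheroid_morphometrics import roundness, segment_spheroid


# ---------------------------------------------------------------------------
# determinism
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "make",
    [
        lambda: generate_fret_scene(SceneParams(seed=11)).pre_bleach.data,
        lambda: generate_ratiometric_series(
            SceneParams(image_shape=(48, 48), seed=11), 0.1, 5.0, 12.0
        ).stacks[-1].data,
        lambda: generate_assembly_movie(AssemblyParams(n_cells=9, duration=30.0, seed=11))[0].data,
        lambda: generate_disassembly_movie(DisassemblyParams(duration=30.0, seed=11))[0].data,
        lambda: generate_spheroid_movie(
            SpheroidParams(duration_h=2.0, frame_interval=30.0, seed=11)
        )[0].data,
        lambda: generate_section_image(True, 30.0, seed=11, noise_sd=0.02, read_noise=0.5)[0].data,
    ],
    ids=["fret_scene", "ratiometric", "assembly", "disassembly", "spheroid", "section"],
)
def test_generators_are_bit_deterministic(make):
    assert np.array_equal(make(), make())


# ---------------------------------------------------------------------------
# FRET scenes
# ---------------------------------------------------------------------------

def test_no_fret_scene_has_identical_donor_at_junction():
    from junctionkit.spectral_fret import (
        build_reference_spectrum,
        estimate_background,
        subtract_background,
        unmix,
    )

    scene = generate_fret_scene(SceneParams(fret_ratio_true=0.0, noise_sd=0.0, read_noise=0.0))
    bg = estimate_background(scene.pre_bleach)
    refs = [
        build_reference_spectrum(scene.pre_bleach, scene.donor_roi, "d", bg),
        build_reference_spectrum(scene.pre_bleach, scene.acceptor_roi, "a", bg),
    ]
    pre = unmix(subtract_background(scene.pre_bleach, bg), refs)
    post = unmix(subtract_background(scene.post_bleach, bg), refs)
    j = scene.junction_mask
    assert np.allclose(pre.donor_abundance[j], post.donor_abundance[j], atol=1e-9)


@pytest.mark.parametrize("bad", [dict(fret_ratio_true=1.0), dict(fret_ratio_true=-0.1),
                                 dict(n_channels_lambda=2), dict(noise_sd=-1.0)])
def test_scene_params_validation(bad):
    with pytest.raises(InvalidParameterError):
        SceneParams(**bad)


# ---------------------------------------------------------------------------
# ratiometric series
# ---------------------------------------------------------------------------

def _junction_ratio(series):
    """Raw acceptor-vs-donor junction signal ratio per frame (band sums)."""
    j = series.junction_mask
    out = []
    for s in series.stacks:
        spec = s.data[j].mean(axis=0)
        out.append(spec)
    return np.array(out)


def test_ratiometric_flat_when_drop_zero():
    p = SceneParams(image_shape=(48, 48), noise_sd=0.0, read_noise=0.0)
    series = generate_ratiometric_series(p, 0.0, 5.0, 12.0)
    spectra = _junction_ratio(series)
    assert np.allclose(spectra, spectra[0])
    assert series.fret_after_true == 100.0


def test_ratiometric_full_drop_removes_acceptor():
    p = SceneParams(image_shape=(48, 48), noise_sd=0.0, read_noise=0.0)
    series = generate_ratiometric_series(p, 1.0, 2.0, 40.0, tau_relax=0.5)
    j = series.junction_mask
    acceptor_band = np.argmin(np.abs(series.stacks[0].band_centers - 528.0))
    donor_band = 0
    last = series.stacks[-1].data[j].mean(axis=0)
    first = series.stacks[0].data[j].mean(axis=0)
    # the acceptor-dominated band collapses while the donor band persists
    assert last[acceptor_band] < 0.35 * first[acceptor_band]
    assert last[donor_band] > 0.8 * first[donor_band]
    assert series.fret_after_true == 0.0


def test_ratiometric_event_outside_series_rejected():
    p = SceneParams(image_shape=(48, 48))
    with pytest.raises(InvalidParameterError):
        generate_ratiometric_series(p, 0.1, 50.0, 12.0)


# ---------------------------------------------------------------------------
# assembly movies
# ---------------------------------------------------------------------------

def test_zero_rate_produces_no_junctions():
    _, truth = generate_assembly_movie(AssemblyParams(rate_true=0.0, n_cells=9, duration=40.0, seed=3))
    assert truth.junctions == []
    assert truth.counts().sum() == 0


def test_full_presence_after_birth():
    _, truth = generate_assembly_movie(
        AssemblyParams(rate_true=0.2, n_cells=16, duration=60.0, presence_fraction=1.0, seed=4)
    )
    assert truth.junctions
    for j in truth.junctions:
        assert j.presence[j.birth_frame :].all()
        assert not j.presence[: j.birth_frame].any()


def test_duration_shorter_than_baseline_rejected():
    with pytest.raises(InvalidParameterError):
        generate_assembly_movie(AssemblyParams(baseline_min=30.0, duration=20.0))


def test_birth_process_mean_slope_matches_rate():
    """Law of large numbers on the birth process: the mean cumulative count
    over many replicate fields grows linearly at rate_true after baseline."""
    params = AssemblyParams(rate_true=0.203, baseline_min=15.0, duration=120.0)
    times = np.arange(0.0, 121.0, 2.0)
    counts = np.zeros(times.size)
    n_rep = 500
    rng = np.random.default_rng(99)
    for _ in range(n_rep):
        births = sample_birth_times(params, rng)
        counts += np.searchsorted(births, times, side="right")
    mean_counts = counts / n_rep
    late = times > 20.0
    slope = np.polyfit(times[late], mean_counts[late], 1)[0]
    assert slope == pytest.approx(0.203, rel=0.05)
    assert mean_counts[times <= 15.0].max() == 0.0


# ---------------------------------------------------------------------------
# disassembly movies
# ---------------------------------------------------------------------------

def test_noiseless_disassembly_matches_closed_form():
    p = DisassemblyParams(tau_true=2.63, lag_true=0.0, noise_sd=0.0, read_noise=0.0)
    movie, truth = generate_disassembly_movie(p)
    j = truth.junction_mask
    measured = movie.data[:, 0, 0][:, j].mean(axis=1)
    expected = disassembly_intensity(truth.frame_times, p)
    assert np.allclose(measured, expected, rtol=1e-9)


def test_disassembly_lag_holds_intensity_constant():
    p = DisassemblyParams(tau_true=7.28, lag_true=10.0, event_time=15.0, noise_sd=0.0, read_noise=0.0)
    vals = disassembly_intensity(np.array([0.0, 15.0, 20.0, 25.0, 30.0]), p)
    assert vals[0] == vals[1] == vals[2] == vals[3]  # constant through event+lag
    assert vals[4] < vals[3]


def test_disassembly_plateau_one_is_flat():
    p = DisassemblyParams(plateau_fraction=1.0, noise_sd=0.0, read_noise=0.0)
    vals = disassembly_intensity(np.arange(0.0, 75.0, 5.0), p)
    assert np.allclose(vals, vals[0])


def test_disassembly_requires_positive_tau():
    with pytest.raises(InvalidParameterError):
        DisassemblyParams(tau_true=0.0)


# ---------------------------------------------------------------------------
# spheroid movies
# ---------------------------------------------------------------------------

def test_spheroid_flat_truth_when_start_equals_plateau():
    p = SpheroidParams(roundness_start=0.5, roundness_plateau=0.5)
    t = np.linspace(0, 48, 97)
    assert np.allclose(spheroid_roundness_truth(t, p), 0.5)


def test_spheroid_truth_monotone_after_baseline():
    p = SpheroidParams()
    t = np.linspace(0, 48, 577)
    r = spheroid_roundness_truth(t, p)
    assert np.all(np.diff(r[t >= p.baseline_h]) >= -1e-12)


def test_spheroid_measured_roundness_tracks_truth():
    p = SpheroidParams(duration_h=6.0, frame_interval=30.0, noise_sd=0.0, read_noise=0.0, seed=2)
    movie, truth = generate_spheroid_movie(p)
    for f in range(movie.n_frames):
        mask = segment_spheroid(movie.data[f, 0, 0])
        assert roundness(mask) == pytest.approx(truth.roundness[f], abs=0.02)


def test_ca_plateau_map_is_monotone():
    assert ca_roundness_plateau(0.0) < ca_roundness_plateau(0.4) < ca_roundness_plateau(2.1)


def test_spheroid_tau_ordering_enforced():
    with pytest.raises(InvalidParameterError):
        SpheroidParams(tau_fast=10.0, tau_slow=5.0)


# ---------------------------------------------------------------------------
# presence tracks and sections
# ---------------------------------------------------------------------------

def test_presence_tracks_have_requested_frequency():
    tracks = generate_presence_tracks(200, 0.75, n_frames=100, seed=5)
    frac = np.mean([t.presence.mean() for t in tracks])
    assert frac == pytest.approx(0.75, abs=0.02)


def test_section_hollow_flag_controls_core():
    solid, ts = generate_section_image(False, 10.0, seed=1)
    hollow, th = generate_section_image(True, 10.0, seed=1)
    assert not ts.hollow and th.hollow
    ny, nx = solid.shape_yx
    center = (slice(ny // 2 - 5, ny // 2 + 5), slice(nx // 2 - 5, nx // 2 + 5))
    assert solid.data[0, 0, 0][center].mean() > 3 * hollow.data[0, 0, 0][center].mean()


def test_section_rejects_negative_laminin():
    with pytest.raises(InvalidParameterError):
        generate_section_image(False, -1.0)
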