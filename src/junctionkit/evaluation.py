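"""Closed-loop parameter-recovery protocols.

Each function generates synthetic fixtures for one assay, runs the full
measurement pipeline on them, and returns the recovered quantity together
with the generating truth.  These protocols are what the acceptance script
and the recovery tests execute; they contain no estimation logic of their
own.

Seeding: every protocol takes a ``base_seed`` and derives one independent
child seed per replicate via :class:`numpy.random.SeedSequence`, so runs
are reproducible and replicates are uncorrelated.
"""
from __future__ import annotations

import numpy as np

from . import fixtures
from .junction_tracking import (
    central_projection,
    junction_intensity_trace,
    junction_lifetime,
    JunctionTrack,
    track_movie,
)
from .kinetics import (
    IntensityTrace,
    fit_baseline_linear,
    fit_exp_decay,
    normalize_to_baseline,
)
from .spectral_fret import measure_scene_fret, measure_series_fret
from .spheroid_morphometrics import ca_dose_summary, roundness_timeseries
from .synthetic_data import (
    AssemblyParams,
    SpheroidParams,
    generate_assembly_movie,
    generate_disassembly_movie,
    generate_fret_scene,
    generate_presence_tracks,
    generate_ratiometric_series,
    generate_spheroid_movie,
)


def child_seeds(base_seed: int, n: int) -> list[int]:
    """n reproducible, independent 31-bit seeds derived from base_seed."""
    ss = np.random.SeedSequence(base_seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


# ---------------------------------------------------------------------------
# FRET
# ---------------------------------------------------------------------------

def bleach_fret_recovery(
    genotype: str = "WT",
    n_scenes: int | None = None,
    noise_sd: float = 0.02,
    base_seed: int = 1,
) -> dict:
    """Mean acceptor-bleach FRET (percent) over synthetic junction scenes.

    Each scene is generated with the genotype's fixture ratio, then pushed
    through reference-spectrum extraction, background subtraction, linear
    unmixing and the donor-dequenching ratio.
    """
    if n_scenes is None:
        n_scenes = int(fixtures.fixture_registry()["bleach_fret"][genotype]["n"])
    values = []
    for seed in child_seeds(base_seed, n_scenes):
        params = fixtures.bleach_scene_params(genotype, noise_sd=noise_sd, seed=seed)
        scene = generate_fret_scene(params)
        values.append(100.0 * measure_scene_fret(scene).fret_ratio)
    values = np.asarray(values)
    return {
        "mean_percent": float(values.mean()),
        "sd_percent": float(values.std(ddof=1)),
        "truth_percent": 100.0 * float(fixtures.bleach_scene_params(genotype).fret_ratio_true),
        "n": n_scenes,
    }


def ratiometric_recovery(
    genotype: str = "WT",
    n_series: int = 8,
    event_time: float = 12.0,
    duration: float = 35.0,
    noise_sd: float = 0.02,
    base_seed: int = 1,
) -> dict:
    """Mean post-chelation FRET level (percent of baseline) over synthetic
    junction series generated with the genotype's fixture drop."""
    drop = fixtures.ratiometric_drop(genotype)
    after = []
    for seed in child_seeds(base_seed, n_series):
        params = fixtures.bleach_scene_params(genotype, noise_sd=noise_sd, seed=seed)
        series = generate_ratiometric_series(params, drop, event_time, duration)
        after.append(measure_series_fret(series).fret_after)
    after = np.asarray(after)
    return {
        "mean_percent": float(after.mean()),
        "sd_percent": float(after.std(ddof=1)),
        "truth_percent": 100.0 * (1.0 - drop),
        "n": n_series,
    }


# ---------------------------------------------------------------------------
# Disassembly kinetics
# ---------------------------------------------------------------------------

def disassembly_tau_recovery(
    genotype: str = "WT",
    n_traces: int = 50,
    noise_sd: float = 0.02,
    base_seed: int = 1,
) -> dict:
    """Mean fitted decay constant over synthetic disassembly movies.

    Traces are junction-mean intensities extracted from rendered movies
    (per-pixel camera noise), normalised to the pre-event baseline and
    fitted from ``event + lag`` onward, mirroring the lag rule used for the
    genotype that holds its intensity for 10 min after chelation.
    """
    taus = []
    for seed in child_seeds(base_seed, n_traces):
        params = fixtures.disassembly_params(genotype, noise_sd=noise_sd, seed=seed)
        movie, truth = generate_disassembly_movie(params)
        track = JunctionTrack(
            junction_id=(0, 1),
            pixels=[np.argwhere(truth.junction_mask)] * movie.n_frames,
            mean_intensity=np.full(movie.n_frames, np.nan),
            frame_interval=params.frame_interval,
        )
        trace = junction_intensity_trace(track, central_projection(movie))
        trace = IntensityTrace(trace.times, trace.values, event_time=params.event_time)
        trace = normalize_to_baseline(trace)
        fit = fit_exp_decay(trace, fit_start=params.event_time + params.lag_true)
        if fit.converged:
            taus.append(fit.params["tau"])
    taus = np.asarray(taus)
    params = fixtures.disassembly_params(genotype)
    return {
        "mean_tau_min": float(taus.mean()),
        "sd_tau_min": float(taus.std(ddof=1)),
        "truth_tau_min": params.tau_true,
        "n_converged": int(taus.size),
        "n": n_traces,
    }


# ---------------------------------------------------------------------------
# Assembly rate and lifetime
# ---------------------------------------------------------------------------

def assembly_rate_recovery(
    genotype: str = "WT",
    n_fov: int = 200,
    noise_sd: float = 0.02,
    base_seed: int = 1,
) -> dict:
    """Assembly rate recovered by the full tracker over many fields of view.

    Every movie runs through projection, pooled-Otsu thresholding, (x,y,t)
    watershed, two-closest-neighbor pair maps, distance gating and track
    extraction; the per-frame junction counts are averaged over fields and
    fitted with the baseline-plus-linear model.
    """
    rate = fixtures.assembly_rate(genotype)
    curves = []
    frame_times = None
    for seed in child_seeds(base_seed, n_fov):
        params = AssemblyParams(rate_true=rate, noise_sd=noise_sd, seed=seed)
        movie, truth = generate_assembly_movie(params)
        _, counts, _ = track_movie(movie)
        curves.append(counts)
        frame_times = truth.frame_times
    mean_curve = np.mean(curves, axis=0)
    fit = fit_baseline_linear(IntensityTrace(frame_times, mean_curve))
    return {
        "slope_per_min": float(fit.params["slope"]),
        "breakpoint_min": float(fit.params["breakpoint"]),
        "truth_rate_per_min": rate,
        "n_fov": n_fov,
    }


def lifetime_recovery(
    genotype: str = "WT",
    n_junctions: int = 50,
    window: tuple[float, float] = (60.0, 120.0),
    base_seed: int = 1,
) -> dict:
    """Mean junction lifetime (percent presence in the window) on synthetic
    tracks drawn with the genotype's fixture presence fraction."""
    p = fixtures.presence_fraction(genotype)
    tracks = generate_presence_tracks(
        n_junctions, p, n_frames=61, frame_interval=2.0, seed=child_seeds(base_seed, 1)[0]
    )
    lifetimes = [junction_lifetime(t, *window) for t in tracks]
    return {
        "mean_percent": float(np.mean(lifetimes)),
        "sd_percent": float(np.std(lifetimes, ddof=1)),
        "truth_percent": 100.0 * p,
        "n": n_junctions,
    }


# ---------------------------------------------------------------------------
# Spheroids
# ---------------------------------------------------------------------------

def spheroid_roundness_recovery(
    genotype: str = "WT",
    n_movies: int = 10,
    noise_sd: float = 0.02,
    base_seed: int = 1,
    frame_interval: float = 5.0,
) -> dict:
    """Mean measured roundness at the final (48 h) frame of synthetic
    spheroid movies generated with the genotype's fixture plateau."""
    finals = []
    for seed in child_seeds(base_seed, n_movies):
        params = fixtures.spheroid_params(
            genotype, noise_sd=noise_sd, seed=seed, frame_interval=frame_interval
        )
        movie, truth = generate_spheroid_movie(params)
        trace = roundness_timeseries(movie)
        finals.append(trace.values[-1])
    finals = np.asarray(finals)
    params = fixtures.spheroid_params(genotype)
    return {
        "mean_roundness": float(finals.mean()),
        "sd_roundness": float(finals.std(ddof=1)),
        "truth_plateau": params.roundness_plateau,
        "n": n_movies,
    }


def ca_dose_curve(
    doses_mM: tuple[float, ...] = (0.0, 0.4, 0.8),
    n_per_dose: int = 4,
    t_query_h: float = 20.0,
    noise_sd: float = 0.02,
    base_seed: int = 1,
    frame_interval: float = 15.0,
    duration_h: float = 24.0,
) -> dict:
    """Measured 20 h roundness per Ca2+ concentration via the dose map."""
    seeds = iter(child_seeds(base_seed, n_per_dose * len(doses_mM)))
    movies = {}
    for ca in doses_mM:
        movies[ca] = [
            generate_spheroid_movie(
                SpheroidParams(
                    ca_ext=ca,
                    roundness_start=0.25,
                    # dose fixtures equilibrate well before the 20 h readout
                    tau_fast=0.5,
                    tau_slow=4.0,
                    noise_sd=noise_sd,
                    seed=next(seeds),
                    frame_interval=frame_interval,
                    duration_h=duration_h,
                )
            )[0]
            for _ in range(n_per_dose)
        ]
    table = ca_dose_summary(movies, t_query_h=t_query_h)
    return {
        "doses_mM": list(table["ca_ext_mM"]),
        "mean_roundness": [float(v) for v in table["mean_roundness"]],
        "n_per_dose": n_per_dose,
    }
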