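# Methods

`junctionkit` quantifies live-cell experiments on cadherin-mediated
adherens junctions: spectral-unmixing FRET between N-cadherin fusion
constructs across a junction, time-lapse detection and identity-preserving
tracking of junctions in 2D cultures, kinetic fits of junction assembly and
chelator-induced disassembly, and morphometrics of 3D spheroid formation.
Because raw microscope data for such experiments is rarely shareable, every
estimator ships with a generative counterpart (`synthetic_data`) whose
ground truth the estimator must recover; all quantitative claims made by the
test suite are closed-loop parameter-recovery statements about these
synthetic study conditions, not about any particular instrument.

## Spectral FRET

**Model.** Emission is detected in 12 wavelength bands from 473 nm upward in
8.7 nm steps. Per-pixel spectra are modelled as non-negative mixtures of two
reference fingerprints (donor ~ Cerulean, peak 475 nm; acceptor ~ Venus,
peak 528 nm; both rendered as Gaussians with 25 nm spectral sd in the
generator — the simplest shape that preserves the difficulty of unmixing
two strongly overlapping emitters).

**Unmixing.** Reference fingerprints are L2-normalised background-subtracted
mean ROI spectra from single-fluorophore regions. Abundances are estimated
per pixel by non-negative least squares (abundances are physical
intensities; unconstrained least squares can go negative in dim pixels).
The implementation solves the unconstrained problem vectorised and falls
back to the active-set solver only where a constraint binds — the two
coincide whenever the unconstrained solution is feasible. Spectra with a
condition number above 1e6 are rejected as collinear. Background is the
per-band mode of the dimmest 10 % of pixels (by total intensity), estimated
with a 64-bin histogram.

**Acceptor-bleach estimator.** After photobleaching the acceptor inside a
junction ROI, donor dequenching gives the FRET ratio

    FRET = (I_postDonor − I_preDonor) / I_postDonor

on mean unmixed donor abundances over the junction mask. A bleach guard
requires the acceptor abundance in the bleach ROI to drop by at least 50 %
(the bleaching protocol is saturating; the guard catches failed bleaches
and degraded data). The scene generator quenches the junction donor by the
target ratio and adds the transferred quanta to the acceptor, so the
noiseless pipeline is exact by construction; with 2 % signal noise the
junction average (~700 px) keeps per-scene error well below a percentage
point.

**Ratiometric estimator.** The acceptor/donor abundance ratio over the
junction is normalised so the pre-event baseline averages 100 %.
`fret_before` is the mean over all pre-event frames; `fret_after` the mean
over the last 25 % of the series (both windows configurable — the published
single before/after numbers do not state their windows, and the late-window
choice reads the relaxed level rather than the transient). Frames with a
non-positive donor mean are flagged and excluded.

## Junction tracking

The pipeline identifies junctions as *cell-pair interfaces* so identity is
carried by the pair key, not by frame-to-frame mask overlap:

1. **Projection** — per frame, maximum-intensity projection of the two
   central z-planes.
2. **Threshold** — Otsu with removal of components below `min_area`
   (default 5 px). `threshold_mask` applies Otsu per frame when called
   alone; the `track_movie` pipeline instead pools the histogram over the
   whole movie (`stack_threshold`) and applies that single threshold to
   every frame. Early frames of an assembly movie contain no junction
   signal, and a per-frame Otsu would then split background noise and flood
   the frame; pooling keeps the threshold anchored to the junction/
   background contrast that exists somewhere in the series. A movie with no
   junction signal anywhere remains degenerate by construction — the
   threshold then falls between background and membrane, which is the
   documented limit of automatic thresholding without a calibration frame.
3. **Cell identity** — the marker channel (nuclei when available, as in the
   disassembly assay) is smoothed and thresholded as an (x, y, t) volume
   with the time axis scaled by a configurable anisotropy factor (default
   1 px per frame interval). Seeds are the connected components of the
   marker volume that carry h-maxima of the time-scaled Euclidean distance
   transform (depth 1 px): the maxima locate cells, and the connected tube
   keeps a cell that drifts a few px/frame on a single seed. The inverted
   distance map is flooded by a 3D watershed, tiling every frame into
   basins whose label — the persistent cell id — survives the whole movie.
   Cells whose in-frame footprint is multi-component (merged basins) are
   flagged and their junctions excluded. Touching cells that never separate
   are a known limitation: they enter as one id.
4. **Pair map** — each pixel is labelled with the unordered pair of its two
   nearest cell centers (centers are per-frame marker centroids). Ties are
   broken by ascending cell id. A distance gate keeps pixels within
   `max_dist` (default 30 µm) of the nearest center.
5. **Track extraction** — junction pixels of pair {a,b} in a frame are the
   suprathreshold, gated pixels labelled {a,b}; presence requires at least
   `min_area` pixels. Because identity is the pair key, spatial or temporal
   gaps never split a track. Tracks touching the image border or involving
   flagged cells are marked excluded — the automated stand-in for the
   manual curation such pipelines otherwise need.

**Statistics.** The assembly curve counts present tracks per frame; the
lifetime of a track is the percentage of frames present within an
observation window (60–120 min by default); intensity traces take the mean
over the track's pixels, holding over the last known pixel set through
absences so a disassembling junction can be followed to its plateau.

## Kinetic models

* **Assembly** — constant baseline then linear growth,
  `f(t) = b` for `t ≤ t0`, `b + m (t − t0)` after; `m` is the assembly rate
  (junctions/min). The breakpoint is profiled by exhaustive search over the
  sample times with a closed-form conditional fit of `(b, m)`; profiling is
  robust where joint gradient fitting of a kink is not, and on ≤100-point
  traces it is exact by construction.
* **Disassembly** — `I(t) = I∞ + A exp(−(t − t_start)/τ)` fitted from
  `fit_start` onward, default the chelator-addition time. Genotypes whose
  decay begins late use `fit_start = event + lag` (the registry stores a
  10-min lag for the X-dimer-deficient mutant). Multi-start initialisation
  over τ ∈ {1, 5, 20, 80} × sampling interval with best-RSS selection;
  flat or rising traces are reported unconverged rather than fitted.
* **Spheroid compaction** — constant baseline then
  `R∞ − A_f exp(−Δt/τ_fast) − A_s exp(−Δt/τ_slow)` fitted to roundness up
  to 20 h; τ_fast is the reported formation constant. Amplitude continuity
  at the breakpoint is built into the parametrisation, τ_slow is
  parametrised as τ_fast × ratio (ratio ≥ 1), and fits with a ratio below
  1.05 are flagged unidentifiable.

All fits are equivariant under affine rescaling of the value axis up to the
corresponding parameter transformation (checked by property tests).

## Spheroid morphometrics and cryo-sections

**Roundness** is the moment-ellipse descriptor `4·Area/(π·major_axis²)`
(1 for a disk, b/a for an ellipse), clipped to [0, 1]; circularity
(`4πA/P²`) is available as an alternative. The published analysis names
"roundness" without a formula; comparisons between genotypes are robust to
the choice, and absolute values are calibrated through the fixtures.
Spheroids are segmented by Otsu thresholding with a contrast gate
(foreground/background separation must exceed 4× the within-class spread —
pure-noise frames fail it), morphological closing, hole filling, and
largest-component selection; the published pipeline used a trained pixel
classifier here, which this deterministic segmenter replaces since
downstream metrics depend only on the mask. Failed frames are interpolated;
movies with more than half their frames failed raise a quality error.

**Sections** are straightened along three diameters through the centroid at
0°/60°/120° ("three axes" made concrete), sampling a 99-px-wide
perpendicular band, binning the axis into 100 bins (so the central window
"bins 30–50" sits mid-profile), background-subtracting and normalising to
the profile maximum. The band average runs over the object's *filled*
footprint: interior holes count as signal loss, which is exactly the
hollow-core signature the central bins must expose (restricting to tissue
pixels would hide the hole; averaging over the full band would make even a
solid disk non-flat). Section masks use the triangle threshold — section
images have a dominant dim tissue class plus a sparse bright lattice, and
Otsu would split lattice from tissue instead of tissue from background.
Peripheral laminin is the background-subtracted mean over the morphological
boundary ring (dilation minus erosion, default half-width 3 px) of the
filled section mask.

## Synthetic study conditions

The generators default to the acquisition settings of the assays they
emulate: 2-min frames for 2 h (assembly; 15-min baseline before linear
growth), 5-min frames with a 15-min baseline and 1 h follow-up
(disassembly), 5-min frames for 48 h (spheroids), 12-band lambda stacks
(FRET). Genotype fixtures (`data/paper_params.yaml`) carry the published
summary values as generating truth: bleach-FRET ratios, ratiometric drops,
assembly rates and presence fractions, decay constants with the lag rule,
and spheroid trajectory anchors. The wild-type spheroid trajectory
constants (τ_fast 0.5 h, τ_slow 20 h, fast fraction 0.68, baseline 2 h)
were chosen once so the trajectory passes near the published
3 h/20 h/48 h triple; the Ca²⁺ dose map is a logistic fit to the published
wild-type dose series, frozen in the registry. Dose fixtures use
τ_slow = 4 h so a 20-h readout sits on the declared plateau, since the
published dose values are 20-h measurements.

Assembly movies place cells on a grid (25 by default) and assign each birth
of a Poisson process — uniform event times on the growth window, so the
expected cumulative count is exactly baseline-then-linear — to a distinct
adjacent cell pair; with 40 adjacent pairs against ~21 expected births,
saturation is negligible. Camera noise is Gaussian with sd = 2 % of signal
plus a 0.5-unit read-noise floor (the study states no noise figures; both
are free parameters of every generator). What the generators do *not*
emulate: optical PSFs, z-dependent aberrations, photobleaching during
acquisition, cell migration and shape change, and intensity heterogeneity
along a junction — so passing recovery tests demonstrates correctness of
the estimators under the declared geometry and noise, not robustness to
every property of real microscope data.

Problem sizes in the recovery protocols (35/32 FRET scenes, 8 ratiometric
series, 50 disassembly movies, 200 assembly fields, 50 lifetime tracks, 10
spheroid movies at 5-min sampling, 4 movies per Ca dose at 15-min sampling)
match the published sample sizes where those exist and otherwise use
ensembles large enough that the Monte-Carlo error is small against each
tolerance.

## Numerical choices and degenerate inputs

Seeds derive from a base seed via `numpy.random.SeedSequence`, keeping
replicates independent and reproducible. Disassembly movies render in
float64 so the noiseless trace matches its closed form to 1e-9; other
movies render in float32. Pixel coordinates are 0-based (row, column);
time is minutes from acquisition start (hours for spheroid traces).
Degenerate inputs raise typed errors rather than returning silent values:
constant images (no contrast), empty masks, ROIs at background level,
collinear spectra, failed bleaches, traces without a decaying component,
event times outside a series, and movies whose spheroid detection fails in
more than half the frames.
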