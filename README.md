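# junctionkit

Quantification toolkit for live-cell experiments on cadherin-mediated
adherens junctions — the cell–cell contacts formed when cadherin
ectodomains on opposing membranes bind in *trans* and organise laterally in
*cis*. It is written for microscopists studying junction biology with
N-cadherin fluorescent-protein fusions (wild type and interface mutants)
who need the full analysis chain behind four standard assays:

* **Spectral FRET** between donor- and acceptor-tagged cadherins across a
  junction: linear unmixing of lambda stacks into fluorophore abundances,
  the acceptor-bleach estimator
  `FRET = (I_postDonor − I_preDonor) / I_postDonor`, and ratiometric
  acceptor/donor time series around a Ca²⁺-chelator (BAPTA) challenge.
* **Junction tracking** in 2D time lapses: cells are segmented by a
  watershed on the (x, y, t) volume so each cell keeps one identity, every
  pixel is labelled with its two nearest cells, and a junction is the
  suprathreshold interface of a cell *pair* — identity survives spatial and
  temporal gaps because it is the pair key.
* **Kinetics**: constant-baseline + linear fits for assembly rate,
  exponential-decay fits (with an optional post-event lag) for disassembly
  time constants, and baseline + fast/slow double-exponential fits for
  spheroid compaction.
* **Spheroid morphometrics**: segmentation and moment-ellipse roundness
  `4A/(π·major_axis²)` over 48-h movies, Ca²⁺ dose summaries, and
  cryo-section analysis (straightened intensity profiles along three
  diameters, peripheral laminin intensity).

Because such imaging data is rarely deposited, the package includes a
first-class synthetic-microscopy module (`junctionkit.synthetic_data`)
generating every input class with known ground truth — spectral scenes,
assembly/disassembly movies, spheroid movies, cryo-sections — so each
estimator is validated by closed-loop parameter recovery. See
`docs/methods.md` for models, parameters and limitations.

## Worked example

Generate an acceptor-bleach scene whose true FRET ratio is the wild-type
fixture value (19.9 %), then run the full measurement pipeline on it:

```python
from junctionkit.synthetic_data import SceneParams, generate_fret_scene
from junctionkit.spectral_fret import measure_scene_fret

scene = generate_fret_scene(SceneParams(fret_ratio_true=0.199, noise_sd=0.02, seed=2))
result = measure_scene_fret(scene)   # spectra -> unmix -> bleach ratio
print(f"FRET = {100 * result.fret_ratio:.2f} %")
```

```
FRET = 20.43 %
```

A single noisy scene reads 20.43 % against a generating truth of 19.9 %;
averaged over 35 scenes the pipeline recovers the truth to a few tenths of
a percentage point. The same pattern — generate with known truth, measure,
compare — runs a spheroid movie through segmentation and roundness:

```python
from junctionkit.synthetic_data import SpheroidParams, generate_spheroid_movie
from junctionkit.spheroid_morphometrics import roundness_timeseries, roundness_at

movie, truth = generate_spheroid_movie(SpheroidParams(seed=3, frame_interval=60.0))
trace = roundness_timeseries(movie)  # per-frame segment -> roundness, times in h
for t in (3, 20, 48):
    print(f"roundness at {t:2d} h: {roundness_at(trace, t):.3f}")
```

```
roundness at  3 h: 0.530
roundness at 20 h: 0.631
roundness at 48 h: 0.670
```

The movie was generated with a compaction trajectory rising from 0.30
toward a 0.68 plateau; the measured values track it within the ±0.02
discretisation tolerance of the mask-based descriptor.

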