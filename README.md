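# neuroflow

Quantitative image analysis of **microtubule retrograde flow (MT-RF)** in
developing neurons.

In cultured hippocampal neurons before axon formation, the microtubule
array inside each neurite is not stationary: photoconverted tubulin
patches, and puncta of the minus-end marker CAMSAP3, drift toward the soma
at roughly 0.2–1 μm/min. This bulk retrograde flow removes microtubule
mass from neurites, drives cycles of microtubule density, and slows down
specifically in the nascent axon shortly after it starts growing.
`neuroflow` implements the full measurement chain needed to quantify this
phenomenon from low-intensity time-lapse fluorescence movies, together
with a synthetic-microscopy generator that produces the same kinds of data
with known ground truth, so every stage is testable end to end without any
imaging data.

## What the package computes

- **Registration** (`neuroflow.registration`): per-frame integer
  translation by Pearson-correlation hill climbing under cyclic rolls —
  a coarse expanding-ring search that stops when the best direction
  repeats five times, then a per-dimension refinement walk. Intensities
  are capped at mean + 6 SD first; the reference frame adapts when the
  correlation drops ≥ 2 SD below its running mean.
- **Neurite tracing** (`neuroflow.tracing`): soma extraction (grey
  opening → Scharr edges → Otsu → hole filling), neuron-threshold search
  (lowest threshold reproducing the soma size, raised until ≥ 5 skeleton
  pixels are lost in a step), direction-constrained gap closing, and
  skeleton decomposition into branches rooted at the soma, with the
  standard filters (terminal subbranches < 1 μm, neurites < 40 points,
  ≥ 70 % cross-frame overlaps, crossing disambiguation by intensity).
- **Kymographs** (`neuroflow.kymograph`): maximum-intensity sampling
  across an 11–25 px line perpendicular to the traced path (soma at
  column 0), neurite length per frame (stop one pixel before the first
  unthresholded pixel), proximal (0–5 μm) vs distal (tip − 10 to − 5 μm)
  densities, and soma-fraction series.
- **Flow quantification** (`neuroflow.flow`): patch tracking and speeds
  (v = |net displacement| / duration, retrograde positive), CAMSAP3 trace
  linking and per-frame median flow, the axon slowdown detector (200-min
  smoothing; slowed when the axon is ≥ 20 % below every other neurite for
  ≥ 95 % of points across ≥ 180 min), polarization-stage classification
  (axon: ≥ 50 μm and ≥ 10 μm ahead), multi-patch synchrony, patch-spread
  edge speeds, and the retro/±1.1 μm-stationary/antero mass partition.
- **Density cycles** (`neuroflow.cycles`): normalization of per-neurite
  tubulin intensity by the polynomial-fitted expression level, 2-frame
  rolling smoothing, and the hysteresis counter in which a density change
  of ≥ 0.2 is half a cycle; frequency = (half-swings / 2) / hours.
- **Orientation** (`neuroflow.orientation`): plus-end-out vs
  minus-end-out calls for EB3 comet tracks — endpoint rule by arc length
  from the soma, angle votes (< 70° / > 110°) on ties, 65 % consensus.
- **Pipeline & statistics** (`neuroflow.pipeline`): staged end-to-end
  runs with manifests, Kruskal–Wallis + Dunn (Bonferroni) and Wilcoxon
  signed-rank comparisons.
- **Synthetic data** (`neuroflow.synthetic`): seeded generators for
  photoconversion movies, CAMSAP3 movies, EB3 comet track sets, density
  traces and mass-partition kymographs, each returning the exact ground
  truth they rendered.

## Worked example

Simulate a photoconversion experiment at the standard imaging regime
(0.22 μm/px, 30-s frames, 10 min, SNR ≈ 5, ±3 px frame jitter), register
it, and measure the flow:

```python
import numpy as np
from neuroflow import (SimConfig, simulate_patch_movie, register_movie,
                       RegistrationConfig, track_patch, speed_from_track)

cfg = SimConfig(seed=42, patch_speed_um_min=(-0.53,), jitter_max_px=3,
                noise_gaussian_sd=15.0, poisson_gain=1.0,
                bleach_rate_per_min=0.02)
movie, truth = simulate_patch_movie(cfg)
registered, shifts = register_movie(movie, RegistrationConfig(channel="tubulin"))
print("jitter recovered exactly:",
      np.array_equal(shifts.shifts, -truth.jitter_px.astype(int)))
track = track_patch(registered.single("converted"), truth.paths[0], start_um=14.0)
m = speed_from_track(track)
print(f"recovered flow: {m.speed_um_min:.3f} um/min {m.direction} "
      f"over {m.duration_min:.0f} min (truth 0.530 retrograde)")
```

prints

```
jitter recovered exactly: True
recovered flow: 0.521 um/min retrograde over 10 min (truth 0.530 retrograde)
```

i.e. the registration undoes every simulated frame shift exactly, and the
tracked patch speed lands within ~2 % of the simulated 0.53 μm/min drift.

The same chain is available from the shell:

```sh
neuroflow simulate --out movie.tif --seed 42
neuroflow register --input movie.tif --out reg.tif --shifts shifts.csv
neuroflow trace    --input reg.tif --out branches.csv
neuroflow kymo     --input reg.tif --branches branches.csv --channel 1 --out kymo.tif
neuroflow flow     --input reg.tif --branches branches.csv --channel 1 --out flow.csv
```

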