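# Methods

This note documents the models and procedures implemented in `neuroflow`,
the parameters that matter, the numerical choices made where the design
was genuinely open, and what the synthetic benchmark does and does not
establish about real data.

## Measurement model

Microtubule retrograde flow (MT-RF) is the bulk translation of the
microtubule array inside a neurite toward the soma. It is measured in two
ways, which the package reproduces faithfully:

1. **Pulse-chase patches.** A small stretch of fluorescent tubulin is
   photoconverted/photoactivated and followed. The patch position along
   the neurite is summarized per frame as the intensity-weighted centroid
   arc length of the background-subtracted signal in the path corridor;
   speed is |net displacement| / duration (the width/height rule applied
   to a kymograph trace), with retrograde reported positive and the
   direction carried by a label. Tracks lasting ≤ 1 min are rejected.
2. **CAMSAP3 fiducials.** Puncta of the minus-end binder CAMSAP3 move
   with the array. Traces are extracted from kymographs (thresholded
   puncta linked frame-to-frame by nearest position, ≥ 3 frames), only
   retrogradely moving traces are kept, and per-frame flow is the median
   slope over the traces covering that frame.

**Axon slowdown.** Per-neurite flow series are smoothed with a centered
rolling mean of 200 min (window truncated at the ends). A time point
qualifies when the smoothed axon flow is at most 0.8× the *minimum* over
all other neurites (strictest reading of "20 % slower than all other
neurites"; comparison against the mean is available as a toggle). The
slowdown is detected when some 180-min window holds ≥ 95 % qualifying
points, with the onset at the start of the earliest such window; series
spanning under 180 min are "not evaluable", distinct from "not detected".
The 95 % criterion is evaluated inside the window (the alternative —
onset-to-end — is a config away but not the default).

**Polarization stage** from neurite lengths: an axon requires the longest
neurite ≥ 50 μm and ≥ 10 μm ahead of the second longest; no-axon requires
the longest < 50 μm and (< 30 μm or < 5 μm ahead); everything else is the
transition stage. Rules are evaluated in that order.

**Patch spread and mass partition.** After subtracting the neurite
background — the minimum over the first five columns of the first and
last four rows of the kymograph, floored at the running maximum of
previous conversion intervals — each analyzed row is trimmed by removing
the lower-valued of its two edge pixels until ≥ 10 % of the summed
intensity is gone (ties remove the pixel farther from the start, both
when equidistant, which keeps symmetric profiles symmetric); the spread
is the surviving extent, and edge speeds are the displacement of the
surviving extremes beyond ±1.1 μm of the start over elapsed time. The
mass partition divides each row's background-subtracted sum into
retrograde (> 1.1 μm soma-ward of the start), stationary (±1.1 μm) and
anterograde zones; rows are analyzed until the peak falls below 1.8×
(1.3× under actin depolymerization) the background. 1.1 μm converts to
pixels by rounding half-up; row "signal" for the stop rules is the row
maximum.

## Registration

Translation-only, integer-pixel, designed for very low photon counts:

- **Capping.** Each channel is clipped at mean + `k_sd`·SD (default 6,
  from the "6 to 7" range), with the statistics computed globally over
  all frames and pixels; a per-pixel variant exists behind a flag. Global
  was chosen because per-pixel SDs are extremely noisy at low counts.
- **Search.** Pearson correlation is computed over the full frames under
  cyclic rolls (rolling rather than padding avoids zero-filled borders
  biasing the correlation of dim images). The coarse stage evaluates the
  8 compass directions at radius 1, 2, … and stops when the same best
  direction repeats 5 consecutive times; ties break by a fixed row-major
  scan order. Refinement walks one pixel at a time per dimension,
  probing up to `lookahead_px` (default 2) past the best value, repeated
  over dimensions until neither improves. Frames with zero variance
  return the seed shift with correlation NaN.
- **Chaining.** The best shift of frame *t* seeds frame *t + 1*. The
  reference is replaced by the current registered frame when its
  correlation falls ≥ 2 SD below the running mean of accepted
  correlations (running statistics need ≥ 3 frames and reset after a
  switch, since a new reference defines a new correlation baseline); a
  drop — not a rise — signals a morphology change, though a two-sided
  toggle exists. Slice mode additionally renews the reference every 3
  frames. Output frames are rolled and their wrapped margins zero-filled
  (|dy|·W + |dx|·H − |dy|·|dx| pixels per frame).

On 64×64 frames with true shifts ≤ 6 px at SNR 5, the hill climb matched
an exhaustive ±10 px FFT search in 200/200 seeded trials (the acceptance
suite requires ≥ 99 %).

## Neurite tracing

The soma is found on the grey-opened frame (disk radius 10 px by default —
it must exceed the neurite width and stay below the soma radius) via
Scharr edge magnitude, Otsu thresholding of the edges, and hole filling;
a one-pixel erosion then compensates the ~2 px width of the edge ring,
which otherwise inflates the soma radius by about a pixel.

The neuron threshold starts at the lowest value whose extracted soma size
matches the edge-derived area within ±5 %. Because the thresholded
component at the soma necessarily includes the neurites, "soma size at a
threshold" is measured after binary opening with the same disk, which
strips the neurites and makes the comparison soma-against-soma. The
threshold then rises in steps of 1 % of the dynamic range; the returned
value is one step before the first step losing ≥ 5 skeleton pixels.
Loss is counted per step (a cumulative variant is a config toggle); with
a diffraction-limited cross-section the whole distal centerline drops in
one step once the threshold crosses its peak, which is what makes the
rule effective.

Gap closing bridges each detached component from its soma-closest point
to the nearest soma-connected point whose bearing lies within 45° of the
component's principal axis (undirected angles; maximum bridge length
30 px). Branch construction removes the 2-px-dilated soma, skeletonizes,
roots every skeleton component within 6 px of the soma cut, and reads
branches as shortest skeleton paths from the root to each tip. Terminal
subbranches < 1 μm are pruned, components with < 40 skeleton points are
dropped, and at branch points a continuation is accepted only when the
emerging branch's median intensity is within [0.5, 2.0]× the incoming
one (operationalizing "similar range" at crossings; the exact band was
not quantified at the source and is configurable). Cross-frame overlap
filtering removes branch pairs from different frames that overlap ≥ 70 %
(share of one branch's points within a 1-px dilation of the other) while
starting > 3 px apart. Coordinates are 0-based (row, column) everywhere.

Known root/tip artifact: skeletonizing after soma removal leaves a 1–2 px
flare along the circular cut and a ~1 px overshoot into the blurred tip,
so accuracy guarantees apply to the branch body.

## Kymographs and derived series

Paths are resampled to 1 px of arc length per column; each value is the
maximum over `width_px` (odd, default 11) nearest-pixel samples along the
normal to a 5-point central-difference tangent. Nearest-pixel lookup (no
interpolation) preserves maximum semantics. Neurite length per frame uses
median smoothing (2×2, or 1×5 across position only for data where
smoothing over time would blur retraction events), manual threshold (Otsu
only as fallback — the source procedure used a manually chosen value),
forcing of the first and last time points into the thresholded set so
interior dropouts become fillable holes, hole filling (optionally after
one dilation, the variant used for minus-end-marker kymographs), and a
walk from the soma stopping one pixel before the first unthresholded
pixel. Proximal/distal densities are mean thresholded intensities in
[0, 5] μm and [L−10, L−5] μm, each normalized to its mean over the first
22.5 min; neurites < 10 μm have no distal value.

## Density cycles

Per-neurite mean tubulin intensity is divided by the expression level:
a degree-2 (long developmental movies) or degree-1 (short drug-treatment
movies) least-squares polynomial in time fitted to the neurite-averaged
intensity. A nonpositive fit raises, because the normalization is then
undefined. Traces are smoothed with a trailing 2-frame mean.

Cycles are counted by hysteresis: the detector tracks the running
extremum and registers half a swing whenever the trace departs ≥ 0.2 from
it in the opposite direction, resetting the extremum. This uniquely
operationalizes "an increase of 0.2 followed by a decrease of 0.2 or vice
versa", and on 1,000 random traces it equals an independent
dynamic-programming enumerator of maximal alternating subsequences. Each
excursion counts as half a cycle, so the frequency is
(half-swings / 2) / duration; the completed-pair count ⌊half/2⌋ is also
reported. Flooring the frequency to completed pairs would bias finite
traces low by up to half a cycle — about 10 % for a 10-h trace at 0.56
cycles/hour, which is why half-cycle resolution is the default.

## Orientation calls

EB3 comets mark growing plus ends, so travel direction reports
microtubule orientation. Comet detection/tracking is external; tracks
come from CSV or the simulator. The neuron image is accumulated from all
track points (1-px dilation, largest component) and skeletonized by the
tracing module. The endpoint rule compares the arc length from the soma
of the nearest skeleton points of the first and last track positions;
on a tie, per-timepoint votes compare the comet direction (t → t+2)
against the local tip-ward skeleton direction (−2 → +2 points): < 70°
votes plus-end-out, > 110° minus-end-out, the 70–110° band abstains. A
label needs ≥ 65 % consensus among voting timepoints (whether abstaining
timepoints enter the denominator is a toggle; voting-only is default).
Tracks farther than 5 px from the skeleton are unassigned. Angles are
unsigned in [0°, 180°], which makes the caller exactly antisymmetric
under time reversal.

## Synthetic benchmark

The generators emulate: somata (disk, default radius 5 μm — typical of
1-day cultures and necessarily larger than the tracer's grey-opening
disk) with Gaussian-profile neurites (σ = 1.5 px, diffraction-limited
appearance without optics modeling) at 0.22 μm/px and 20–180 s frame
intervals; photoconverted patches as arc-length Gaussians drifting at
configured signed speeds, rendered with bilinear subpixel splatting and
renormalized so total patch intensity is conserved (bleaching and noise
aside); integer-pixel frame jitter (subpixel optional); Gaussian read
noise plus Poisson shot noise with defaults (σ = 15, gain = 1, patch
amplitude 100) giving peak SNR ≈ 5; exponential bleaching; CAMSAP3
puncta appearing at staggered times; EB3 comets at 12–18 μm/min with a
configurable plus-end-out fraction; triangle/sine density traces whose
`amplitude` is the peak-to-trough excursion (so amplitude 0.1 sits below
the 0.2 half-cycle threshold by construction); and mass-partition
kymographs whose zone sums equal the requested fractions exactly before
noise, at a row signal mass of 2000 (a bright converted patch, ~15–20×
background) so that the background-estimation residual perturbs the
recovered fractions by ≲ 1 percentage point rather than dominating them.

All randomness flows through one generator seeded from `SimConfig.seed`;
identical configs give bit-identical outputs.

What the benchmark does **not** emulate: optical PSFs and photophysics,
3-D volumes, neurite growth/retraction dynamics during patch tracking,
organelle traffic and autofluorescence backgrounds, and comet detection
noise. Passing recovery tests therefore demonstrates correctness of the
analysis chain under controlled imaging statistics, not robustness to
every biological confound.

## Benchmark experiment sizes

The recovery experiments use: 30 single-neurite movies (21 frames of
240² px) for the unpolarized-regime speed; 25 cells × 3 movies for the
paired minor/axon regimes; 30 two-patch neurites (280² px, no jitter —
the paired design isolates the speed ratio) for the distal excess;
27 cells × 4 neurites × 201 frames for cycle counting; 20 kymographs for
the mass partition; 200 cohorts × 95 pairs for the correlation. These
sizes match the reported group sizes where stated and keep a full run at
about a minute on one CPU.

## Known limitations

- Registration is integer-translation only; rotation, scaling and
  subpixel refinement are out of scope.
- The tracer expects cytosol/shaft markers; tip-enriched markers break
  the threshold search.
- `track_patch` follows one patch per corridor window; overlapping
  patches need explicit start positions.
- The slowdown detector assumes a shared time base across neurites and
  treats missing flow values as non-qualifying.
- Dunn's test uses the normal approximation with tie correction; exact
  small-sample Dunn p-values are not implemented.
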