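# Methods

`myxostream` quantifies *streams* — elongated regions of a starving
*Myxococcus xanthus* swarm in which cells are nematically aligned, moving,
and at elevated local density, persistently in place — from time-lapse
fluorescence movies of a sparsely labeled subpopulation (1 frame/min), and
tests whether streams are spatially enriched around nascent aggregates.
This note documents the model behind each stage, the parameters that
matter, and the choices made where the procedure was genuinely open.

## Persistence imaging

Raw frames are summed pixelwise over a symmetric moving window of 5 frames
(`persistence_stack`). A gliding cell leaves a streak whose length and
direction encode its motion over 5 min; a stationary cell leaves a bright
spot. Sums are accumulated as direct per-window additions in float64 so
they are lossless for 16-bit input and bit-identical to a naive loop.
Frames at the stack edges where the symmetric window does not fit are
dropped, not padded; persistence frame *k* is timestamped at its central
input frame.

Each persistence frame is then globally histogram-equalized
(`skimage.exposure.equalize_hist`, 256 bins) to [0, 1], balancing contrast
between dim and bright regions. The mapping is the empirical CDF — monotone
up to ties — so rank order is preserved and re-equalizing changes values by
less than one gray level. Tile-based (adaptive) equalization is not used;
it would break the global intensity ranking the density thresholds rely
on.

Equalized persistence frames are tiled into 30-frame analysis windows at a
5-minute stride (`make_windows`); each window is one analysis timepoint,
timestamped at its center.

## Feature fields

**Speed.** Dense optical flow between consecutive persistence frames via
iterative Lucas–Kanade (`skimage.registration.optical_flow_ilk`, radius 7,
i.e. a 15-px integration window): a local least-squares solve of the
brightness-constancy equation with Gaussian weighting. Reported as
per-pixel displacement magnitude in px/frame; x is the column axis, y the
row axis (down). Constant frames carry no gradient and return a zero field
with a warning. Two caveats are inherent and absorbed by threshold
re-optimization rather than corrected: flow along a streak's own axis is
under-estimated (aperture problem), and magnitudes in empty regions are
noise.

**Orientation and alignment.** Each frame is tiled with 15-px windows at
70% overlap (grid spacing round(0.3·15) = 5 px). Per window: subtract the
mean, apply a 2-D Hann taper, FFT, zero the DC bin, and form the
second-moment (inertia) tensor of the power spectrum. Stripes concentrate
spectral power along their normal, so the reported nematic orientation is
perpendicular to the tensor's principal axis, taken modulo π. The tensor's
anisotropy (λ₁−λ₂)/(λ₁+λ₂) is kept as a per-window confidence weight;
isotropic windows still contribute their (meaningless) angle with equal
weight, matching the unweighted default of the reference AFT approach —
random angles simply average out in the next step.

The scalar nematic order parameter at each grid node is
S = √(⟨cos 2θ⟩² + ⟨sin 2θ⟩²) over the (2n+1)² surrounding orientation
vectors (n = 2 by default, 25 vectors; edge nodes use truncated
neighborhoods with the correct count). S = 1 for identical angles; for
i.i.d. uniform angles E[S] = √(π/4n) → 0 as the neighborhood grows. The
grid is bilinearly upsampled to pixel resolution for masking.

**Density.** Gaussian smoothing of the equalized persistence frame
(σ = 10 px, reflective boundaries) blurs individual cells into a local
density estimate.

## Stream mask

Each feature raster is thresholded (bounds inclusive): speed ≥ speed_min,
S ≥ align_min, density_min ≤ ρ ≤ density_max (the upper bound removes
cell-free holes' complement — aggregates and clumps). The three masks are
ANDed into a candidate mask per persistence-frame pair; a 30-frame window
yields 29 candidates (flow needs pairs; alignment and density are taken
from the first frame of each pair). The temporal-persistence rule keeps
pixels present in at least ⌈min_fraction · n_candidates⌉ candidates —
⌈0.5·29⌉ = 15, the same count as the nominal 15-of-30 half rule. Coverage
is reported as %FOV over the whole crop with no border erosion; peak time
resolves ties to the earliest window. Persistence is counted per pixel,
not per connected region, matching the raster mask outputs; no
morphological cleanup is applied.

## Threshold optimization

Human judgment ("visual screening", "sharp decline") is replaced by two
explicit rules on %FOV-vs-cutoff curves of calibration frames:

* **Speed** (grid 0.1–0.7, step 0.05): largest cutoff whose mean mask
  coverage ≥ 80% of the FOV — the mask detects *that* cells move rather
  than how fast. If no cutoff reaches 80% (typical for a sparse labeled
  channel, where flow covers only part of the FOV) the grid minimum is
  chosen and a calibration warning logged.
* **Alignment** (grid 0.1–0.9): the value right before the largest forward
  drop of the curve. A curve whose largest drop barely exceeds the typical
  step (no distinct decline, e.g. uniform-random S) is flagged
  low-confidence; a flat curve falls back to the grid midpoint.
* **Density** (two-sided): per stream frame, the lower bound is the grid
  value just *after* the largest drop — where the (majority) background
  has fallen out and cells remain; per aggregate frame, the upper bound is
  the same rule restricted to cutoffs above the lower bound — where the
  cell population has fallen out and only the aggregate core remains.
  Each bound is averaged over its calibration frames (three per replicate
  in the intended design); replicates are optimized independently by
  calling the routine per movie.

Grid step 0.05 throughout; published threshold values can be supplied
directly as a `ThresholdSet` to bypass optimization.

## Aggregates and the band/outside statistic

Aggregates are detected per frame as 8-connected components above an
intensity threshold with at least `area_min_px` pixels; a chain of
overlapping components that survives ≥ 10 consecutive frames is an
aggregate, dated and footprinted at the chain's first frame. The
persistence requirement and minimum area replace the visual onset
identification of manual analysis; both are configurable.

For a focal aggregate, every aggregate mask is dilated by a Euclidean disk
of radius 20 px. The *band* is the focal dilation ring minus any pixel
claimed by another aggregate or its dilation; the *outside* excludes all
aggregates and all dilations. The three regions are therefore pairwise
disjoint by construction (asserted per partition); bands clipped by the
frame edge are retained. With the stream mask taken from the analysis
window nearest onset − 15 min:

    P(stream | band)    = |S_stream ∩ S_band| / |S_band|
    P(stream | outside) = |S_stream ∩ S_outside| / |S_outside|

Across aggregates, `paired_comparison` reports how many have the band
proportion higher vs lower (ties separately) and a paired two-sided
Student t-test on the differences. If streams are placed independently of
aggregates the test is calibrated at its nominal level — verified by
simulation — and the higher/lower split is near 50/50.

## Track metrics

Net displacement of a cell between two timepoints is the Euclidean
distance between its positions at the nearest track frames (a gap of more
than 2 frames at either endpoint excludes the track rather than
interpolating), converted by `um_per_px`; summaries report mean ± SD in
microns and in cell lengths (7 µm default, configurable). Net displacement
is bounded by path length; frequent reversals shrink the former, not the
latter.

## Synthetic movie generator

The generator produces the statistical structure the detector assumes,
with exact ground truth; it is not a physics simulation.

* **Agents**: `n_cells` labeled rods (7 × 0.7 µm, rendered as anisotropic
  Gaussian kernels of amplitude `cell_amplitude` on a 16-bit background)
  glide along their body axis at `speed_um_per_min` (default 3 µm/min) and
  reverse with exponential waiting times (`reversal_period_min`, default
  8 min). Orientation diffuses with per-frame Gaussian jitter; frame
  boundaries reflect.
* **Pre-stream phase**: before the earliest lane onset, rods move at
  `pre_stream_speed_factor` (default 0.3) of full speed — dispersed, slow,
  randomly oriented, as in the phase preceding stream formation.
* **Stream lanes**: polyline centerlines with a width and an active frame
  span. Rods inside an active lane snap (nematically, choosing the tangent
  direction closer to their heading) to the lane tangent with reduced
  jitter and a 5-fold reduced reversal rate. Lane interiors additionally
  receive an elevated background (`lane_boost`) plus an anisotropic
  texture, long-correlated along the lane and drifting at the gliding
  speed — the dim, aligned, co-moving unlabeled majority. Default lanes
  (three parallel, each 10% of the frame wide, ~30% combined coverage —
  comparable to peak stream coverage in real swarms) switch on after the
  first sixth of the movie.
* **Aggregates**: disks where rods stall and intensity ramps to
  `aggregate_amplitude` over ~10 frames.
* **Ground truth**: per-frame lane-interior masks, aggregate specs, and
  the full track table; geometry is set by the config, so different seeds
  change tracks and noise but not truth.

What the generator does **not** emulate: rod–rod collisions and excluded
volume, slime trails/EPS, signaling, gradual stream nucleation and
merging, photobleaching, drift, or uneven illumination. Passing tests
therefore demonstrate that the pipeline recovers the constructed
statistical structure (moving + aligned + dense + persistent regions and
their co-localization geometry), not that it segments any particular real
movie; on real data the thresholds must be re-optimized per replicate
exactly as the optimization module does.

## Numerical choices and degenerate inputs

* Threshold bounds are inclusive; `lo > hi` is an error.
* Peak-coverage ties resolve to the earliest window.
* Constant flow frames → zero field + warning; constant equalization
  input → single output value; empty candidate list → error naming the
  requirement.
* Flow sign convention: positive vx/vy for content moving toward larger
  column/row indices.
* The order-parameter neighborhood mean divides by the true in-bounds
  vector count at edges (no zero-padding bias); S is clipped to [0, 1]
  against float round-off.
* Empty band or outside regions flag the partition and exclude the
  aggregate from paired statistics rather than producing 0/0.
* All randomness flows from a single `numpy` Generator seeded by the
  config; identical configs give bit-identical movies, masks, and CSVs.

## Test problem sizes

The suite exercises the full pipeline on 120–200 px movies of 40–100
frames with a 10-min analysis stride, sizes at which every stage's
behavior (lane recovery at IoU ≥ 0.5, <5% quiet-phase coverage, null
calibration of the band statistic over 150 synthetic aggregates, 500-run
t-test calibration) is measurable in minutes on one CPU. Full 400-px,
310-frame movies run through the same code paths via the CLI.
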