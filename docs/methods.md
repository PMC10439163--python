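# Methods

This note documents the models and numerical choices behind `flowquant`'s
five analysis workflows and the synthetic-microscopy generator they are
validated against.

## Imaging model and calibration

All pixel intensities are treated as arbitrary units ≥ 0; nothing is ever
rescaled on load. Physical outputs require two calibrations: `fps` (frames/s,
videomicroscopy only) and `um_per_px` (µm/pixel); both must be strictly
positive and are attached to the `FrameStack` once. Coordinates are 0-based
with x = column (rightward) and y = row (downward); regions of interest are
half-open boxes. Background subtraction defaults to the per-pixel median over
all frames ("static-median"), subtracted and clipped at zero — deterministic,
and exact for static structures such as channel walls when the camera is
fixed; a rolling-median variant (default 11-frame window) tolerates slow
drift. Both require ≥ 2 frames by construction.

## Single-cell tracking

Cells are modeled as compact particles with a 2-D Gaussian-like brightness
profile. Detection: (1) bandpass = Gaussian smoothing (σ = 1 px) minus a
boxcar average at the expected diameter, clipped at 0; (2) grayscale-dilation
local maxima with brighter-peak-wins suppression within one diameter, and a
candidate floor of 10⁻⁶ × the image maximum to exclude numerical dust;
(3) iterative intensity-weighted centroid refinement in a circular window
(radius = diameter//2), re-centering while the offset exceeds 0.5 px (max 10
iterations). Each detection carries integrated mass, radius of gyration Rg,
moment eccentricity (√(1 − λ₂/λ₁) of the second-moment tensor), and raw peak
intensity; `min_mass`, `min_intensity` and `max_diameter` (on 2·Rg) filters
reject noise, debris and aggregates respectively. An `invert` flag handles
dark-on-light cells (dense RBCs, brightfield platelets).

Linking solves one rectangular assignment problem per frame: candidate links
are displacements ≤ `search_range_px`, costs are squared displacements,
and every track/detection may stay unmatched at cost `search_range²`
(augmented LAP). This minimizes total squared displacement globally within
each frame pair and is fully deterministic. Tracks unseen for up to
`memory_frames` frames stay alive at their last position (no motion model).
Quality filters — minimum frames present and minimum path distance — are
applied after linking and are monotone: raising either never adds
trajectories.

Velocity uses elapsed time = frame span / fps, so bridged gaps count toward
time. `free` mode divides the total path distance by elapsed time; the
`x_channel_flow` mode uses net x-displacement (straight-channel transit /
deformability readout) and flags negative values instead of clipping.

**Size convention.** A uniform disk of radius r has Rg = r/√2, so the
reported effective radius is √2·Rg and the area π·(√2·Rg)² = 2π·Rg². This
uniform-disk equivalence makes the area exact for flat disk-like adherent
cells (verified against exhaustive rasterization: a radius-10 disk measures
78.8 µm² at 0.5 µm/px vs the 79.25 µm² pixel-count truth) and is applied
uniformly across the tracking and adhesion workflows.

Per-cell fluorescence is the mean over frames of the summed intensity in a
circular aperture about the centroid; frames where the aperture leaves the
image are skipped with a warning.

## Suspension velocimetry

Texture features are Shi-Tomasi corners (scikit-image response, relative
quality threshold, minimum corner separation, 1-px border exclusion so
wall-adjacent rows stay sampled). Tracking is sparse pyramidal
Lucas–Kanade: 3 pyramid levels (halved until the level is smaller than twice
the window), bilinear patch sampling with edge clamping (patches may overhang
the frame; only an out-of-bounds patch center is fatal), Newton iterations on
the 2×2 normal equations until the update is < 0.01 px (max 12), and failure
when the structure tensor's minimum eigenvalue is < 10⁻⁴ (untextured patch).
Features are re-seeded every `reseed_every` frames (default 10; dense
profiles use 5) at locations not already occupied, so fast flow does not
deplete the tracked set.

`window_size_px` is the maximum distance a feature may travel between
consecutive frames: a recovered step larger than the window marks the step
invalid and ends the track. Flows faster than the window therefore
under-sample — lost features and low-biased survivors — which is the
documented failure mode of window-based tracking; the window must exceed the
expected per-frame displacement.

Time courses attribute the step t→t+1 to frame t, exclude steps below
`min_step_px` as noise, and report frames with no valid feature as missing
(not zero). Profiles bin each feature's mean valid-step velocity by its
*initial* signed distance from the channel center (center = midpoint of the
user's channel span, or of the frame height); bins tile the span. The
bluntness ratio divides the mean of the two outermost non-empty bins by the
frame maximum velocity, where the frame maximum is aggregated as the median
over frames of each frame's maximum valid-step velocity — a robust estimator,
since a single mismatched corner would otherwise inflate the denominator and
deflate the ratio (plug flow measures ≈ 1.0 with it, 0.75 without).

## Adhesion

Fluorescence segmentation binarizes the membrane channel at the user
threshold (strictly greater = signal) and labels 8-connected regions —
8-connectivity avoids splitting thin protrusions. Per region: area, centroid,
moment eccentricity (reported as circularity), equivalent-disk radius,
texture = standard deviation of membrane intensity over region pixels,
secondary-stain sum over above-threshold pixels, and nuclear lobe count.
Lobes are local maxima of the lobe channel inside the region, above its
threshold, with pairwise Euclidean spacing ≥ `min_peak_sep_px` enforced by a
greedy strongest-first pass (the library peak finder's `min_distance` uses a
square footprint, which over-suppresses diagonal pairs at exactly the spacing
limit).

Protrusion counting computes a Harris response (k = 0.04, σ = 1) on the
region mask smoothed by a σ = 1 Gaussian (raw rasterized boundaries are
staircase corners). Candidates above an absolute floor of 10⁻³ (scale-free on
a unit-height mask; a smooth disk's staircase response stays well below it)
are kept only if within 5 px of a convex-hull *vertex* — tips coincide with
hull vertices while concave notches lie strictly inside the hull, and the
Harris peak of a sharp tip sits up to ~4 px inside the apex, which rules out
a hull-edge-distance test. The sharpness fraction is applied relative to the
maximum response among these convex-boundary candidates (the global maximum
is usually a notch for high-order stars), candidates closer than
`min_separation_px` merge keeping the strongest, and each survivor snaps to
the locally farthest boundary pixel — the protrusion end — for the
centroid-to-end distances. Planted star orders 3–8 are recovered exactly with
tip distances matching the rasterized tips to ~0.1 px.

Transient adhesion detects and links as in tracking (small default search
range, adherent cells are near-stationary), discards detections whose
integrated mass exceeds `max_intensity` as debris, drops tracks shorter than
`min_frames`, and reports the inclusive frame span over fps — every time is
an exact multiple of 1/fps. The path distance is reported alongside so a
transit-time reading of the same trajectories stays recoverable.

## Occlusion / accumulation

Signal masks are per-plane `pixel > threshold`. The device map counts signal
occurrences per pixel across all planes and timepoints and keeps pixels with
count ≥ `map_threshold` (default 1 = plain union; the parameter exists
because the summed map may warrant a stricter cut on noisy data).
Microchannels are assumed horizontal: connected regions (single-column
dropouts closed for labeling only) become channels indexed top-to-bottom;
walls are the per-column min/max rows, interior gaps linearly interpolated,
then median-filtered over 5 columns — ±1-px ragged walls smooth to within
1 px of the true walls. A channel's analysis region is the area *between its
smoothed walls*, which makes the identity "span-weighted mean of per-x
occlusion = whole-channel occlusion" hold exactly. Occlusion is
100·|signal ∩ region|/|region|; accumulation is the per-interval signal-area
change; the accumulation rate is the least-squares slope of signal area
(µm²) versus time (min) — reported both ways because a rate is the natural
cross-experiment summary while intervals localize instability. Spatial
occlusion is reported per x with x counted from each channel's inlet
(proximal end).

## Clustering

Feature tables pool across samples with one label per file; rows with missing
selected features are dropped (counted). Standardization (zero mean, unit
s.d. over the pooled points) defaults to on because the features mix units
(µm², µm/s, a.u.) and unscaled Euclidean k-means would be dominated by the
widest-ranged feature. K-means uses k-means++ seeding, 10 restarts, and a
fixed user seed; cluster ids are renumbered by descending size so labels are
stable across runs. The scree suggestion is the arg-max of the second
difference of the inertia curve (the elbow); it is advisory — a user-chosen k
always wins. The silhouette is the mean of (b−a)/max(a,b) and matches a
brute-force pairwise-distance computation to 10⁻⁹; it is undefined for k = 1.
The sample × cluster frequency table is emitted in contingency layout for
downstream Chi-squared testing (the test itself is out of scope).

## Synthetic fixtures

The generator renders what each workflow consumes, with truth computed by
construction or exhaustive rasterization — never by the analysis under test:

* moving cells: 2-D Gaussian spots (σ = 2 px, amplitude 200 by default) on
  separate rows (> 4σ apart, so identities are unambiguous), translating at
  exact per-frame sub-pixel displacements; optional co-moving stain plane
  with analytically known integrated signal (2πAσ²);
* adherent scenes: rasterized disks/ellipses/stars/polygons on a membrane
  plane, a centrally concentrated secondary stain of known sum, and lobe
  Gaussians placed on a regular polygon with side = the requested separation;
* suspension flow: Gaussian speckles (σ = 1.1–1.3 px, density ≈ 0.03/px²)
  advected horizontally by a prescribed v(y), periodic in x with wrap-around
  ghosts, optionally time-modulated (ramps);
* occlusion series: stencil pixels lit in a deterministic order (from the
  inlet, random, or a rotating window over a seeded permutation whose union
  covers the stencil), with per-timepoint areas rounded to exact pixel
  counts.

Noise is additive Gaussian clipped at zero — a controllable SNR knob. All
renders are bit-identical under a fixed seed.

What the fixtures do **not** emulate: optical point-spread functions, shading
and vignetting, photobleaching, cell shape change and overlap, out-of-focus
debris, and compression artifacts. Passing tests therefore demonstrate
algorithmic correctness on well-formed inputs and graceful degradation under
additive noise and the documented window-size failure, not robustness to
every artifact of real microscopy; on real data the interactive parameters
(thresholds, diameters, windows) still need tuning per dataset, which is why
every workflow exposes them and the sweep harness tabulates sensitivity.

## Problem sizes and study conditions

Validation uses 10 cells × 50 frames (detection/linking), 5 cells × 40 frames
per speed in {50, 125, 250} µm/s with noise σ = 3 (velocity recovery), a
128-px channel at 300 µm/s peak with ~450 tracked features × 30 frames and
16-µm bins (profiles; window 7 px), stars of outer radius 16 px (protrusions),
a 32-channel comb stencil of 23 040 px² (occlusion), and 300-point planted
clusters separated by 10 within-cluster s.d. in both features (clustering).
These sizes keep every property measurable with comfortable statistical
margin while the full suite and the acceptance script each run in well under
a minute of compute per workflow.

## Known limitations

* Linking uses nearest-position assignment without a motion model; it is
  exact for the planted separations but would swap identities for crossing
  cells closer than the search range.
* Lucas–Kanade velocities within ~half a window of a wall average over the
  local shear, biasing wall-bin means slightly high for strongly curved
  profiles (≤ ~4% of the maximum velocity under the fixture conditions).
* Protrusion counting assumes protrusions are convex-boundary features;
  protrusions of a strongly concave cell body would be filtered out.
* The microchannel model is horizontal-flow only; rotate other orientations
  during loading.
* AVI decoding depends on an imageio video plugin being available; frame
  sequences (TIFF/PNG) are the always-available path.
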