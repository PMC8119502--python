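# Methods

This note documents the models, estimators and numerical choices behind
`sheetflow`, and what the synthetic-data validation does and does not show
about real microscopy data.

## The measurement model

The object of study is an approximately circular epithelial sheet expanding
into free space, imaged in phase contrast at two opposing edges
(0.582 µm/pixel, 1024 × 1344 px fields of view, one frame every 3 min).
Physical coordinates are µm with y up; image rows increase downward, so
`y = stage_y − row · pixel_size`.  The two traced edges, mapped through the
stage positions, are fit to one circle per frame (Kåsa algebraic least
squares — exact on noise-free circles); the center is fixed at the temporal
median of per-frame centers and R(t) is the mean distance of each frame's
edge points to that center.  This center defines the *outward radial
direction* used by every direction-dependent metric, and the normalized
radial coordinate r/R (1 = leading edge).

## Edge analysis

Segmentation: Sobel gradient magnitude → Gaussian smoothing (σ = 1.5 px) →
Otsu threshold → 5 × 5 median filter → morphological closing and opening
(disk r = 3) → largest connected component → hole filling → 2 px erosion.
The final erosion compensates the ~2 px outward spread of the gradient
response around the intensity step, re-centering the traced boundary on the
true edge (validated at ≤ 1.5 px mean distance on ground-truth movies).  A
frame whose Otsu split separates nothing (foreground/background energy
ratio < 2) is classified whole: textured frames return a full mask, blank
frames raise.  All parameters live in `SegmentationConfig`.

Edge tracing is a shortest-path problem: nodes are mask pixels 8-adjacent
to background, edges connect 8-neighbors with weight 1 (axial) or √2
(diagonal), and Dijkstra (via `scipy.sparse.csgraph`) finds the cheapest
path between the lateral image borders.  Edge length is the summed
point-to-point distance in µm; *complexity* is its temporal mean and
*variability* its sample (n−1) standard deviation.  Curvature is the signed
Menger curvature over a ±40-boundary-point window (κ = 2·cross/(|a||b||c|),
i.e. the reciprocal circumradius), with outward bulges positive; collinear
triples return 0, and window-less endpoints are excluded.  Sheet
displacement is R(t_end) − R(t₀); negative values (shrinkage) are legal and
logged.

## PIV

Multipass FFT cross-correlation in MatPIV's offset-only style: passes of
64, 64, 32, 32 px windows at 50 % overlap (window k covers
`[k·w/2, k·w/2+w)`, center at `k·w/2 + w/2`; final grid spacing 16 px ≈
9.3 µm), each pass shifting the second frame's windows by the rounded
previous-pass displacement.  Windows are mean-subtracted and correlated by
zero-padded FFT; the correlation map is divided by the per-lag overlap area
(the unbiased estimator) because the raw zero-padding envelope pulls the
sub-pixel peak toward zero lag.  Peaks are refined by a 3-point Gaussian
fit per axis — exact for Gaussian-shaped peaks, hence the speckle texture
below.  SNR is first peak over second peak outside a 3 px exclusion zone;
vectors under 1.3 are invalidated and replaced by the component-wise median
of their valid 8-neighbors (left invalid with none).  Texture-free windows,
windows that leave the image, and windows wholly outside the sheet mask are
invalid.  Velocities are `px/frame · pixel_size / frame_interval` (µm/min),
with u along +x (columns) and v along physical +y.

Measured accuracy on noise-free speckle: integer shifts ≲ 1e-14 px,
half-pixel shifts ≲ 0.02 px mean error, 0.2° rigid rotation ≤ 0.2 px RMS.

## Flow metrics

* **Angular deviation.**  θᵢ is the signed angle (counterclockwise
  positive) from the local outward unit vector to the velocity; zero-speed
  vectors and center-coincident sites are skipped.  The dispersion is
  √(2(1−z)) with z the mean resultant length; z is clamped to 1 against
  floating rounding.  Values: 0 aligned, √2 uniform.
* **Spatial autocorrelation.**  The radial component v = **v**·ê_r is
  correlated over unordered site pairs, binned at one grid spacing
  (rounded to the nearest bin); for each bin C = Σv_iv_j/√(Σv_i²·Σv_j²)
  with the sums over first/second pair members, computed per frame and
  averaged.  Self-pairs populate the zero bin, so C(0) ≡ 1.  *Local
  coordination* is C linearly interpolated at 100 µm (a few cell lengths).
* **FTLE.**  Tracers start on the PIV grid and are advected with explicit
  Euler (one step per 3 min frame; RK4 available and used for analytic-flow
  checks), bilinear interpolation in space, piecewise-constant in time,
  over non-overlapping 2 h windows.  For each quad of four initially
  neighboring tracers, F is the central-difference (least-squares) linear
  map of final versus initial positions, C = FᵀF, and λ = ln λ_max(C) — the
  raw log, with no 1/(2T) normalization.  Quads losing a tracer off the
  interpolable domain are invalid; > 80 % invalid raises.  %(λ > ε) with
  ε = 1e−6 absorbs rounding.  Euler integrates the saddle test flow
  (kT = 1.2) to λ = 2.365 vs the closed form 2.4 — the documented ~1.5 %
  first-order integration bias, within the 5 % validation band.
* **Coarse-graining scales.**  σ(t) is the variance over sites and
  components of the field averaged over every sliding window of t frames,
  averaged over placements (computed via cumulative sums); σ(l) is the
  variance of block means over squares of side l.  Fits use trust-region
  least squares with all parameters ≥ 0, five log-spaced starts of the
  scale parameter, and tolerances 1e−12; σ of the *variance* (mean of
  component variances) is used throughout — the alternative readings
  (variance of speed, of the norm) change constants but not the decay
  scales.  Curves with < 5 % relative decay are reported degenerate
  (scale = NaN) rather than fitted.
* **Radial profiles.**  Per-site scalars are averaged in r/R bins of 0.05;
  sites beyond r/R = 1.1 are excluded.

## Density

Nuclei are localized Crocker–Grier style: difference-of-Gaussians bandpass
(σ = low/2 and high/2 for the 4 px and 30 px feature limits) kept in raw
intensity units, so the peak threshold (default 6) is on the camera's
grey-level scale; local maxima are found with a *circular* exclusion
footprint (radius 2 × low-pass size = 8 px — a square footprint would also
suppress diagonal neighbors out to 8√2 px), refined by intensity-weighted
centroids in a 4 px window, and de-duplicated (plateau peaks closer than
half the separation limit keep only the brighter).  Two spots 5 px apart
merge into one detection — the documented resolution limit of the 4/30
bandpass.  Fold change is count(t15)/count(t0); average density divides by
the mask area (or fitted circle area); radial profiles divide per-annulus
counts by annulus area in r/R bins of 0.05.

## Phenotype statistics

Replicates are paired by plate: the t-statistic per (metric, line) is
mean(d)/SE(d) over per-replicate differences d against the same-plate
control (all-zero d → 0; zero-variance nonzero d is degenerate and
raises).  Clustering uses correlation distance (1 − r), average linkage,
and scipy's exact optimal leaf ordering.  The leaf-ordered correlation
matrix is segmented by a greedy boundary search scored with BIC under a
two-population Gaussian model of the off-diagonal entries (within-block vs
between-block; variances floored at 1e−6; parameter count 2 for one block,
else 4 + number of boundaries).  The external block-splitting procedure
this emulates is not fully specified in the literature we follow, so this
likelihood is our documented, brute-force-verified choice.  Confidence
intervals are mean ± t_{0.975,n−1}·SD/√n, deliberately unadjusted for
multiple comparisons.

## Synthetic data: what it emulates, and what it does not

The generator's role is statistical, not photometric.  Velocity directions
use a **Gaussian copula**: a latent unit-variance Gaussian field carries
the spatial correlation (periodic Gaussian kernel, σ = correlation_length,
normalized by kernel energy so every pixel is exactly N(0,1)) and the
temporal persistence (AR(1) with coefficient e^(−Δt/τ)), and is mapped
through the von Mises quantile function.  The angle marginal is therefore
*exactly* von Mises(0, κ) at any correlation setting — a smoothing of raw
von Mises draws would shrink the dispersion — while the correlation scales
of the transformed field remain proportional to the latent ones (a
monotone transform rescales a Gaussian correlation function pointwise, so
distance scaling is preserved exactly).  Consequences used by the
validation suite:

* recovered angular deviation matches √(2(1−I₁(κ)/I₀(κ)));
* the fitted l_c and t_c are *proportional to* (not equal to) the
  generating correlation length and persistence time — the validation
  checks doubling ratios and monotone 3-point sweeps, with the
  proportionality constant established empirically;
* speeds are exactly `mean_speed`, so the speed estimator is exact by
  construction and speed carries no replicate variance in flow-level
  pipelines.

Two estimator-design details matter at the validation problem size
(40 × 40 grid, 120 frames, 5 seeds).  The marginal-law (κ = 2) check uses
weakly correlated fields (correlation 10 µm, persistence 10 min): under
the strongly correlated defaults the pooled sample has only ~5 × 10³
effective draws and the estimator's own Monte-Carlo error (~2.5 %) is
comparable to the 3 % validation band.  The l_c-doubling check fits the
two σ(l) curves over *scale-matched* block windows (1–10 vs 2–20 sites):
σ(l) for a doubled correlation length equals the original curve at l/2 in
the continuum, so matched windows make the ratio estimator unbiased up to
grid discreteness, whereas a common window biases it by the
range-dependent misspecification of the exponential-plus-offset model
(block-mean variance decays asymptotically as l^−2, not exponentially).

Sheet movies render a disk of radius R(t) = R₀ + rate·t centered far below
the frame, filled with band-limited speckle that advects with the mean
motion, over low-amplitude background noise, with the boundary perturbed
radially by smoothed AR(1) noise of amplitude `edge_roughness`.  The
speckle feature size defaults to 3 px: measured on this generator, ~10 px
features broaden the correlation peak enough to bias sub-pixel PIV and
wash out edge localization to ~5 px, while ~3 px features (the classic
particle-image diameter) achieve the engine's design accuracy — texture
trackability being the sole purpose of the speckle.  Nuclei images place
Gaussian spots (σ = 1.8 px) in the disk by rejection sampling against a
radial density profile with a minimum spacing of 6 px (random sequential
packing; infeasible requests raise).

None of this emulates: phase-contrast optics (halos, shading), cell-scale
texture statistics, proliferation or apoptosis, multi-sheet fields, or
uneven illumination.  Passing the synthetic validation therefore
demonstrates the *correctness of the estimators under the stated
statistical model* — not robustness to every imaging artifact of real
movies, which is what the exposed segmentation/detection parameters are
for.

## Pipeline scale defaults

Pipeline runs default to deliberately interactive problem sizes
(flow mode: 24 × 24 grids, 48 frames; movie mode: 256 × 256 px, tens of
frames); all sizes are configuration, and the validation suite uses the
larger sizes quoted above where a criterion depends on sampling error.
Seeds for (line, replicate) pairs are derived deterministically from the
run seed; a rerun with an identical config is bit-identical, and the run
manifest records the config hash and package version.

## Known limitations

* Offset-only multipass (no window deformation): strong shear within a
  window broadens the peak; rotation/shear validation is restricted to the
  small-deformation regime the assay operates in.
* Euler tracer advection carries O(Δt) bias (~1.5 % at kT = 1.2); switch
  to RK4 for analytic studies.
* The exponential σ(l) model is a fitting convention, not the true decay
  law; compare l_c values only between conditions measured with the same
  windows (the package's comparison helpers do this).
* The block-BIC likelihood is a reconstruction; alternative penalties can
  move boundaries on weakly separated matrices (the brute-force scorer
  `bic_for_boundaries` is exported for sensitivity checks).
* Edges that leave the lateral borders, multi-sheet images, and sub-pixel
  edge localization are out of scope.
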