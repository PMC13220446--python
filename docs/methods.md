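# Methods

This note documents the models, conventions, parameter choices and known
limitations of the `nanoscope` pipelines, in the order the data flow runs.

## Units and coordinate conventions

All public coordinates are nanometres and all times seconds.  Images use
the origin at the upper-left corner with y increasing downward; pixel
(i, j) (row, column) covers the half-open square
[j·s, (j+1)·s) × [i·s, (i+1)·s), so its centre is ((j+0.5)·s, (i+0.5)·s)
for pixel size s.  Localization CSVs are comma-separated with a mandatory
header; common exporter column names ("x [nm]", "x_nm", "x_px", ...) are
recognized, and pixel-unit tables are converted on read given the camera
pixel size (80 nm for the acquisitions this package models).

## Drift correction

Drift is estimated by absolute image correlation: the acquisition is cut
into 200-s windows, each window's 2-D localization histogram (10-nm bins)
is cross-correlated against the first window, and the correlation peak —
refined per axis by a 3-point quadratic fit, i.e. to sub-bin accuracy —
gives the window displacement.  Per-frame shifts interpolate linearly
between window centres with constant extrapolation outside.

Choices that matter:

- *Reference window.* All windows correlate against the first ("absolute"
  correlation) rather than against their predecessor; this avoids random
  accumulation of per-step errors.
- *Gauge freedom.* Image correlation determines drift only relative to the
  reference window's mean position.  The recovered trajectory therefore
  differs from the injected truth by a global translation (≈ the drift at
  the first window's centre); validation removes the mean offset before
  computing the RMS error.  Applying the correction translates the whole
  field uniformly, which no downstream statistic is sensitive to.
- *Trailing partial window.* A final window at least half full is included
  (centred on its actual span); otherwise acquisitions whose length is not
  an exact multiple of the window leave their tail constant-extrapolated,
  which dominated the RMS error in testing.
- Windows with fewer than 100 localizations (configurable) are skipped with
  a warning and bridged by the interpolation.

Under the validation conditions (≥ 500 localizations per window, linear
drift of ≤ 200 nm amplitude over 10,000 frames at 10 Hz) the recovered
trajectory is accurate to ≈ 6–8 nm RMS; the residual comes from quadratic
interpolation on histogram correlation peaks broadened by intra-window
drift.

## Blink tracks and merging

A fluorophore blinks over several consecutive frames; counting each
appearance separately inflates cluster occupancy.  Linking is greedy
nearest-neighbour between consecutive frames (gap 0 by default): candidate
links within the linking radius are taken in order of increasing distance,
ties broken by lowest row index, each end used once.  This is deterministic
for a given row order.  The default linking radius used in the validation
pipelines is 50 nm, ≈ 3.5× the per-appearance jitter of a 10-nm-precision
localization (successive appearances of one molecule differ by √2·10 nm).

Tracks with frame span outside 1–5 frames are removed — the 1–5 window is
the processing convention this package reproduces, and makes run lengths
above 5 frames (rare for genuine single molecules) drop out.  Surviving
tracks merge to one localization at the precision-weighted mean position
(unweighted if any member's precision is unknown), frame = first frame,
combined precision (Σσᵢ⁻²)^(−1/2).  A precision cut-off, when wanted, must
be given explicitly; no default is assumed because no published value
exists for these data.

Rendering integrates each localization's Gaussian exactly over every
lattice pixel (product of per-axis normal CDF differences) truncated at
4σ, so the image sums to the localization count to ≪ 1%.

## Cluster analysis

Grid segmentation anchors a 3000-nm grid at the ROI bounding-box minimum
corner and keeps a square iff the ROI polygon covers it entirely — an
exact geometric predicate (the documented fallback contract, corner plus
edge-midpoint sampling, is what the exact test replaces).  No anchor-offset
search is performed; the rule is deterministic.

DBSCAN uses ε = 20 nm, minPts = 5, with the ε-neighbourhood *including*
the point itself (the convention of the R `dbscan` package).  Border
points join the first cluster that reaches them in ascending scan order.
The implementation is scikit-learn's, which follows exactly this
convention; an independent O(n²) brute-force implementation (explicit core
graph + BFS) lives in the test suite and the acceptance script as the
cross-check.

Cluster geometry: convex-hull area (Qhull), equivalent-circle radius
√(A/π), density n/A.  Clusters with fewer than 3 non-collinear points get
area 0, radius 0 and density NaN rather than an error.

Ripley's K uses the isotropic edge correction on the square sub-region
window: each pair (i, j) is weighted by the reciprocal of the fraction of
the circle centred at i with radius d_ij that lies inside the window,
evaluated in closed form for rectangles (per-edge arc cuts minus
per-corner double counts) and capped at 100.  L(r) = √(K̂/π) is evaluated
on 110 equal steps to r_max = 2200 nm (20-nm steps; the grid density is a
package choice, the source method states none), and the summary statistic
is the *signed* maximum of L(r) − r, since the quantity is interpreted as
clustering strength; an absolute-value option exists.  Under CSR the mean
K̂(r) is within 2% of πr² for r ≤ r_max/4 (500 points, 3000-nm window,
200 replicates) and the mean signed max deviation is ≈ +7 nm — small but
positive, as expected for the maximum of a zero-mean fluctuating process.
Sub-regions are analyzed independently; clusters straddling a grid line
are counted in both squares, which inflates cluster density by ≈ 4% under
the validation conditions (parents within ≈ 2σ of a line).

## Radial profiling

Segmentation is automatic (Otsu threshold, connected components ≥ 10 µm²
by default, marching-squares outline, binary centroid); a fixed-threshold
option substitutes for the manual outlining the workflow derives from.
Ring assignment uses ρ = |p − c| / R(θ) with R(θ) the *first* crossing of
the outline along the pixel's direction; cells where rays cross the
boundary more than once (non-star-shaped) are flagged, and a
distance-transform fallback (ρ = 1 − dt/dt_max) handles shapes whose
centroid falls outside the mask.  Bin index = min(⌊ρ·50⌋, 49); every mask
pixel lands in exactly one ring and the counts are conserved.

Normalization divides each ring's MFI by the *innermost* ring's MFI — the
convention that makes profiles start at exactly 1.00 at the centre, which
is how the cohort profiles this mimics are reported ("respective inner
ROI" read as the central ROI; adjacent-ring normalization is available
behind a flag).  Cohort averaging is a per-ring mean and sample SD with
NaN rings skipped pairwise.  The periphery/centre summary is the mean of
the outer 10% of rings over the mean of the inner 10%.

## FRAP

Normalization follows the three published steps: subtract the non-bleached
reference, set the first post-bleach sample to exactly 0, scale the
pre-bleach mean to exactly 1.  Two deliberate choices:

- *Reference smoothing.* The reference ROI measures slow acquisition
  photobleaching, a smooth near-exponential decay.  Subtracting the raw
  reference injects its shot-to-shot noise into both bleached curves,
  inflating the error of a single-sample mobile-fraction read by ≈ 1.7×.
  The default therefore smooths the reference with a centered 9-sample
  moving average (3 min at the 20-s cadence — short against the 15-min
  recovery, so the bias on a smooth decay is negligible); `ref_smooth=1`
  restores raw subtraction.
- *Subtractive vs ratiometric.* The reference correction is subtractive,
  matching the published procedure.  Subtraction does not perfectly cancel
  *multiplicative* photobleaching: with decay e^(−λn) on all ROIs and
  equal baselines, the measured endpoint is 1 − (1 − A·r)·e^(−λΔn) rather
  than A·r, a bias of ≈ +0.015 at λ = 0.002/frame.  A ratiometric mode
  (divide by the reference rescaled to its pre-bleach mean) cancels it
  exactly and is provided behind a flag.

The prebleach baseline is the mean over the whole 2-min pre-bleach phase.
MF is read directly at the last sample ≤ 900 s (no model fit, no
extrapolation; optionally the mean of the last k samples).  RI =
MF(periphery)/MF(centre), undefined when MF(centre) ≤ 0.  `fit_recovery`
(A·(1−e^(−t/τ)) least squares) exists for simulation validation only; τ is
bounded above by 10× the post-bleach span, and fits that hit the bound are
flagged — a curve that never saturates (e.g. a linear ramp) is the
τ→∞ limit of the model and must not pass silently.

Under the validation noise model (independent Gaussian noise of SD 0.02 ×
pre-bleach on each of the three raw traces) the median mobile-fraction
error over the A ∈ {0.2…1.0} × τ ∈ {60, 120, 300 s} grid is ≈ 0.019.
This sits close to the 0.02 claim because the procedure reads MF from a
single noisy sample anchored to another single noisy sample; a median over
a few hundred draws fluctuates by ≈ ±0.0013.  With raw reference
subtraction the median rises to ≈ 0.023.

## Kymographs and flow speeds

Unsharp masking uses I′ = (I − a·G_r(I))/(1 − a) with a = 0.8 and Gaussian
σ = 5 *pixels* (the source protocol prints "5 nm", which is sub-resolution
and read as a units typo; the radius is exposed as a parameter).  Periodic
boundary handling preserves the mean exactly.

The kymograph samples each frame by bilinear interpolation at unit-pixel
spacing along the user line (averaging across an optional perpendicular
width); rows stack in time order.  Fiber detection is automated where the
original measurement was manual: the kymograph is robustly z-scored
(median/MAD), lightly smoothed, thresholded at 2.5 robust SDs, candidate
streaks found by probabilistic Hough, and each candidate refined by
per-row intensity centroids in a window around the predicted position
followed by a least-squares line fit (two rounds).  The refinement is what
delivers 2-nm/s resolution: Hough angular quantization alone is far too
coarse for a 0.02 px/frame slope.  Speeds are signed positive toward the
cell centre (retrograde); origin = fitted position at the streak's first
visible row as a fraction of the line, classed central (< 1/3), peripheral
(> 2/3) or middle.  At contrast-to-noise ≥ 3 the validation recovers
speeds across 2–30 nm/s with ≤ a few % error and full recall; pure-noise
kymographs return an empty list in ≥ 95% of seeds.

## Synthetic data

The generators define the validation conditions; all draw from a single
seeded NumPy Generator and return complete ground truth.

- *Localizations*: a Thomas process — parents Poisson(κ·A) uniform in the
  window, offspring per parent Poisson(μ) displaced N(0, σ²I), uniform
  Poisson background — with one blink run per molecule (length uniform on
  1–5 frames by default, configurable beyond to make the track filter
  consequential), per-appearance Gaussian localization error, and linear
  drift added cumulatively.  Validation conditions: κ = 2 µm⁻², μ = 30,
  σ = 15 nm, background 5 µm⁻², 9 × 9 µm window, 10,000 frames at 10 Hz,
  10-nm precision, drift 0.05 nm/frame.  The 10-nm precision and 10-Hz
  rate are package choices in the typical dSTORM range.  A Thomas process
  is used because cluster-recovery validation needs a parametric clustered
  truth, not because the real receptor distribution is claimed to be one.
- *Synapse images*: star-shaped outline R(θ) = R₀(1 + Σ aₖcos(kθ + φₖ))
  with random phases; per-pixel ρ computed by the same outline-following
  convention as the analysis; radial presets flat, linear, and
  "centralized" (raised cosine from 1 to the contrast c, default 0.46 —
  the regime the real CD40L profiles motivate); optional central Gaussian
  cluster and concentric rings; actin channel = uniform fill + brighter
  cortical rim.  Gaussian read noise, optional Poisson.
- *FRAP*: closed-form recovery floor + A(1−e^(−t/τ))·(F₀−floor) with 2-min
  pre-bleach, 20-s cadence, 900-s recovery, optional multiplicative
  per-frame photobleaching on all ROIs, Gaussian noise per raw trace.
  Defaults A = 0.66 (centre) / 0.80 (periphery), τ = 120 s — the
  mobile-fraction regime the analysis is designed for.
- *Flow movies*: Gaussian features translating along the central row at
  specified signed speeds from specified origins; 100-nm pixels, 1-s
  frames (live actin imaging cadence), 300 frames.

What the generators do **not** emulate: fluorophore re-blinking and
photophysics beyond a single run, detector-specific (EMCCD/sCMOS) noise,
sample-plane inhomogeneous background, cell motion or shape change during
acquisition, out-of-focus light, and multi-cell crowding.  Passing the
closed-loop tests therefore demonstrates correctness of the estimators
under the stated statistical models, not performance on any particular
experimental dataset; the published cohort numbers (e.g. periphery values
0.46/0.64, mobile fractions 66–100%) require the original images and are
deliberately not targets.

## Test and validation sizes

The suite validates with 200 random DBSCAN instances against the brute
force oracle, 200 CSR replicates for Ripley calibration, 50 seeds of the
end-to-end Thomas pipeline (medians within 20% of κ and μ), 2 drift seeds,
a 15-cell A × τ FRAP grid with 20 seeds per cell plus 100 seeds for the
restriction index, and 16 kymograph streaks spanning 2–30 nm/s; the
acceptance script uses the same conditions with 100/20-seed batches.
These sizes keep the median estimates stable while the whole suite runs in
a couple of minutes on one CPU.
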