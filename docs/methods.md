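# Methods

This note documents the models, estimators, numerical choices and
limitations behind `monolayer_mech`, in the order of the analysis
pipeline.  Units are µm, minutes (velocities µm/h where stated), seconds
for AFM dwell times, mN/m for tensions and Newtons for forces; every
file format carries its units in the header.

## Synthetic data as study material

None of the raw data this kind of analysis is usually run on
(phase-contrast movies, segmentation masks, AFM force curves) is bundled;
instead every stage is validated against a seeded generator whose ground
truth is known exactly.  The generators define the study conditions for
all tests and for `scripts/acceptance.py`:

- **Velocity fields.**  Each component is an independent stationary
  Gaussian random field with isotropic covariance σ²·exp(−r/ξ)
  (Gaussian kernel available), plus a uniform drift.  Fields are
  synthesized by circulant embedding: the covariance is evaluated on a
  2× padded torus, its FFT gives the embedding eigenvalues, and white
  noise filtered by their square root yields an exactly stationary field
  in O(N log N); slightly negative embedding eigenvalues of the
  exponential kernel are clipped, which biases the variance by <5%.
  The exponential kernel is the default because measured velocity
  correlation curves decay monotonically to an x-intercept.  Gaussianity
  is an assumption of the stand-in, not a claim about real monolayers:
  real fields have non-Gaussian tails, finger instabilities at the edge
  and temporal persistence, none of which the generator emulates, so
  passing tests certify the estimators, not biology.
- **Speckle pairs.**  Band-limited noise (Gaussian-smoothed, σ = 1 px —
  fine texture comparable to camera grain, which is what sub-pixel PIV
  accuracy requires) advected by the field with bilinear sampling and
  periodic boundaries.  A displacement beyond half the interrogation
  window triggers a warning because correlation PIV cannot recover it.
- **Tessellations.**  Voronoi labels of points sampled from a log-normal
  random density field (smoothing length ≈ one mean cell diameter);
  denser regions give smaller cells, so the log-field σ controls the
  right skew of the area distribution.  The map from `skew_target` to σ
  is a monotone interpolation table calibrated once (16-seed means at
  n = 500) and frozen in source.  Targets below the intrinsic
  Poisson-Voronoi skewness (≈1) are unreachable by random seeding;
  explicit point lists (e.g. symmetric lattices, skewness 0) bypass the
  sampler.  Sample skewness of heavy-tailed areas fluctuates strongly at
  n = 500 (seed-to-seed s.d. ≈ 0.3–0.4), so skewness checks average over
  seeds.  The truth record carries the exact per-cell pixel areas of the
  emitted mask.
- **Tracks.**  Brownian (i.i.d. Gaussian steps, MSD = 4Dτ), ballistic
  (fixed random heading, MSD = v²τ²) and persistent motion (exact
  discretization of a stationary Ornstein–Uhlenbeck velocity with
  persistence time τ_p and rms speed v).
- **Force curves.**  The forward capped-shell model (below) times
  (1 + noise_rel·N(0,1)) — multiplicative noise, as deflection noise
  scales roughly with signal on these instruments.
- **YAP images.**  Two-level intensity images with a closed-form
  nucleus/whole-cell ratio.

Determinism is a contract: one `numpy.random.Generator` per call, seeded
explicitly; identical (seed, kind, parameters) give bit-identical
output, and the pipeline writes a SHA-256 manifest to make reruns
checkable.

## Velocimetry

**Order parameter.**  Mean of cos α over masked vectors, α measured
against the `migration_axis` (the edge normal, which equals the mean
migration direction in an expanding monolayer — reproducing order 1 for
edge-directed motion).  Zero-magnitude vectors are excluded rather than
counted as zero because cos α is undefined at zero velocity.

**Edge profiles.**  Distance from the free edge is measured along the
migration axis per grid row/column by default (valid when the edge is
roughly aligned perpendicular to the axis, as in a well-prepared assay);
a Euclidean-distance-transform option covers irregular masks.  Bins are
one mesh wide; the first two bins are kept but flagged, since
window-based velocimetry is biased within a window of the edge.

**Spatial autocorrelation.**  Computed on the velocity component
perpendicular to the migration axis, mean-subtracted — this isolates
collective fluctuations from the mean drift; a both-components variant
exists but is non-default.  The field is first cropped to the largest
axis-aligned rectangle inscribed in the monolayer mask (a deterministic
stand-in for cutting leader-cell fingers by hand).  The 2-D correlation
is FFT-based with per-lag pair-count (unbiased) normalization, forced
exactly symmetric under lag negation, and normalized to AC(0) = 1.
Radial averaging uses annuli one mesh wide out to half the half-extent,
beyond which too few lags contribute.

**Correlation length.**  The radial curve is integrated up to its first
linearly interpolated zero crossing (first bracket on ties) to exclude
anti-correlated tails.  The *raw* weighted integral ∫ r·AC dr has units
of length²; the default output is the first-moment normalization
L = ∫r·AC/∫AC, which has length units and equals ξ exactly for
AC = exp(−r/ξ) on [0, ∞) — consistent with correlation lengths being
reported in µm.  Trapezoidal quadrature throughout; curves with fewer
than three points are rejected.  Because a single 128×128 field gives a
noisy AC tail (the zero crossing wanders), correlation curves are
averaged over frames/realizations *before* integrating — the estimator
recovers ξ = 30 µm within 15% as the mean over 20 fields, and its
single-field estimates scatter much more.

**PIV.**  Per window (32 px, 50% overlap): mean-subtracted normalized
cross-correlation with per-lag overlap normalization (removing the
window-margin bias on the peak's neighbors), peak search restricted to
± half a window, and 1-D parabolic sub-pixel refinement per axis.
Filters mirror standard practice: peak height < 0.3 (featureless),
first/second-peak ratio < 1.1 (the second peak is searched outside a
3 px exclusion zone), and a 4-standard-deviation global cut per
component.  Temporal down-sampling to 1 frame/7.5 min is a documented
pre-processing option, not enforced.

## Morphometrics

Coordinates are 0-based pixel indices, origin top-left, x = column;
boundary vertices sit at pixel centers.  For each label the one-pixel
outline ring is subtracted (binary erosion) so touching cells never
share pixels, then the outer contour of the largest remaining component
is traced (Moore neighborhood, Jacob's stopping criterion).  Labels with
fewer than 4 interior pixels are skipped with a warning; border-touching
labels are kept but flagged as geometrically truncated.

Area is the shoelace formula on the contour polygon (verified against a
Pick's-theorem pixel-counting oracle on random lattice polygons);
centroids are first-order moments of the pixel set.  The aspect ratio
averages two branches: (i) the axis ratio of the moments-equivalent
ellipse, computed in closed form from the polygon's Green's-theorem
second moments — exact (ratio a/b) for rectangles and rotation-
equivariant — and (ii) the side ratio of the minimum-area rotated
rectangle (rotating calipers over the convex hull).  An algebraic
least-squares conic fit is available as `method="conic"` but is not the
default: such fits are provably biased high for rectangle-like shapes
(≈2.11 for a 2:1 rectangle), while enclosing rectangles bias low for
rounded shapes — averaging a high- and a low-biased branch is the
intent, and the moments ellipse keeps the calibration cases exact.  If
the ellipse branch is infeasible (<5 vertices, degenerate moments) the
rectangle branch alone is returned with a flag rather than dropping the
cell.

Area skewness is the biased Fisher–Pearson moment coefficient
g₁ = m₃/m₂^{3/2} (not the bias-corrected G₁): with hundreds of cells the
difference is negligible and g₁ is the plainest reading of "skewness";
it is NaN for constant samples and undefined below n = 3.  Density is
cells per occupied monolayer area.  The YAP ratio is mean nuclear over
mean whole-cell intensity per cell, with ratios > 1 excluded (and
counted) by default as segmentation failures.  Cell volume is the
area × height slab product, with the isotropic cylinder expansion
scaling radius and height by the cube root of the volume ratio; the
height itself is a numeric input (it is read manually from side views in
practice, which the package does not automate).

## Tracking and MSD

Linking minimizes total squared displacement per consecutive frame pair
(rectangular assignment with per-track/per-detection "no match"
alternatives priced at the squared search radius), so any link longer
than `max_disp_um` is rejected in favor of ending/starting a track; a
greedy nearest-first variant exists for speed but is non-default.
Tracks may vanish for up to `memory_frames` frames and resume within the
same search radius; positions inside gaps are never invented, and MSD
pairs spanning gaps use the stored endpoints.  Tracks shorter than
`min_length` points (default 5) are discarded as spurious.  Defaults
(4.6 µm search radius — the stated values being a µm/px units slip for
8–10 px at 0.576 µm/px —, memory 4, 7.5 min frames) suit monolayer data.

Mean speed averages |Δx|/Δt over consecutive steps, which normalizes for
frame rate.  The ensemble MSD averages squared displacements over all
cells and time origins; lag 0 is included as 0 and empty lags are
omitted.  Power-law fits are unweighted least squares on
(log τ, log MSD) with nonpositive points excluded (≥3 must remain);
amplitude a is exp(intercept) in µm²·min⁻ⁿ.  Morphology binning assigns
each track the *median* of its per-point attribute (robust to
segmentation outliers over a track's lifetime), partitions into
half-open bins [k·w, (k+1)·w) — an attribute exactly on an edge joins
the upper bin — and reports the fitted exponent and the power law
evaluated at 60 min per bin, suppressing bins with fewer than 3 tracks.
No drift correction is applied by default.  Exponents are reported
without interpretive labels.

## Capped-shell mechanics

Geometry: a spherical cap of base radius R₁ and contact angle φ (cap
sphere radius R₁/sin φ, height h₀ = R₁(1 − cos φ)/sin φ) on a fixed
cylindrical footprint; a conical indenter of half-angle ϑ (θ = 90° − ϑ;
default ϑ = 17.5°, the nominal side angle of the usual soft cantilever,
configurable) pushes the apex down by δ < h₀.

**Shape solution.**  The deformed surface is a cone frustum in contact
from the apex out to radius r₁, continued by a free spherical cap
through the *fixed* base circle.  Prescribing the apex depth and
requiring the free sphere to pass through both the base circle and the
cone contact circle leaves the sphere radius in closed form as a
function of r₁; the enclosed volume (analytic solid of revolution) then
makes volume conservation a 1-D root-finding problem in r₁, solved by
bisection (brentq, xtol 1e-13).  Volume residuals are ≤1e-10 relative
across all four presets, verified against independent quadrature.
Note the surface is allowed a kink at the contact circle: enforcing
tangency there as well would overdetermine the system once the base
circle, apex depth and volume are all fixed.  The area strain ε is the
relative dilation of the total apical surface (contact cone + free cap)
over the undeformed cap; the free-cap-only variant is also computed.
ε is continuous, monotone in δ, and *small*: ≤0.2% for the `wt` preset
and ≤1.7% (the maximum over presets, `dkd-small` near full depth).

**Force and time dependence.**  The force bracket is evaluated in the
algebraically equivalent form 2πT·R₁r₁(r₁ sin φ + R₁ sin θ)/(R₁² − r₁²),
which vanishes *exactly* at r₁ = 0 in floating point.  During the
constant-height dwell the shape is frozen and the force follows
T(t) = T₀ + K_A⁰(t/t₀)^(−β)·ε, evaluated with the deformed contact angle
φ_eff (the undeformed angle can be passed explicitly).  The reference
time t₀ = 1 s is a convention and is always reported with K_A⁰; the
first fitted sample is at t ≥ 1 ms to stay clear of the power-law
singularity.

**Fitting.**  Bounded nonlinear least squares over (T₀, K_A⁰, β) with
T₀, K_A⁰ ≥ 0, β ∈ [0, 1], residuals scaled by the peak force so
optimizer tolerances (1e-12) act on relative error.  Initialization
matches the curve endpoints (T₀ from the final force, K_A⁰ from the
initial drop, β = 0.5) plus four deterministically perturbed restarts;
the lowest-cost converged run is kept.  Identifiability: at β = 0 only
the lump T₀ + K_A⁰ε is determined, so the fit compares its best solution
against the flat model and, when they tie, reports the lump (as T₀, with
K_A⁰ = β = 0) under a `collinear` flag; any fitted β < 0.05 is flagged
likewise.  Noise-free round trips recover all three parameters to
≤1e-6 relative.  Under noise the recovery is structurally asymmetric:
because ε is small, the viscoelastic force component K_A⁰·ε·(t/t₀)^(−β)
is ~0.1% of the total force for wild-type-like parameters
(T₀ = 0.35 mN/m, K_A⁰ = 0.02 mN/m, β = 0.5), so with 1% multiplicative
noise T₀ is recovered to ≲0.1% while K_A⁰ and β are near the information
limit — the global least-squares minimum falls on a log-relaxation ridge
(large K_A⁰, β → 0⁺) for roughly half the noise realizations, and the
collinearity flag marks these.  The fit report should therefore be read
as: T₀ is robust; K_A⁰ and β require either low-noise data or a larger
imposed area strain than this geometry admits.  Contact-point and
baseline determination on raw instrument curves is out of scope; input
curves are assumed baseline-corrected with known δ.

**Tether tension.**  T_t = F_t²/(8π²κ), κ = 2.7 × 10⁻¹⁹ J by default;
pure arithmetic, reported in mN/m.

## Pipeline and formats

CSV files are comma-separated UTF-8 with a mandatory header and
`#`-prefixed metadata (units always declared; µm/h velocities, µm
lengths, seconds for dwell times); floats are written with `repr` and
read with round-trip precision so write→read is bit-exact.  Label masks
are single-channel 8/16-bit TIFFs.  Force curves are two-column CSV with
a JSON sidecar holding geometry and indentation; vendor AFM formats are
out of scope.  The pipeline executes a configured stage list in order,
never mutates inputs, echoes the resolved config (seed and stages — the
output directory is a runtime choice and is not part of the run's
identity) and writes a checksum manifest; deterministic configs
reproduce manifests bit-identically.

## Problem sizes

Defaults were chosen so each check completes in seconds on one core
while leaving the estimators in their intended regime: 20 × 128×128
fields for correlation-length recovery, 200 tracks × 200 frames for MSD
fits, 50 walkers for linking accuracy, 6 × 500 cells for tessellation
skewness, 500-sample dwell curves and 20 noise seeds for the mechanics
recovery suite.

## Known limitations

- The edge-distance default assumes an axis-aligned migration direction;
  oblique fronts need the EDT option.
- The PIV stage is single-pass with a fixed window; it is a validation
  tool for the statistics chain, not a replacement for a full
  multi-pass/deforming-window PIV package.
- The tessellation generator controls the area distribution, not cell
  shapes; its aspect-ratio statistics are those of (density-modulated)
  Voronoi cells.
- Segmentation itself, leader-cell identification, and monolayer-mask
  detection are out of scope; masks and detections are inputs.
- The capped-shell model admits only small area strains for δ < h₀, with
  the fitting consequences described above.
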