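# Methods

## Data model

A *trajectory* is the time-ordered sequence of 3D centre coordinates
(μm) of one tracked focus, sampled every `frame_interval` seconds
(default 10 s, about 100 frames per movie). Frames are 0-based; a frame
with no recorded position is a *gap*, stored as a NaN row, never as a zero
coordinate. A focus that appears mid-movie therefore carries leading gaps.
In CSV form a gap is simply an absent row, reconstructed from the frame
index on read. One consequence: gaps trailing the last observed frame of a
whole file leave no trace in the frame grid and do not survive a
round-trip; leading and interior gaps do.

Manual tracking produces a single consensus coordinate table per movie;
no provision is made for merging discordant annotations. Axial (z)
coordinates are the caller's responsibility (stack index × step size,
which varies per movie); the reader accepts a per-file `z_scale` factor.

## Kinematics

Step displacements are Euclidean 3D distances between consecutive
observed frames; pairs spanning a gap are dropped. Speeds divide by the
frame interval. The rolling (SMA) speed uses a window of 3 successive
intervals (30 s) with stride 1, computed per gap-free segment — a window
never spans a gap. The speed trend is an ordinary least-squares line of
SMA speed against the mean window end-time; a clearly negative slope
reads as a slowing focus, a slope near zero as static. Two pooling
conventions exist for "average speed across foci" (per-focus means pooled,
or all intervals pooled); `mean_speed` exposes both and privileges
neither, since they differ when trajectories have unequal lengths.

Run lengths are the same per-interval displacements expressed in nm and
binned into contiguous 200 nm bins from 0 — at 10 s sampling, "net
distance traveled in 10 s" and the single-interval displacement are the
same quantity, and the 200 nm width matches the granularity in which
run-length ranges are conventionally reported for these foci.

## Movement model

Each step is modelled as partially correlated with the previous one:

    y_{t+1} = y_t + γ T(θ) d_{t−1} + ε_t,

with γ the directional correlation, T a rotation by the mean turn angle
θ, and ε_t an isotropic Gaussian random-walk displacement with per-axis
standard deviation Σ (μm/step). Design choices, made where the model as
stated leaves freedom:

* **T = identity during estimation.** In 3D a single angle does not
  determine a rotation matrix (the axis is unspecified). Systematic
  turning is absorbed into the residual, and θ is reported descriptively
  as the mean arccos of normalized consecutive step dot products
  (zero-length steps skipped).
* **Single behavioural state.** No hidden-state switching; one (γ, θ, Σ)
  triple per trajectory.
* **Estimator: conditional least squares (CLS), no intercept,
  components pooled.** Regressing each displacement vector d_t on its
  predecessor d_{t−1} with x, y, z stacked gives the closed form
  γ̂ = Σ_t d_t·d_{t−1} / Σ_t |d_{t−1}|², which coincides with maximum
  likelihood under isotropic Gaussian residuals. The implementation uses
  `lstsq`; the closed form is kept in the test suite as an independent
  oracle (agreement to 1e−9). Σ̂ is the RMS residual norm per step
  divided by √3, i.e. a per-axis standard deviation — outputs are
  labelled as such since "variability" could equally denote a variance.
* **Degenerate inputs.** An all-zero-displacement trajectory has an
  *undefined* γ (division by zero), reported as an error rather than 0.
  At least 4 gap-free frames (2 consecutive displacement pairs) are
  required; (d_t, d_{t−1}) pairs spanning a gap are excluded.
* **Classification.** Movement is "random" when γ is strictly below the
  threshold (default 0.5); a fit exactly at the threshold is "directed".

Properties verified by the tests: γ = 1 and Σ = 0 in the constant-step
(ballistic) limit; scale invariance (γ, θ unchanged, Σ linear under
coordinate rescaling); and parameter recovery on simulated unconfined
walks — over γ ∈ {0, 0.3, 0.6, 0.9} × Σ ∈ {0.05, 0.2} μm with 500 steps
and 20 replicates, the mean absolute error of γ stays below 0.05 and the
mean Σ within 10% relative. Confinement biases γ̂ downward (wall
reflections anti-correlate successive steps); this is characterized as a
direction-only property test, not corrected. Anisotropic sampling
(coarser z) is likewise not corrected.

## Cell geometry

Ellipsoid volumes read the three measured *full* axis lengths as
diameters: V = (4/3)π(l_x/2)(l_y/2)(l_z/2). This is the only
dimensionally conventional reading of V = (4/3)πabc when the inputs are
end-to-end extents.

The conceptual cell sphere is fitted from ≥4 non-coplanar membrane edge
points by algebraic least squares (the linear system |p|² = 2c·p +
(R² − |c|²)), exact on noiseless spheres; with only diameter
measurements, R is the mean diameter halved and the centre is the
centroid of whatever edge points exist (centre placement with diameters
alone is otherwise indeterminate, so edge points are required for it).
The automatic method prefers the edge fit when ≥6 points are available.

An aggregate at distance r from the centre maps to relative periphery
distance (R − r)/(2R), clipped to [0, 0.5]: 0.0 on the membrane, 0.5 at
the centre, linear in between. Manual membrane coordinates make slightly
outside-sphere aggregates (r > R) inevitable; these clip to 0.0 with a
warning rather than triggering a re-fit.

## Synthetic data

The simulator runs the movement model generatively (T = identity):
d_t = γ_true d_{t−1} + ε_t, ε_t isotropic Gaussian with per-axis scale
σ_true, inside a reflecting sphere of radius `cell_radius` (specular
radial fold, which preserves the step-length distribution; rejection
sampling would not). γ_true ≥ 1 is rejected as nonstationary. Focus size
can grow linearly in volume (μm³/step) from an initial volume, and
σ_true may be a function of current volume to emulate size-dependent
mobility. All generators take integer seeds and are bit-reproducible.

Defaults are the study conditions of the tracked movies: 100 steps at
10 s, cell radius 2.5 μm (a typical ~5 μm haploid yeast diameter).
The two presets encode the observed strain contrasts:

* `wildtype` — 5 foci in 5 cells, one per cell; per-axis σ = 0.75/1.596
  ≈ 0.470 μm so the mean 3D step is ~0.75 μm per 10 s (1.596 = 2√(2/π)
  is the chi-3 mean); growing volumes with mobility ∝ v^(−2/3), so foci
  slow as they mature; 88% of scored cells drawn with a single aggregate.
* `act1-122` — 11 foci in 6 cells: six large static foci (σ = 0.18 μm)
  and five small mobile ones (σ = 0.50 μm), overall mean step ~0.55 μm
  per 10 s; 45% of scored cells drawn with a single aggregate, the rest
  with 2–5.

Aggregate positions draw the radial coordinate with density ∝ r^(2+b) on
[0, R]; b = 0 is uniform in volume (mean relative periphery distance
exactly 1/8, since E[r] = 3R/4), larger b biases positions toward the
membrane. Plate counts are Binomial(cfu_total × density_factor,
true_frequency), with preset frequencies 0.006 (wildtype) and 0.0035
(act1-122, ~1.7-fold lower), three transformant replicates each.

What the generator does *not* emulate: localization error and its
time-correlation, anisotropic z sampling, deconvolution artifacts,
cell growth and budding during the movie, focus fusion/fission, and
non-spherical (budded) cell shapes. Passing recovery tests therefore
show the estimators are correct for the model's data-generating process,
not that real tracking data satisfy that process.

## Statistics

Size-vs-movement relations use OLS with a two-sided slope test
(`scipy.stats.linregress`); a constant response is reported as slope 0
with r² = 0 and p = 1 rather than NaN. Group comparisons delegate to
Welch's t (default), the paired t (equal lengths required; zero
within-pair variance is a degenerate-case error) and the two-sample
Kolmogorov–Smirnov test (sensitive to spread changes, e.g. periphery
distance distributions widening under actin-depolymerizing drugs).
P-values are reported unadjusted — one test per planned comparison —
with an optional Holm helper (`adjust_pvalues`) for users running larger
families.

Induction frequency is colonies on the selective plate divided by total
CFUs plated there (CFU count on the permissive plate × the plating
density factor, default 100). Fold changes are ratios of mean
frequencies across transformant replicates; because occasional extreme
replicates occur, the averaging convention is exposed
(`mean_induction_frequency(..., exclude_above=...)`) with no exclusion
by default.

## Problem sizes and tolerances

Exact identities (periphery anchors, ballistic limits, closed-form
volumes, oracle equivalences) are asserted at 1e−9–1e−12. Stochastic
checks use fixed seeds and problem sizes chosen so Monte-Carlo error sits
well inside the asserted band: 16 × 100-step walks for the randomness
ceiling (sampling SD of γ̂ ≈ 0.06, so the 0.4 bound is ~6 SDs away),
160 × 500-step walks for the recovery grid, and 2 × 10⁴ draws for the
uniform-periphery mean (SE ≈ 7 × 10⁻⁴ against a 5 × 10⁻³ tolerance).
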