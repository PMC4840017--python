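# Methods

This note records the models, numerical choices and known limitations behind
`nirstopo`, in the order data flows through the pipeline.

## Optics

Differential, two-wavelength continuous-wave spectroscopy only. The modified
Beer–Lambert law is inverted per sample and channel as a 2×2 linear solve;
units are fixed (α in mM⁻¹cm⁻¹, source–detector distance in cm, ΔHbO/ΔHbR in
mM) and never rescaled implicitly. The conversion is singular when the
extinction-coefficient determinant c = α_H(λ₁)α_Q(λ₂) − α_H(λ₂)α_Q(λ₁)
vanishes; construction fails when |c| < 1e-12 × the product of the largest
coefficients, because a near-singular inversion would amplify measurement
noise into the concentration estimates.

Default extinction coefficients are shipped as a small table derived from the
Gratzer/Prahl hemoglobin spectra (eight common wavelengths, ~1% rounding) and
are overridable; they are a documented convention, not a ground truth. The
default differential-pathlength factor is the general age- and
wavelength-dependent polynomial of Scholkmann & Wolf (2013), valid for
690–880 nm; a plain `{wavelength: value}` table may be supplied instead.
Partial-volume correction and >2 wavelengths are out of scope.

## Temporal preprocessing

Fixed order: motion correction → band-stop → DCT high-pass → downsample.
All stages are channel-wise independent; all but motion correction are
linear.

- **Motion artifacts** are detected per channel where the moving SD (default
  window 1 s) exceeds 3× its median; each contiguous segment is replaced by
  a heavily smoothed spline fit plus a linear ramp matching the neighbouring
  untouched samples, so baselines re-join continuously and samples outside
  segments are returned bit-identical. This moving-SD + spline scheme is an
  interpretation of common practice (MARA-style); both parameters are
  exposed.
- **Physiological oscillations** (respiration ~0.25 Hz, cardiac ~1 Hz) are
  removed with 5th-order Butterworth band-stops at 0.12–0.35 and 0.7–2.0 Hz,
  applied forward–backward. Zero-phase filtering avoids phase-distorting the
  hemodynamic response at the cost of doubling the effective order.
- **Drifts** are removed by projecting out an orthonormal DCT basis with
  frequencies below 1/64 Hz (constant included); the projection is
  idempotent. Note the commutation of band-stop and high-pass holds exactly
  only for ideal infinite-length LTI operators; on finite series the two
  orderings agree to ~1% RMS in the interior, dominated by spectral leakage
  into the drift basis and filtfilt edge transients.
- **Downsampling** (default 10 → 1 Hz) accepts integer ratios only, to avoid
  resampling-kernel ambiguity. The anti-alias filter is a zero-phase FIR
  (20·q + 1 taps): unlike the common Chebyshev IIR default, its DC gain is
  exactly one, so constant signals survive to machine precision.

## Within-subject GLM

The canonical HRF is the double gamma with onset 0 s, peak 6 s and
undershoot peak 16 s; dispersions (1 s) and undershoot ratio (1/6) are
conventional defaults, configurable, since only the three delays are
constrained. Events are delta sticks (boxcars when duration > 0) convolved
with the HRF and, by default, its temporal derivative (raw finite
difference, not orthogonalized); a constant confound is always appended
because Δ-series retain arbitrary offsets after filtering.

Serial correlation is modelled as a single global AR(1): the coefficient is
the pooled lag-1 autocorrelation of OLS residuals across all channels
(clipped to ±0.99), and the model is refitted once after whitening with the
banded square root S of V⁻¹ (innovations form) — a Cochrane–Orcutt-style
single pass rather than full ReML, which the two-level analysis does not
require because only the contrast values, not first-level variances, are
carried to the second level. Degrees of freedom are reported as M − L
without an AR-induced correction, for the same reason. Whitening is
estimated at the analysis rate (after downsampling).

## Scalp geometry

Channel MNI coordinates are required input (subject-space registration via
anatomical databases is out of scope); when head center/radius are not
supplied, a least-squares sphere is fitted through the optode and channel
positions. The 3D canonical surface is an icosphere (subdivision 4 →
2562 vertices by the 10·4^s + 2 rule). The 2D surface is the
azimuthal-equidistant projection about the vertex — planar radius equals
arc length from Cz, azimuth preserved — on a 64×64 grid whose extent is
chosen so the channel disc inscribes the grid; the mm pixel size is recorded
in the NIfTI affine. The search mask keeps pixels/vertices within a support
radius (default 30 mm, the optode separation scale) of any channel;
formally the mask is also intersected with the channel convex hull dilated
by the same radius, but since every channel lies in the hull that
intersection never removes anything, so the implementation is the plain
union of balls/caps.

The synthetic 52-channel probe wraps a 3×11 alternating source–detector
array over the forehead band of an 85 mm sphere. A regular grid cannot be
flattened onto a sphere, so separations compress toward the vertex row
(~19–30 mm against the 30 mm nominal); this mirrors the cap deformation of
real whole-forehead montages and is irrelevant to the statistical machinery
the probe exists to exercise.

## Interpolation

The 2D path is piecewise-linear (Delaunay barycentric weights, precomputed
once per layout as a sparse operator), exact at channels, undefined outside
the channel hull — extrapolation is deliberately avoided because group
overlap is only meaningful where channels support the map. All explicit
smoothing lives on this path: an isotropic Gaussian of default FWHM 14 mm
(σ = FWHM/2√(2 ln 2)), renormalized over defined pixels so constants are
preserved and edge pixels are unbiased.

The 3D path is the order-4 spherical spline. The Legendre series for
g_m(x) is summed by the stable three-term recurrence and truncated when the
term bound (2n+1)/(n(n+1))^m falls below 1e-10 (~30 terms at m = 4). The
augmented symmetric system enforcing Σk = 0 and channel reproduction is
solved directly and polished with mixed-precision iterative refinement
(extended-precision residuals): the kernel is so smooth that close channel
pairs produce tiny eigenvalues and large coefficient norms, and the
refinement drives the reproduction error — which equals the system
residual — to ~1e-10. No ridge term is applied by default: any ridge δ
perturbs channel reproduction by ~δ·‖k‖, which for dense layouts violates
the exactness the interpolant is defined by; a `ridge` parameter remains
for deliberately regularized fits. No additional smoothing is applied on
the mesh; the spline's implied smoothing is the only one.

Limits of exactness: with near-coincident channels (<~0.2°) coefficients
reach ~1e10 and double-precision *evaluation* alone carries ~1e-5 error, so
exact reproduction is numerically meaningless there; real optode layouts
(centimetre separations) are far from this regime, and duplicate channels
are rejected with an explicit error.

## Second level and inference

The summary-statistic random-effects model is ordinary least squares on the
stacked subject contrast images over the intersection of subject masks; the
residual variance per location estimates σ_w² + σ_b² jointly, and the t-map
has N − P degrees of freedom. Locations with variance at machine-precision
zero are flagged NaN rather than raising. For a one-sample design the
statistic reduces exactly to the classical one-sample t.

Inference is one-sided (contrast direction explicit). Two routes:

- **Bonferroni over channels** on the un-interpolated contrast vectors.
- **RFT over the surface**: smoothness is estimated from the second-level
  standardized residuals (the only residuals the summary-statistic pipeline
  has) via the variance of their spatial derivatives, FWHM =
  √(4 ln 2 / λ) per dimension (finite differences on the grid, per-edge
  directional derivatives on the mesh, where isotropy makes any direction
  representative). Resel counts follow the standard construction: R₂ =
  area/∏FWHM, R₁ = half-perimeter/FWHM, R₀ = the mask's Euler
  characteristic (cubical complex on the grid, V − E + F on the mesh). The
  peak threshold solves Σ_d R_d ρ_d(t) = α by bracketed root-finding
  (tolerance 1e-8), with the Worsley t-field EC densities; peak p-values
  are the EC sum capped at 1. Cluster extents use the stationary 2-D
  Gaussian-field approximation — expected cluster count from the EC sum,
  expected suprathreshold volume from the height tail, exponential extent
  distribution — computed in log space to survive extreme thresholds;
  exact t-field extent densities are a possible extension. Connectivity is
  8-neighbour on the grid and shared-edge on the mesh.

Small degrees of freedom deserve a warning: at dof ≤ ~4 the t-field EC
densities decay so slowly that no finite threshold reaches conventional α
for realistic resel counts; the threshold solver reports this as a
diagnostic error rather than returning a spurious value.

## Synthetic data

The generator emulates an event-related colour–word Stroop protocol: 80
frequent and 20 rare events in random order, ISI uniform in 9–12 s,
10 Hz sampling, 52 channels. Per subject, active channels carry the
HRF-convolved event train scaled by w_n = w_pop + z_n with z_n ~ N(0, σ_b²)
drawn once per subject and channel; noise is stationary AR(1) (default
ρ = 0.5, marginal SD 2 µM) plus fixed-frequency cardiac (1.1 Hz) and
respiratory (0.25 Hz) sinusoids with subject-random phase — deliberately
inside the preprocessing stopbands so the band-stop stage is exercised
verifiably. HbR mirrors HbO at ratio −0.35 with half the noise. Default
amplitudes (2/4 µM for congruent/incongruent, σ_b = 2 µM) put group
t-values in the single-digit-to-low-double-digit range that fNIRS group
studies report. The default active set is a spatially contiguous
three-channel patch, as a focal effect requires. All randomness flows
through substreams spawned from one master seed.

What the generator does not emulate: scalp-versus-cortex partial volume and
superficial contamination, heteroscedastic or non-Gaussian noise,
subject-varying HRF shape, and spatially correlated between-subject
variability (z_n is independent across channels by default). The last point
matters for interpreting validation results: with independent channel
noise the interpolated fields are comparatively rough, so estimated resels
are large and the RFT threshold can exceed the 52-channel Bonferroni
threshold; with spatially correlated variability — the regime of real
scalp maps — resels fall well below the channel count and the RFT route is
the more sensitive one. The test suite probes both regimes (a 40 mm
squared-exponential process on the sphere for the correlated case).

## Validation problem sizes

The statistical acceptance checks run at sizes chosen to make the suite a
routine development tool: family-wise error calibration uses 200 null
groups of N = 21 subjects × 52 channels simulated at the contrast level —
the summary-statistic model's null, equivalent for everything downstream of
the first level — interpolated to a reduced 32×32 grid; power uses 50
replicates of a d = 1.5 focal effect on the same geometry; smoothness
recovery uses 100 Gaussian random fields of known 14 mm FWHM on the full
64×64 grid. End-to-end time-series recovery (optics → preprocessing → GLM →
maps → group) is tested at smaller N with shorter event streams. Passing
these tests demonstrates internal statistical consistency of the
implementation under its own generative model, not performance on real
recordings.
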