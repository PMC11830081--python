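# Methods

## Model family and assumptions

Four radially symmetric PDE variants describe the total cell density
`u(t, r)` of a growing spheroid on 0 ≤ r ≤ L (default L = 5 mm), with
time in weeks and density in the arbitrary intensity units of processed
brightfield images (typically 0–0.5). The general RD-ARD model has a
proliferative compartment `u₁` and a migratory compartment `u₂` that
additionally advects outward; both diffuse linearly and grow
logistically against the shared total `(u₁+u₂)/K`. All coefficients are
non-negative constants — no density-dependent or otherwise nonlinear
transport is modeled. The initial condition splits the observed total
profile as `u₁ = α u₀`, `u₂ = (1−α) u₀`; boundaries are no-flux at both
ends. The single-population variants (RD, ARD) are the `α = 1`
restrictions, RD-RD sets `A₂ = 0`.

The advection term is implemented exactly as the model states it,
`∂(A₂u₂)/∂r`, not the spherical divergence `(1/r²)∂(r²A₂u₂)/∂r`. The two
differ by the geometric dilution term `2A₂u₂/r`; with outward advection
the printed form slightly under-dilutes near the origin. We keep the
printed form and note the difference here.

## Spatial discretization and time integration

Method of lines on a uniform node-centered grid (default 400 nodes, so
Δr = 12.5 µm). Diffusion is in conservative flux form with central
differences; the diffusive flux is mirrored to zero at both boundaries,
which enforces the zero-derivative contract and conserves the spherical
mass `4π∫r²u dr` of a pure-diffusion run to well below 0.1% (asserted in
tests against a trapezoid quadrature oracle). At the coordinate
singularity r = 0 the radial Laplacian is replaced by its symmetry limit
`3D ∂²u/∂r²` using the mirrored one-sided second difference; this keeps a
uniform node-centered grid aligned with the data's radial bins.
Advection is discretized centrally in flux form with the advective flux
zeroed at both ends. Central advection can oscillate on coarse grids; at
the default resolution the oscillations are negligible for A ≤ 3
mm/week (the admissible bound).

Time integration uses LSODA (stiff-capable, variable order) with
rtol = 1e-6, atol = 1e-8. The state is interleaved per node so the
Jacobian is banded (bandwidth 2) and cheap to form by finite
differences. A carrying capacity of exactly zero is admissible only for
a compartment that is identically zero (its logistic term is evaluated
as 0); a populated compartment with K = 0 and ρ > 0 is rejected as a
domain error, and the fitter maps such trial points to a large penalty
SSE. Integrator output is clipped at zero; the most negative pre-clip
value is kept as a diagnostic (`min_preclip`, about −1e-6 or better in
all benchmark runs).

## Fitting

The objective is the unweighted SSE over every (tᵢ, rⱼ) observation,
including the initial slice (which contributes ~0 because the simulation
starts from the observed initial profile). Simulations run on the solver
grid and are linearly interpolated to the observed radii, decoupling
solver resolution from data binning; output times are evaluated exactly.

Stage 1 is the DIRECT global search over the admissible box
(D ∈ [0, 0.2] mm²/wk, ρ ∈ [0, 15] wk⁻¹, K ∈ [0, 1], A ∈ [0, 3] mm/wk,
α ∈ [0, 1]), with default budgets of 2000 model evaluations for the
3–4-parameter variants and 10000 for the 7–8-parameter ones. Stage 2
polishes the DIRECT optimum with L-BFGS-B (bounded quasi-Newton,
finite-difference gradients, ftol 1e-8); the polished SSE never exceeds
the stage-1 SSE. Both stages are deterministic, so fits are exactly
reproducible. Budget exhaustion returns the best-so-far with a
diagnostic flag rather than failing.

Model comparison uses the least-squares AIC
`N[ln 2π + 1] + N ln(SSE/N) + 2(κ+1)` with κ = 3/4/7/8 estimated
parameters; ties in AIC go to the model with fewer parameters. An SSE of
exactly zero returns −∞ with a warning. When replicates of a cell line
are fitted, per-line parameters are the arithmetic means of the
replicate estimates — the aggregation is a package choice; a joint fit
across replicates would be the natural alternative and is not
implemented.

## Wave-front analysis

For a density level `u*`, the front position at a time point is the
outermost radius where the profile crosses `u*` from above (the leading
invasive edge; interior crossings of non-monotone "hump" profiles are
deliberately ignored), localized between grid nodes by linear
interpolation. The speed at that level is the OLS slope of front radius
against time over a window; levels attained at fewer than 3 window times
are left undefined and excluded from summaries. The default recipe uses
100 levels from 0.02 to 0.8·max(u) and the window [0.75·t_f, t_f], and
is applied to model simulations at fitted parameters rather than raw
data: the data are noisy and span only one week, so the fitted model is
re-simulated to a 5-week horizon (default 101 output times) where the
front has developed. `c_shape` is reported as a magnitude — the slope of
a decreasing front is negative, and the scale is "smaller = more
diffuse".

Two choices here deserve emphasis:

* **Benchmark geometry.** Traveling waves are a planar construct (a
  spherically expanding front only approaches a constant speed
  asymptotically, and the curvature correction is significant at r ≈ 2–4
  mm), so the canonical heterogeneity benchmarks
  (`waves.HETEROGENEITY_BENCHMARKS`) are simulated with the planar
  Laplacian. Data fitting always uses the spherical default.
* **Benchmark summary levels.** For the four benchmark scenarios,
  `c_diff` is evaluated from the two representative densities 0.4 and
  0.1 (`benchmark_front_speeds`), not the 100-level scan. In the
  strongly heterogeneous scenario the advected hump crosses mid-range
  levels during the window, making the outermost crossing jump
  discontinuously between the hump and the trailing front; a max–min
  over all 100 levels is then dominated by those tracking artifacts
  (c_diff ≈ 2.0 instead of ≈ 0.77) and no longer measures front-speed
  heterogeneity. The two-level summary rides the two physically distinct
  fronts — the proliferative core and the invasive edge — and is stable.
  The 100-level recipe remains the default for fitted-cell-line use,
  where fronts are smoother.

With the default compact initial profile (0.5 mm core, peak 0.5, 0.1 mm
logistic edge), the four benchmarks give c_diff ≈ 0.77 / 0.31 / 0.003 /
0.0001 mm/week — strongly heterogeneous dynamics separated from
homogeneous ones by two orders of magnitude. The Fisher-KPP check uses a
steeper initial edge (0.02 mm): a pulled front's speed is set by the
initial decay rate when that is shallower than `sqrt(ρ/D)`, so a 0.1 mm
edge would measure the initial-condition speed `D/w + ρw` (w = edge
width) rather than the model's minimum speed `2√(Dρ)`. Even with a steep
edge the finite-horizon transient sits ~6% below the asymptotic value
(the universal `−3/(2λ*t)` correction), which motivates the 15%
tolerance.

## Synthetic data

The density generator evolves the default compact profile under a chosen
variant and adds i.i.d. Gaussian observation noise (default σ = 0.01,
i.e. 2–5% of typical peaks — a deliberately unstructured model, matching
the least-squares objective) clipped at zero. Noise is applied only
where the noiseless density exceeds 1e-3: real processed profiles are
*exactly zero* beyond the detected spheroid boundary, and without this
masking the positive far-field noise in the observed initial slice is
amplified as `e^{ρt}` by the logistic term and dominates every model's
SSE — an artifact processed data cannot exhibit. With noise disabled the
output is bit-identical to the solver output. Generators return their
ground truth and are deterministic per seed.

The image generator renders a dark, radially symmetric core-plus-halo
object on a light background (1152×1536 px ↔ 3.24×4.33 mm, i.e. 2.819
µm/px) with optional Gaussian pixel noise and elongated dark distractor
objects for the segmentation tie-break tests. It makes no attempt at
realistic optics (no PSF, vignetting, or depth effects), so passing
image-pipeline tests demonstrate correctness of the processing chain,
not robustness to real microscopy artifacts.

## Image processing

Center estimation: subtract the median intensity, Gaussian-smooth
(σ = 4 px), binarize where |deviation| > 0.08 on a [0, 1] scale (integer
images are first divided by their dtype maximum), drop connected
components below 4000 px², keep the component with the lowest
ellipse-fit eccentricity (ties → larger area), and take the mean of its
pixel indices. The threshold is applied to the *magnitude* of the
deviation: a dark-on-light brightfield object is negative after median
subtraction, and a one-sided threshold would find nothing on exactly the
image convention the later inversion step (`1 − im`) assumes; the
magnitude form reduces to the one-sided operation for bright objects.

Radial profiling: invert intensity, bin pixels by distance to the center
into 600 annuli of 2 px, average per bin (annuli beyond the image
corners are empty and carry the last observed value forward), smooth
with a 201-bin moving average truncated at the edges, and set the
boundary `i*` at the first bin beyond bin 100 (the core-exclusion zone)
where the first difference of the moving average changes from negative
to positive. Beyond `i*` the profile is held constant and that value is
subtracted everywhere, so the background is exactly zero. On noise-free
synthetic images the smoothed profile is monotone and exactly flat
outside the object, so no sign change exists; the boundary then falls
back to the last bin with a warning — harmless, since the subtracted
background is the same. The sign test uses the raw first difference of
the moving average, and bin distances use pixel centers.

## Phenotyping

Fitted coefficients are made dimensionless by dividing by population
aggregates: the across-line mean of `(D₁+D₂)/2`, of `(ρ₁+ρ₂)/2`, and of
`A₂`. Means are used rather than bare sums so the normalized values read
as fold-of-average; the Go-or-Grow conditions compare products of the
same aggregates on both sides, so the labels are invariant under any
common rescaling (property-tested). A line is Go-or-Grow at factor k
(default 5, strict inequalities) when one subpopulation's rescaled
motility (advection counting toward population 2) exceeds k times the
other's while the rescaled growth relationship is reversed. Note the
normalization is population-relative: a cohort in which *every* line has
tiny advection still normalizes those values to ≈ 1, so labels depend on
the cohort composition by design.

Clustering is average-linkage agglomerative on standardized Euclidean
distances (each feature divided by its across-line sample SD, ddof = 1);
zero-variance features are dropped with a warning. The default feature
set is the raw fitted parameter vector per line. The partial correlation
of A and B controlling for C is the standard first-order formula,
clamped to [−1, 1]; |ρ| = 1 controls are domain errors.

## Pipeline

`run_full_analysis` wires the stages together from a YAML config:
load-or-generate replicates → fit the model set per replicate →
aggregate per line → wave parameters on aggregated-fit simulations →
normalization/classification → clustering → CSV tables plus a provenance
record (config hash, seed, versions). One global seed fans out through
`numpy.random.SeedSequence.spawn`, so identical configs give identical
bundles and stages are individually reproducible. Replicate failures are
isolated, logged, and reported without aborting the run; an existing
output directory is only overwritten with `force`.

## Problem sizes and defaults

Production defaults: 400-node grid, DIRECT budgets 2000/10000, 100 wave
levels, 101 output times on a 5-week wave horizon. The test suite
exercises the same code paths at reduced sizes chosen as sensible
desk-scale analyses — 64–150-node grids, DIRECT budgets of 60–1200, and
8–10 observation times — which keep each fit in seconds while leaving
parameter recovery within the asserted tolerances.

## Known limitations

* Central advection is not monotone; strongly advective fits on very
  coarse grids could show wiggles (not observed at default resolution).
* Parameter identifiability from one week of data is weak for α and the
  growth split; trajectory-level recovery is the meaningful contract,
  and no uncertainty quantification (profile likelihood, bootstrap) is
  provided.
* The wave summaries inherit the outermost-crossing convention; for
  profiles with persistent multi-modal structure the 100-level scan can
  include jump artifacts (see above).
* The synthetic image model is geometric, not optical, and the density
  units are uncalibrated image intensities, not cell counts.
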