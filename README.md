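# spherowave

Mechanistic PDE modeling of multicellular tumor-spheroid growth and
invasion, for quantifying intra-tumor heterogeneity from radial
cell-density time series.

Patient-derived glioblastoma cells grown as 3D spheroids invade the
surrounding matrix while proliferating, and the two processes are hard to
disentangle from images alone. `spherowave` addresses this for anyone
analyzing spheroid invasion assays: it converts brightfield images into
radial density profiles, fits a family of radially symmetric PDE models
to the resulting `u(t, r)` data, compares the models by information
criteria, summarizes front-propagation heterogeneity with numerically
estimated wave speeds, and classifies cell lines as "Go-or-Grow"
(migration and proliferation split between subpopulations).

## The models

The general two-population model (RD-ARD) couples a proliferative and a
migratory compartment through a shared logistic competition term, in
radially symmetric spherical coordinates on 0 ≤ r ≤ 5 mm with no-flux
boundaries:

```
∂u₁/∂t = (1/r²) ∂/∂r (r² D₁ ∂u₁/∂r) + ρ₁ u₁ (1 − (u₁+u₂)/K₁)
∂u₂/∂t = (1/r²) ∂/∂r (r² D₂ ∂u₂/∂r) + ρ₂ u₂ (1 − (u₁+u₂)/K₂) − ∂(A₂u₂)/∂r
```

with `u = u₁ + u₂`, initial split `u₁(0) = α u₀`, `u₂(0) = (1−α) u₀`.
Restrictions give the other variants: RD (single Fisher-KPP population,
κ = 3 parameters), ARD (single population with advection, κ = 4), RD-RD
(two populations, no advection, κ = 7), RD-ARD (κ = 8).

Fitting minimizes the sum of squared residuals over every (time, radius)
observation with the derivative-free DIRECT global search over the
admissible box (D ∈ [0, 0.2] mm²/wk, ρ ∈ [0, 15] wk⁻¹, K ∈ [0, 1],
A ∈ [0, 3] mm/wk, α ∈ [0, 1]) followed by bounded L-BFGS-B refinement,
and models are ranked by the least-squares AIC

```
AIC = N[ln(2π) + 1] + N ln(SSE/N) + 2(κ + 1),    N = N_t · N_r.
```

Front heterogeneity is summarized by tracking, per density level, the
outermost radius where the profile crosses that level and regressing it
on time: `c_max`, `c_min`, `c_diff = c_max − c_min` (≈ 0 for a
homogeneous traveling wave, large when subpopulations migrate at
different rates) and `c_shape`, the front-steepness slope at the final
time.

## Worked example

Generate synthetic data from a known heterogeneous two-population truth,
fit the RD-ARD model, and compute wave parameters:

```python
import numpy as np
from spherowave import (
    ModelParams, NoiseSpec, RadialGrid, SpheroidGrowthModel,
    generate_density_series,
)

grid = RadialGrid.uniform(L=5.0, n=100)
truth = ModelParams("RD_ARD", D1=0.007, rho1=2.5, K1=0.65,
                    D2=0.07, rho2=1.5, K2=0.4, A2=0.4, alpha=0.5)
observed, _ = generate_density_series(
    truth, np.linspace(0, 1, 8), grid, noise=NoiseSpec(sigma=0.01, seed=42))

result = SpheroidGrowthModel(observed, "RD_ARD", solver_grid=grid).fit(
    direct_maxfun=1000)
print(result.summary())
wp = result.wave_parameters()
print(f"c_diff = {wp.c_diff:.4f} mm/week")
```

prints

```
Spheroid growth model fit
================================================
model:          RD_ARD
observations:   800 (N_t=8, N_r=100)
parameters:     8
SSE:            0.0217363
AIC:            -6122.4
------------------------------------------------
  D1     = 0.0141673    (bounds [0, 0.2])
  rho1   = 2.61191      (bounds [0, 15])
  K1     = 0.635092     (bounds [0, 1])
  D2     = 0.0669117    (bounds [0, 0.2])
  rho2   = 1.13607      (bounds [0, 15])
  K2     = 0.270371     (bounds [0, 1])
  A2     = 0.57491      (bounds [0, 3])
  alpha  = 0.642511     (bounds [0, 1])
------------------------------------------------
evaluations:    DIRECT 589, local 306
c_diff = 1.8597 mm/week
```

The fitted trajectory reproduces the noiseless truth to well within the
noise level even though individual parameters (notably α and the split of
growth between compartments) are only weakly identified from one week of
data — the usual situation for these assays. The large `c_diff` reflects
the fast-diffusing, advecting second population: low-density fronts
outrun the high-density core.

`compare_models(observed)` fits all four variants and ranks them by AIC;
on data like the above RD-ARD wins despite its 8-parameter penalty.

A thin CLI mirrors the library: `spherowave profile` (image → radial
density CSV), `fit`, `compare`, `waves`, `classify`, `cluster`, and
`spherowave run --config run.yaml` for the full pipeline.

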