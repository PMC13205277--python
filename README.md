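# transrr

Transfer learning for **ridge-regularized robust linear regression** in the
moderate-dimensional regime — the setting where the number of predictors
`p` is of the same order as the sample size `n`, the coefficients are
diffuse rather than sparse, and the errors may be heavy-tailed (Cauchy-like
contamination included). Typical consumers are statisticians and applied
scientists with a small *target* study and a larger related *source* study
— multisite metabolomics cohorts or spectra from two instruments in a
calibration-transfer problem — who want to borrow strength from the source
without being burned when the two studies turn out to differ.

## What it computes

Given target data `(x_i, y_i)`, `y_i = x_i'β₀ + ε_i`, and source data
`(x_j¹, y_j¹)`, `y_j¹ = (x_j¹)'w₀ + ε_j¹`, with discrepancy
`δ₀ = β₀ − w₀`, `h = ‖δ₀‖`:

1. **Two-stage transfer estimator** (`trans_rr`).
   Stage 1 fits a robust ridge on the source:
   `ŵ = argmin (1/n₁) Σ ρ̃(y_j¹ − (x_j¹)'w) + (τ₁/2)‖w‖²`.
   Stage 2 fits a shrunken correction on the target:
   `δ̂ = argmin (1/n) Σ ρ(y_i − x_i'(ŵ + δ)) + (τ/2)‖δ‖²`, and
   `β̂ = ŵ + δ̂`. The default loss is the smoothed Huber loss
   (δ = 1.35, η = 0.1), whose score ψ = ρ′ is bounded with Lipschitz ψ′.

2. **Single-study and pooled baselines** (`single_rr`, `pooled_rr`) and
   **cross-validated penalty tuning** (`cv_tune_penalty`, 5-fold MAE over
   the geometric grid `3^a`, `a = −2, −1.5, …, 2`).

3. **Adaptive aggregation against negative transfer**
   (`adaptive_trans_rr`): `β̂_ada(θ) = θβ̂ + (1−θ)β̂_st` with the mixing
   weight `θ ∈ {0, 0.1, …, 1}` chosen by K-fold cross-validation on the
   target study, so the procedure can fall back to either endpoint.

4. **Asymptotic risk solver** (`solve_risk_system`). As `p/n → κ`,
   `‖β̂ − β₀‖ → r` where `(r, c)` solves the proximal fixed-point system

   ```
   E[ prox(cλ²ρ)′(W) ]                              = 1 − κ + τc
   κ E[ (W − prox(cλ²ρ)(W))² / λ² ] + τ²d²c²        = κ²r²
   ```

   with `W = ε + rλZ`, `Z ~ N(0,1)`, and `d = ‖β₀ − ŵ‖` the realized
   source discrepancy. The solver uses deterministic quadrature plus
   nested bracketed root-finding, and `risk_curve` traces `r(d)` across
   penalties — the theoretical picture of when transfer helps and when it
   hurts (the crossover sits near `h = 1`).

5. **Simulation pipelines** (`simulate` module) for three noise scenarios
   (Gaussian; Unif(0,√3)-scaled designs with Cauchy errors; a 50/50
   mixture) and **spectral-style preprocessing** (`thin_columns`,
   `fit_whitener`, `rmse`) for real calibration-transfer data.

## Worked example

```python
import numpy as np
from transrr import (adaptive_trans_rr, case_mixture, cv_tune_penalty,
                     fit_robust_ridge, gen_coefficients, gen_study,
                     smoothed_huber, solve_risk_system, trans_rr)

loss = smoothed_huber()          # delta = 1.35, eta = 0.1
p, n, n1 = 200, 200, 400
rng = np.random.default_rng(0)
coefs = gen_coefficients("diffuse", p, n, rng=rng)     # fixed truth
source = gen_study("I", p, n1, "source", coefs.w0, rng)
target = gen_study("I", p, n, "target", coefs.beta0, rng)

fit = trans_rr(target.data, source.data, loss, loss, tau=1.0, tau1=1.0)
err = np.sum((fit.beta_hat - coefs.beta0) ** 2)
d = np.linalg.norm(coefs.beta0 - fit.w_hat)
sol = solve_risk_system(loss, kappa=p / n, tau=1.0,
                        spec=case_mixture("I", "target"), d=d)
print(f"squared error {err:.4f}, theory r^2 {sol.r**2:.4f}")
```

prints

```
squared error 0.3409, theory r^2 0.3636
```

— a single replicate's squared estimation error next to the deterministic
limit predicted by the risk system at the realized discrepancy `d ≈ 0.67`;
averaged over 500 replicates the two agree to the third decimal (about
0.365 for this design). A command-line interface mirrors the library:
`transrr fit-transfer target.csv source.csv`, `transrr risk-curve`,
`transrr experiment comparison --case I --p 400`, each emitting JSON or
CSV.

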