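# mlsem — multilevel SEM for clustered ordinal questionnaire data

`mlsem` measures a latent psychiatric-morbidity factor from the twelve
ordinal items of the General Health Questionnaire (GHQ-12) and explains it
with individual- and household-level predictors, while accounting for the
clustering of individuals within households. It is aimed at biostatisticians
and epidemiologists analysing household health surveys in which several
adults per household answer the same screening instrument.

## The model

Each item response `Y_pij ∈ {1,…,4}` (item *p*, individual *i*, household
*j*) is an ordinal-probit indicator of a continuous latent response
`Y*_pij = λ_p η_ij + ε_pij`, cut at thresholds `τ_p1 < τ_p2 < τ_p3`. The
individual morbidity factor has a household-level random intercept that is
itself regressed on household covariates:

```
η_j(HH)  = γ'Z_j + u_j,            u_j ~ N(0, ψ_HH)
η_ij     = β'X_ij + η_j(HH) + e_ij, e_ij ~ N(0, ψ_Ind)
```

with loadings invariant across levels (λ_1 fixed to 1 for identification).
The pipeline estimates this in two stages:

1. **Measurement (DWLS).** Item thresholds and pairwise polychoric
   correlations with asymptotic variances; a one-factor model fit by
   diagonally weighted least squares; CFI/TLI/RMSEA/GFI; score-test
   modification indices with stepwise freeing of error covariances.
2. **Structural (ML).** Full-information maximum likelihood for the
   two-level model with nested Gauss–Hermite quadrature (outer rule over
   the household residual, inner rule over each member's residual),
   analytic gradients, Wald standard errors, directional hypothesis tests,
   standardized coefficients, latent and indicator-level intraclass
   correlations (ICC = ψ_HH/(ψ_HH+ψ_Ind)), explained variance per level,
   and tolerance/VIF collinearity diagnostics.

A synthetic-data generator creates households of two or more adults with
known ground-truth parameters (its defaults reproduce the item margins,
predictor margins and published parameter estimates of a large English
household health survey), so the whole pipeline is testable without any
external data. The co-resident mental-health-history flag `X_co` is derived
from household composition, never sampled independently.

## Worked example

```python
from mlsem import (default_config, generate_households, polychoric_matrix,
                   ModelSpec, fit_dwls, MSEMSpec, fit_msem, fit_null_model,
                   latent_icc, explained_variance, ITEM_NAMES)

ds = generate_households(default_config(n_households=888, seed=11))
pm = polychoric_matrix(ds.df[ITEM_NAMES])
cfa = fit_dwls(pm, ModelSpec(item_names=list(ITEM_NAMES)))
spec = MSEMSpec.from_cfa(cfa, pm)
null = fit_null_model(ds, spec, n_nodes=11)
full = fit_msem(ds, spec, n_nodes=11)
print(f"latent ICC (null): {latent_icc(null.psi_hh, null.psi_ind):.3f}")
print(f"explained variance, individual level: "
      f"{100*explained_variance(null.psi_ind, full.psi_ind):.1f}%")
print(f"history-of-illness coefficient: "
      f"{full.estimates()['X4_history']:.4f} (se {full.se['X4_history']:.4f})")
```

prints

```
latent ICC (null): 0.283
explained variance, individual level: 25.9%
history-of-illness coefficient: 0.0530 (se 0.0055)
```

The ICC says ~28% of the latent morbidity variability in this synthetic
survey lies between households; the individual-level predictors then explain
~26% of the within-household latent variance; the positive history
coefficient (z ≈ 10) confirms the generating effect of a personal history of
common mental disorder. (Estimates sit on the stage-1 standardized
latent-response metric, so they differ numerically from the generating
values only through the estimated measurement scale.)

A command-line interface mirrors the library:

```
mlsem simulate --seed 1 --out data.csv
mlsem run --data data.csv --out results/
```

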