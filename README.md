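# lcvar — latent-class vector-autoregression for EMA panels

`lcvar` clusters individuals by the *temporal dynamics* of their momentary
states. The motivating application is ecological momentary assessment (EMA)
of eating behaviour: participants rate affect, stress coping, hunger and
food craving on 0–100 sliders six times a day (09:00, 11:30, 14:00, 16:30,
19:00, 21:30) for 14 days, and the question is whether subgroups of people
share similar lagged associations — e.g. whether craving at one beep
predicts feeling less calm at the next.

## The model

Individuals i = 1..n each contribute a multivariate time series
x_{i,t} ∈ R^d (d momentary items). A latent class k owns a VAR(p_k) model
with exogenous covariates:

    x_t = B z_t + A_1 x_{t−1} + … + A_p x_{t−p} + ε_t,   ε_t ~ N(0, Σ_k)

where z_t holds an intercept and time-of-day indicators, the A_l carry
autoregressive (diagonal) and cross-lagged (off-diagonal) effects, and each
individual belongs to exactly one class with prior probability π_k.
Estimation is maximum likelihood via EM over *individuals*: the E-step
computes posterior class responsibilities from each participant's whole
conditional Gaussian likelihood (log-sum-exp normalised), and the M-step
refits each class by responsibility-weighted multivariate least squares.
Within-participant occasions are chained in (day, beep) order, so each day's
last beep is the lagged predictor of the next day's first beep.

Model selection scans a grid of cluster counts K and lag orders p, runs 15
pseudo-random centre-based starts plus a rational k-means start (and a warm
start) per cell with up to 50 EM iterations (convergence tolerance 1e-07 on
the log-likelihood), and ranks cells by the per-observation Hannan–Quinn
criterion. A degenerating class (fewer than 2 expected members, or a
non-positive-definite Σ) is rescued by adding 10 to every element of its Σ
and re-randomising its responsibilities.

Around the core model the package provides the full study pipeline:

- `lcvar.synthetic` — panels with known class structure (stable VAR
  parameters, diurnal "M-curve" appetite means, missingness, trait tables,
  shuffled-null controls);
- `lcvar.data` — long-format panel I/O, the ≥ 50-of-84 completed-prompts
  compliance rule, pooled z-scoring, lagged design matrices;
- `lcvar.impute` — chained-equations single imputation (Bayesian-draw
  regression sweeps, optional predictive-mean matching);
- `lcvar.model` — the EM mixture and the K × lag grid search;
- `lcvar.profiles` — coefficient heatmap tables and per-cluster daytime
  courses;
- `lcvar.characterize` — one-way ANOVAs with generalised eta-squared, Tukey
  HSD contrasts, Pearson chi-squared, and an exact Fisher test for r×c
  tables (full enumeration, probability-ordering two-sided rule);
- `lcvar.pipeline` — one-config orchestration with a reproducibility
  manifest.

## Worked example

```python
import numpy as np, warnings
from lcvar import (FitConfig, SimulationSpec, fit_grid, m_curve_profiles,
                   make_var_params, simulate_panel, standardize)

models = [
    make_var_params(4, 1, cross_effect=0.35, seed=1,
                    cross_pairs=[(0, 1, +1.0), (1, 0, +1.0)]),
    make_var_params(4, 1, cross_effect=0.35, seed=2,
                    cross_pairs=[(0, 1, -1.0), (1, 0, -1.0)]),
]
spec = SimulationSpec(n_participants=40, cluster_models=models,
                      cluster_proportions=np.array([0.5, 0.5]),
                      diurnal_profiles=m_curve_profiles(2, 6, 4), seed=11)
panel, truth = simulate_panel(spec)
z, _ = standardize(panel)
grid = fit_grid(z, FitConfig(k_min=2, k_max=3, lag_min=1, lag_max=2, seed=5))
print(grid.summary())
```

prints the HQC-ranked grid (excerpt):

```
 K  lags        loglik  n_params       hqc      aic  converged
 2   1/1 -16282.705121       101  9.936193 9.869702       True
 2   2/2 -16058.376162       133  9.961294 9.872790       True
 3 1/1/1 -16242.862854       152  9.976489 9.876423       True
 3 2/2/2 -16012.220212       200 10.018588 9.885500       True
```

The K=2, lag-1 cell wins (lowest HQC); its hard labels recover the true
two-class partition with adjusted Rand index 1.000, and the class-specific
craving→hunger lag-1 coefficients come out with opposite signs (−0.381 vs
+0.394 on the standardised scale), the separation the generator planted.
The scripts in `examples/` walk through each capability end to end
(simulation, preparation/imputation, grid fitting, profiles and the
shuffled-null control, trait characterisation, full pipeline).

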