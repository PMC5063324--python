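# svclake

Bayesian **spatially-varying coefficient (SVC) regression** for the
nutrient–water color paradigm of lake trophic state: how total phosphorus
(TP, μg/L) and water color (PCU) jointly drive chlorophyll *a* (CHL, μg/L)
across hundreds of north-temperate lakes, and how those relationships change
over geographic space.

The package is written for limnologists and spatial statisticians who want to
fit, compare and score these models on their own lake tables, and for anyone
who needs a tested reference implementation of an SVC sampler with a
coregionalized Gaussian-process prior.

## The model

For log10 chlorophyll `y_t(s)` at lake location `s` and sampling time `t`:

```
y_t(s) = x̃_t(s)ᵀ β̃(s) + x_t(s)ᵀ β + e_t(s),      e_t(s) ~ N(0, τ²)
```

* `x̃_t(s) = (1, log10 TP, log10 color)ᵀ` carries the **spatially-varying**
  coefficients `β̃(s)`;
* `x_t(s)` holds optional space-invariant covariates (log10 maximum depth,
  log10 catchment:lake area ratio, catchment agriculture and wetland
  proportions, a drainage-lake dummy) with global coefficients `β`;
* `β̃(s) ~ MVGP(β̃_mu, Σ(θ))` — a multivariate Gaussian process whose
  cross-covariance is a Linear Model of Coregionalization,
  `Σ = Σ_j (a_j a_jᵀ) ⊗ R_j`, with exponential correlation
  `R_j = exp(−φ_j d)` so each coefficient surface has its own decay rate
  `φ_j` and **effective spatial range** `−ln(0.05)/φ_j ≈ 3/φ_j` (the distance
  at which correlation falls to 0.05).

Estimation is Metropolis-within-Gibbs MCMC: conjugate Gibbs blocks for
`(β̃_mu, β)`, the stacked coefficient fields, and `τ²`; adaptive random-walk
Metropolis for `θ = (φ, A)`. Candidate models are compared with DIC, and
out-of-sample predictions are scored with RMSPE, CRPS, and 95% interval
coverage (PCI) and width (PIW).

## Worked example

```python
import numpy as np
import svclake as sl

# synthetic lake table under realistic study conditions
cfg = sl.SimConfig(n_sites=100)
df, truth = sl.generate_dataset(cfg, np.random.default_rng(1))

kept, drop_log = sl.apply_filters(df)          # area/season/triplet/depth rules
frame = sl.build_model_frame(kept)             # log10 transforms, site list
train, hold = sl.split_holdout(frame, 0.10, seed=2)

res = sl.SVCModel(train).fit(n_iter=6000, n_burn=3000, n_thin=5, seed=3)
print(res.summary())
print(res.effective_ranges())
print(res.score(hold, rng=4))
```

Output (seeded as above):

```
SVC chlorophyll model | n_obs=819 n_sites=91 draws=600

                            mean       sd     q2.5     q97.5
beta_mu[intercept]       -0.0943   0.4210  -0.9058    0.7597
beta_mu[log_tp]           0.6827   0.1679   0.3397    1.0064
beta_mu[log_color]       -0.0955   0.1748  -0.4502    0.2524
beta[log_max_depth]      -0.1236   0.2685  -0.6184    0.4070
beta[log_calk]           -0.1850   0.1695  -0.5128    0.1360
beta[prop_agriculture]   -0.1504   0.5128  -1.1094    0.9232
beta[prop_wetland]        0.3626   0.7285  -1.0842    1.8350
beta[drainage]            0.1243   0.1743  -0.2331    0.4437
tau2                      0.5928   0.0300   0.5415    0.6559
eff_range[intercept]     71.4328  36.9605  39.7000  186.6369
eff_range[log_tp]        85.1532  42.4518  41.0339  193.8259
eff_range[log_color]    121.4546  59.8921  42.3089  246.0677

Metropolis acceptance: phi=0.38, A=0.28
{'intercept': 58.08, 'log_tp': 71.87, 'log_color': 109.19}
PredictiveScores(rmspe=0.937, crps=0.519, pci=88.89, piw=3.133)
```

The posterior mean TP elasticity (0.68; generating value 0.698) says a 1%
rise in TP lifts CHL by roughly 0.7%; `tau2` near 0.59 estimates the residual
log10-CHL variance (generating value 0.63); the effective ranges estimate how
far each coefficient surface stays spatially correlated; and the holdout
block reports log10-scale prediction error and interval calibration (here
88.9% of the 91 held-out observations fall inside their 95% intervals).
Note only 91 of the 100 lakes appear in this training split; the other 9 are
single-observation lakes whose rows all landed in the holdout, and their
predictions are kriged from the Gaussian-process conditional.

Per-lake science comes from the coefficient field:

```python
field = res.coefficient_field()                   # per-lake mean/CI/signif.
sl.classify_significance(field)                   # positive/negative/null counts
sl.translate_effect(0.73, chl=4.47, ref_value=14.0)  # -> 0.233 μg/L CHL per μg/L TP
grid = sl.interpolate_surface(field, "log_tp")    # IDW surface for mapping
```

A thin CLI wraps the same stages:

```bash
svclake simulate --seed 7 --out synth.csv
svclake prepare  --input synth.csv --seed 42 --outdir run1/
svclake fit      --train run1/train.csv --holdout run1/holdout.csv \
                 --model svc_full --seed 1 --outdir run1/fit/
svclake summarize --fit run1/fit --outdir run1/summary/
```

## Layout

| module | role |
|---|---|
| `svclake.pipeline` | read/validate/filter observation tables, build model frames, holdout splits |
| `svclake.gp` | distances, exponential correlation, effective range, LMC covariance, MVGP sampling |
| `svclake.model` | `SVCModel` / `NonSpatialModel`, the Metropolis-within-Gibbs sampler, `SVCResults` |
| `svclake.evaluate` | DIC, Gaussian and sample CRPS, posterior prediction (with kriging to new lakes), holdout scores |
| `svclake.summaries` | significance classes, natural-scale effects, IDW surfaces, correlations, Welch contrasts |
| `svclake.simulate` | synthetic-data generator and filter-rule fixtures |

See `docs/methods.md` for modelling assumptions, priors, numerical choices
and known limitations.
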