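# dosemeta

Fixed-effects dose–response meta-analysis of aggregated binary-outcome data,
with the goodness-of-fit tools the practice usually skips: the deviance and
its chi-square specification test, the generalized coefficient of
determination, and the decorrelated residuals-versus-exposure plot.

## The problem

Epidemiological studies commonly report relative risks (RRs) for categories
of a quantitative exposure — grams per day, cups per day — each against the
same reference category. A dose–response meta-analysis pools these
dose-specific log RRs across K studies into one curve. Two features make this
harder than ordinary meta-analysis:

1. **No intercept.** The log RR at each study's reference dose is identically
   0, so the study model `y_i = X_i β_i + ε_i` has no constant term and every
   basis column must vanish at the reference dose.
2. **Correlated outcomes.** All of a study's non-referent log RRs share the
   reference group, so the errors `ε_i` are correlated: `V(ε_i) = S_i` has
   nonzero off-diagonals. `S_i` is not reported and must be reconstructed from
   the aggregated data, here by the Greenland–Longnecker or Hamling
   pseudo-count methods (an `independence` fallback is also provided).

Estimation is generalized least squares, either **two-stage** (fit each study,
then pool the `β̂_i` by multivariate fixed-effects meta-analysis or
meta-regression on study-level covariates) or **one-stage** (stack all
studies with block-diagonal `S` and fit once). The two routes are
algebraically equivalent and the package verifies this to machine precision.

Because of the correlation, a well-fitting pooled curve need *not* pass
through the data points, so overlaying the curve on the reported RRs can
mislead. The fit is instead assessed with:

* **Deviance** `D = e'S⁻¹e` (the generalized residual sum of squares), which
  is asymptotically χ²(n − p) under a correctly specified model — a
  specification test — and whose differences between nested models are
  χ²(q);
* **Generalized R²** `= 1 − (e'S⁻¹e)/(y'S⁻¹y)` with its sample-size adjusted
  version `1 − (n/(n−p))(1 − R²)`;
* **Decorrelated residuals** `e* = C⁻¹e` from the Cholesky factorization
  `S = CC'`, plotted against exposure with a LOWESS smoother;
* study-specific variants of all three, a joint χ²(n − Kp) test across
  studies, and multivariate Cochran Q / I² for residual heterogeneity.

Intended users are biostatisticians and epidemiologists conducting or
reviewing quantitative syntheses of published dose–response data.

## Worked example

Simulate 8 studies (mixed case-control / cumulative-incidence /
incidence-rate designs, a true log-linear slope of 0.05 per dose unit), fit
linear and quadratic models, and compare their fit:

```python
import numpy as np
import dosemeta as dm

cfg = dm.SimulationConfig(K=8, seed=42)
dataset, truth = dm.simulate_dataset(cfg)

linear = dm.fit_one_stage(dataset, dm.TransformSpec(), "gl")
quad = dm.fit_one_stage(dataset, dm.TransformSpec(kind="polynomial", degree=2), "gl")
f1 = dm.fit_first_stage(dataset, dm.TransformSpec(), "gl")
f2 = dm.fit_first_stage(dataset, dm.TransformSpec(kind="polynomial", degree=2), "gl")
print(dm.gof_table([("linear", linear), ("quadratic", quad)], [f1, f2]))
```

```
    model  deviance  df  p_specification  p_relative  r2_pct  r2_adj_pct      Q  Q_df  p_heterogeneity  i2_pct
   linear    20.086  23            0.637         NaN  88.436      87.934  1.789     7            0.971     0.0
quadratic    18.635  22            0.668       0.228  89.272      88.297 13.161    14            0.514     0.0
```

The linear model passes the specification test (D = 20.1 on 23 df,
p = 0.64 — no evidence of lack of fit), explains 88% of the generalized
total sum of squares, and the quadratic term buys nothing (relative-fit
p = 0.23); Cochran Q shows no residual heterogeneity (I² = 0%). The pooled
slope is 0.0474 (SE 0.0038), covering the true 0.05, and the predicted curve

```python
print(dm.predict_curve(linear, [0, 2.5, 5, 10]))
```

```
 dose    rr  rr_low  rr_high  extrapolated
  0.0 1.000   1.000    1.000         False
  2.5 1.126   1.105    1.147         False
  5.0 1.267   1.221    1.316         False
 10.0 1.606   1.490    1.731          True
```

returns RR = 1 exactly at the reference dose and flags doses outside the
observed range. `dm.residual_plot(linear)` draws the decorrelated residuals
against exposure with a LOWESS smoother; under a correct model the points
scatter around the zero line with no pattern.

The same pipeline is available from the shell:

```sh
dosemeta simulate --out sim --seed 42
dosemeta fit --input sim/dataset.csv --out results \
    --transform linear --transform rcs --covariance gl
dosemeta calibrate --reps 500
```

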