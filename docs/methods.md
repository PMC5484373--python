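# Methods

## Data model

The unit of analysis is the non-referent log relative risk. A study
contributes `n_i` of them, one per exposure category above/below its
reference category, together with the assigned dose, the case count and a
design-specific denominator (non-cases for case-control, total subjects for
cumulative incidence, person-time for incidence rate), and a 95% CI or
standard error. Standard errors are derived from CIs as
`(ln U − ln L) / (2 × 1.959964)`; the normal quantile is fixed at that value
everywhere for cross-platform reproducibility. Reference rows carry
`log RR = 0, SE = 0` by construction. Doses are taken as the values assigned
in the source table; assigning typical doses to open-ended intervals is out
of scope.

Changing a study's reference category shifts the log RRs by the log RR of
the new reference; the standard errors, which are tied to the old shared
reference group, are re-derived from the Greenland–Longnecker pseudo-counts
(below), so rescaling requires counts. On crude (unadjusted) tables this
reproduces the count-ratio RRs exactly and leaves the fitted trend invariant.

## Within-study covariance

The covariance of two log RRs sharing a reference group decomposes into a
term specific to each category plus a term from the common reference:
`1/a₀` (incidence rate), `1/a₀ − 1/N₀` (cumulative incidence),
`1/a₀ + 1/b₀` (case-control odds). Since adjusted RRs do not come with a
usable table, the reference cell is reconstructed:

* **Greenland–Longnecker (`gl`, default):** find fitted cases `a*_j` whose
  crude association measures equal the reported RRs while matching the
  category denominators and the total number of cases. For rate and risk
  ratios the fitted cases are proportional to `exp(L_j) × denom_j`, so the
  solution is closed-form; for odds ratios the reference cell solves a
  monotone scalar equation, handled by Newton iteration with a bisection
  safeguard, stopping when the pseudo-count table changes by `< 1e-8` (sup
  norm) or after 200 iterations (a `ConvergenceError` then carries the last
  iterate). The reported variances stay on the diagonal of `S_i`; the
  pseudo-counts enter through the implied correlations only.
* **Hamling (`hamling`):** solve for effective counts that reproduce every
  reported variance and the RR ratio structure exactly, anchored to the
  observed margins (total cases plus total non-cases, totals, or person-time
  by design; a 1-D or 2-D root find started at the observed reference
  counts). `S_i` is then the delta-method covariance of the effective table,
  so its diagonal matches the reported variances by construction.
* **`independence`:** `diag(SE²)`, as a deliberately naive baseline.

On crude tables both reconstructions recover the true counts, hence the
analytic delta-method covariance, to solver precision — the oracle used in
the tests. When reported inputs admit no positive table (risks above 1,
SEs smaller than any count table can produce), the methods raise instead of
clipping: a clipped covariance would silently corrupt every downstream
deviance. Mixed designs within one study are rejected.

## Dose transformations

Design matrices never include an intercept; every basis column is centred by
subtracting its value at the study's reference dose, so the fitted log RR at
the reference is exactly 0. Available bases: linear, polynomial, and
restricted cubic splines in the Harrell truncated-power form (cubic between
the boundary knots, linear beyond; k knots give k − 1 columns). Default
knots sit at the 25th/50th/75th percentiles of the pooled non-referent doses
(all studies, unweighted; linear-interpolation percentile rule — several
conventions exist and one had to be fixed). The nonlinear columns are kept
on the raw truncated-power scale; `normalize_rcs` divides them by the
squared knot range for compatibility with software that does. Interactions
with study-level covariates append `basis × covariate` columns
(basis-major order), keeping p identical across studies.

## Estimation

All GLS solves use Cholesky whitening (`S = CC'`, solve triangular systems,
then QR on the whitened design); `S` is never inverted explicitly, and rank
deficiency is reported with the offending column names. The one-stage fit
stacks outcomes, designs and covariances (block-diagonal `S`). The
two-stage fit pools first-stage `β̂_i` by GLS with weights `V(β̂_i)⁻¹`,
with second-stage design `Z_i = [I_p, z_i I_p, …]` for meta-regression —
the exact counterpart of one-stage interaction columns, which is why the
two routes agree entry-by-entry. Studies with `n_i < p` are excluded from
the first stage with a warning (the one-stage fit does not need per-study
invertibility); a spline column that is identically zero within a study
(all doses below the first knot) is a genuine rank deficiency and raises.
Wald 95% intervals use normal quantiles, consistent with the fixed-effects
framework.

The two-stage deviance is computed through the decomposition
`D = Σ_i D̃_i + Σ_i (β̂_i − Z_i θ̂)' V(β̂_i)⁻¹ (β̂_i − Z_i θ̂)`, which equals
the one-stage `e'S⁻¹e` identically; the equivalence test exercises both
code paths.

## Goodness of fit

* `D = e'S⁻¹e`, compared to χ²(n − p): small p-values indicate residual
  variation beyond what the covariance structure explains; large p-values do
  not certify the model.
* Nested models: `D(M₁) − D(M₂) ~ χ²(q)`; a negative difference (non-nested
  misuse) is clamped to 0 with a warning rather than raised, since it is a
  user-facing reporting path.
* `R² = 1 − GRSS/GTSS` with `GTSS = y'S⁻¹y` (no-intercept form; lies in
  [0, 1] because θ = 0 is feasible). Adjusted
  `R²_adj = 1 − (n/(n−p))(1 − R²)` may be negative and is clamped at 0 for
  reporting only (the raw value is retained).
* Study-specific `D̃_i` on `n_i − p` df; saturated studies (`n_i = p`) get
  df 0 and a NaN p-value rather than an error. The joint statistic
  `D̃ = Σ D̃_i ~ χ²(n − Kp)` follows from independence across studies.
* Multivariate Cochran Q sums `(β̂_i − Z_i θ̂)' V(β̂_i)⁻¹ (β̂_i − Z_i θ̂)`
  with df `Gp − r`, where G counts the first-stage data series (a study
  contributing several series counts once per series). `I²` is
  `max(0, (Q − df)/Q) × 100` — Q-based, the convention consistent with how
  such tables are reported; other I² definitions exist.
* Displayed p-values use three decimals with a `<0.001` floor.

## Diagnostics

Decorrelated residuals solve `C e* = e` by forward substitution with the
lower-triangular Cholesky factor of `S` (block-diagonal for pooled fits, so
`e*` respects dataset row order). Under a correct model `e*` is
approximately white; the empirical covariance over repeated fits differs
from identity only by the GLS projection (the average diagonal is
`1 − p/n`). The residual plot draws `e*` against exposure, a zero reference
line, per-covariate-level markers, and LOWESS smoothers (statsmodels
implementation; tricube local linear, `frac = 2/3`, 3 robustifying
iterations — standard defaults). The vertical distances are not directly
interpretable, which the figure annotation states; the plot is read for
patterns across exposure levels. Groups with fewer than 5 points get
markers without a smoother.

Curve prediction re-centres the basis at a user-chosen reference dose
(default: the smallest study reference dose), so RR equals 1 there with a
degenerate CI; intervals come from the delta method on `x(d)'θ̂`, and doses
outside the observed range are flagged, not refused.

## Synthetic data

The generator draws, per study, a full outcome table from the sampling model
matching its design — binomial cases for cumulative incidence, Poisson
against person-time for incidence rate, independent Poisson case and
non-case cells for case-control — with category risks/rates/odds
proportional to `exp(x'θ_i)`. Crude log RRs and SEs are then computed from
the realized counts, so the shared reference group induces exactly the
correlated-error structure the estimators assume, and the analytic
covariance of every generated table is known. Defaults: K = 8 studies, 3
non-referent categories, doses uniform on (0.5, 10] with reference 0, slope
0.05 per dose unit (RR ≈ 1.65 at the top of the range — a moderate,
realistic association), baseline risk/rate 0.10, 2000 subjects or
person-time units per category, equal design mix, no heterogeneity.
Counts are kept large so the asymptotic χ² claims are testable at moderate
replicate numbers; categories with zero cells are redrawn up to 100 times.
Optional per-coefficient heterogeneity (normal deviations) and binary
study-level covariates with interaction effects are available. A single
seeded NumPy generator governs every draw, making datasets byte-identical
across runs.

What the generator does *not* emulate — adjusted (confounder-controlled)
RRs whose SEs depart from crude table arithmetic, unequal or data-dependent
category boundaries, dose measurement error, and selective reporting — means
that passing calibration here shows the estimators and tests are correct
under the stated sampling model, not that real published meta-analyses meet
these assumptions.

The calibration suite (2000 replicates by default, about half a minute)
refits the correctly specified model to each replicate and reports the
rejection rates of the pooled, joint, and nested-difference tests, the
first two moments of D against (n − p, 2(n − p)), and a KS comparison of
the joint deviance to χ²(n − Kp).

## Known limitations

* Fixed effects only. Random-effects estimation is out of scope; the
  decorrelated-residual plot would extend by adding the random-effects
  covariance into the Cholesky factorization, and this is left as an
  extension point.
* Covariance reconstruction needs counts (GL) or counts-plus-SEs (Hamling);
  studies reporting neither can only use `independence`, which understates
  the correlation and distorts the deviance.
* The χ² reference distributions are asymptotic in the per-category counts;
  with sparse tables the specification test can be miscalibrated, and no
  small-sample correction is applied.
* Publication-bias assessment and dose-assignment methods for interval
  data are out of scope.
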