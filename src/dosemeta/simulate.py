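"""Synthetic aggregated dose-response meta-analysis data with known truth.

Each simulated study draws a full 2 x (n_i + 1) outcome table from the
sampling model matching its design — binomial risks for cumulative
incidence, Poisson counts against person-time for incidence rates, and
independent Poisson case/non-case cells for case-control — with category
risks (rates, odds) proportional to exp(x' theta) against the reference
category.  Crude log RRs and their standard errors are then computed from
the realized counts, so the shared reference group induces exactly the
correlated-error structure the estimation modules assume, and the analytic
covariance of each table is known for cross-checking the reconstruction
methods.

Default configuration (the study conditions used throughout the test suite):
8 studies of 4 categories (3 non-referent), doses on (0, 10] with the
reference at 0, a linear log RR trend of 0.05 per dose unit, baseline
risk/rate 0.10, 2000 subjects (or person-time units) per category — large
counts, so the chi-square asymptotics of the deviance are testable — and an
equal mix of the three designs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .data_io import ExposureDataset, Study
from .design_basis import TransformSpec, basis_matrix

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_dataset",
    "calibration_suite",
    "CalibrationReport",
]


@dataclass
class SimulationConfig:
    """Generator settings; the defaults define the reference study conditions."""

    K: int = 8
    categories_per_study: int | tuple = 4       # total categories incl. reference
    dose_range: tuple = (0.0, 10.0)
    spec: TransformSpec = field(default_factory=TransformSpec)
    knots: np.ndarray | None = None             # required for rcs truth
    true_theta: tuple = (0.05,)
    design_mix: dict = field(default_factory=lambda: {
        "cc": 1 / 3, "ci": 1 / 3, "ir": 1 / 3})
    baseline_risk: float = 0.10
    subjects_per_category: int | tuple = 2000
    heterogeneity_sd: float = 0.0
    covariate_effects: dict | None = None       # name -> per-coef effect vector
    seed: int = 12345

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not 0 < self.baseline_risk < 1:
            raise ValueError("baseline risk must be in (0, 1)")
        total = sum(self.design_mix.values())
        self.design_mix = {k: v / total for k, v in self.design_mix.items()}


@dataclass
class SimulationTruth:
    """Ground truth retained alongside a simulated dataset."""

    theta: np.ndarray
    theta_i: list
    designs: list
    covariates: dict
    knots: np.ndarray | None
    seed: int
    tables: list                 # realized (cases, denom) per study


def _draw_int(rng, value) -> int:
    if isinstance(value, (tuple, list)):
        return int(rng.integers(value[0], value[1] + 1))
    return int(value)


def _simulate_study(rng, cfg: SimulationConfig, study_id: str, design: str,
                    theta_i: np.ndarray, covariates: dict) -> Study:
    lo, hi = cfg.dose_range
    span = hi - lo
    n_cat = _draw_int(rng, cfg.categories_per_study)
    if n_cat < 2:
        raise ValueError("studies need at least 2 categories")
    m = _draw_int(rng, cfg.subjects_per_category)

    for _ in range(100):
        ref_dose = lo
        doses = np.sort(rng.uniform(lo + 0.05 * span, hi, size=n_cat - 1))
        if len(np.unique(doses)) != n_cat - 1:
            continue
        all_doses = np.concatenate([[ref_dose], doses])
        B = basis_matrix(all_doses, cfg.spec, ref_dose, cfg.knots)
        eta = B @ theta_i                      # log RR per category, 0 at ref

        if design == "ci":
            risk = cfg.baseline_risk * np.exp(eta)
            if np.any(risk >= 0.95):
                raise ValueError(
                    "true risks approach 1; lower the baseline risk or slope"
                )
            denom = np.full(n_cat, float(m))
            cases = rng.binomial(m, risk).astype(float)
            ok = np.all(cases > 0) and np.all(cases < denom)
        elif design == "ir":
            rate = cfg.baseline_risk * np.exp(eta)
            denom = np.full(n_cat, float(m))   # person-time
            cases = rng.poisson(rate * m).astype(float)
            ok = np.all(cases > 0)
        else:  # cc: independent Poisson case and non-case cells
            mu_cases = cfg.baseline_risk * m * np.exp(eta)
            cases = rng.poisson(mu_cases).astype(float)
            noncases = rng.poisson(np.full(n_cat, float(m))).astype(float)
            denom = noncases
            ok = np.all(cases > 0) and np.all(noncases > 0)
        if not ok:
            continue

        if design == "ci":
            risk_hat = cases / denom
            logrr = np.log(risk_hat / risk_hat[0])
            var = (1 / cases - 1 / denom) + (1 / cases[0] - 1 / denom[0])
        elif design == "ir":
            rate_hat = cases / denom
            logrr = np.log(rate_hat / rate_hat[0])
            var = 1 / cases + 1 / cases[0]
        else:
            odds = cases / denom
            logrr = np.log(odds / odds[0])
            var = (1 / cases + 1 / denom) + (1 / cases[0] + 1 / denom[0])
        se = np.sqrt(var)
        se[0] = 0.0
        logrr[0] = 0.0
        return Study(
            study_id=study_id, design=design, dose=all_doses, logrr=logrr,
            se=se, ref_index=0, cases=cases, denom=denom,
            covariates=dict(covariates),
        )
    raise RuntimeError(
        f"study {study_id}: failed to draw a table without zero cells in "
        f"100 attempts"
    )


def simulate_dataset(cfg: SimulationConfig, rng: np.random.Generator | None = None
                     ) -> tuple[ExposureDataset, SimulationTruth]:
    """Draw a dataset of K studies; reproducible from ``cfg.seed``."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    theta = np.asarray(cfg.true_theta, dtype=float)
    design_names = list(cfg.design_mix)
    design_probs = np.array([cfg.design_mix[d] for d in design_names])

    cov_values: dict[str, np.ndarray] = {}
    if cfg.covariate_effects:
        for name in cfg.covariate_effects:
            cov_values[name] = rng.integers(0, 2, size=cfg.K).astype(float)

    studies, theta_i_all, designs = [], [], []
    for i in range(cfg.K):
        theta_i = theta.copy()
        if cfg.heterogeneity_sd > 0:
            theta_i = theta_i + rng.normal(0.0, cfg.heterogeneity_sd,
                                           size=len(theta))
        covs = {}
        if cfg.covariate_effects:
            for name, effect in cfg.covariate_effects.items():
                z = cov_values[name][i]
                covs[name] = z
                theta_i = theta_i + z * np.asarray(effect, dtype=float)
        design = design_names[int(rng.choice(len(design_names), p=design_probs))]
        study = _simulate_study(rng, cfg, f"study{i + 1:02d}", design,
                                theta_i, covs)
        studies.append(study)
        theta_i_all.append(theta_i)
        designs.append(design)

    dataset = ExposureDataset(studies)
    truth = SimulationTruth(
        theta=theta, theta_i=theta_i_all, designs=designs,
        covariates={k: v.tolist() for k, v in cov_values.items()},
        knots=cfg.knots, seed=cfg.seed,
        tables=[(s.cases.copy(), s.denom.copy()) for s in studies],
    )
    return dataset, truth


@dataclass
class CalibrationReport:
    """Null behaviour of the specification tests over repeated simulation."""

    reps: int
    alpha: float
    n: int
    p: int
    reject_rate_specification: float
    reject_rate_joint: float
    reject_rate_nested: float
    mean_deviance: float
    var_deviance: float
    expected_df: float
    ks_stat_joint: float
    ks_p_joint: float


def calibration_suite(cfg: SimulationConfig, reps: int = 2000,
                      alpha: float = 0.05,
                      cov_method: str = "gl") -> CalibrationReport:
    """Empirical calibration of the deviance tests under the null.

    Repeatedly simulates data from the configured truth, fits the same
    (correctly specified) model, and records the rejection rates of the
    pooled specification test, the joint study-specific test, and — with an
    extra quadratic term whose true coefficient is zero — the nested
    deviance-difference test; also the first two moments of D against the
    chi-square reference (mean n - p, variance 2(n - p)) and a
    Kolmogorov-Smirnov comparison of the joint deviance to chi2(n - K p).
    """
    from .estimation import fit_first_stage, fit_one_stage
    from .gof import (deviance, deviance_difference_test, fit_deviance,
                      joint_specification_test, specification_test)

    if reps < 2:
        raise ValueError("need at least 2 replicates")
    root = np.random.default_rng(cfg.seed)
    seeds = root.integers(0, 2 ** 31 - 1, size=reps)

    bigger = replace(cfg.spec, kind="polynomial", degree=2) \
        if cfg.spec.kind == "linear" else None

    rej_spec = rej_joint = rej_nested = 0
    Ds, Djoints = [], []
    n = p = df_joint = None
    for s in seeds:
        sub = replace(cfg, seed=int(s))
        dataset, _ = simulate_dataset(sub)
        fit = fit_one_stage(dataset, cfg.spec, cov_method, knots=cfg.knots)
        D = fit_deviance(fit)
        n, p = fit.n, fit.r
        df, pval = specification_test(D, n, p)
        rej_spec += pval < alpha
        Ds.append(D)

        sfits = fit_first_stage(dataset, cfg.spec, cov_method, knots=cfg.knots)
        joint = joint_specification_test(sfits)
        df_joint = joint.df
        rej_joint += joint.p_value < alpha
        Djoints.append(joint.deviance)

        if bigger is not None:
            fit2 = fit_one_stage(dataset, bigger, cov_method)
            pnest = deviance_difference_test(D, fit_deviance(fit2),
                                             fit2.r - fit.r)
            rej_nested += pnest < alpha

    Ds = np.asarray(Ds)
    ks = stats.kstest(np.asarray(Djoints), stats.chi2(df_joint).cdf)
    return CalibrationReport(
        reps=reps, alpha=alpha, n=n, p=p,
        reject_rate_specification=rej_spec / reps,
        reject_rate_joint=rej_joint / reps,
        reject_rate_nested=(rej_nested / reps if bigger is not None
                            else float("nan")),
        mean_deviance=float(Ds.mean()),
        var_deviance=float(Ds.var(ddof=1)),
        expected_df=float(n - p),
        ks_stat_joint=float(ks.statistic),
        ks_p_joint=float(ks.pvalue),
    )
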