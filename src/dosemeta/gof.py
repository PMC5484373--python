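"""Goodness-of-fit and heterogeneity statistics for dose-response meta-analysis.

The central quantity is the deviance

    D = (y - X theta_hat)' S^-1 (y - X theta_hat) = e' S^-1 e,

the generalized residual sum of squares of the GLS fit.  Under a correctly
specified fixed-effects model D is asymptotically chi-square with n - p
degrees of freedom (n non-referent log RRs, p pooled parameters), which
yields a specification test; differences of deviances between nested models
are chi-square with q degrees of freedom (q extra parameters).  The
generalized coefficient of determination for the no-intercept GLS model is

    R^2 = 1 - GRSS / GTSS,   GTSS = y' S^-1 y,

with the usual sample-size adjustment.  Study-specific versions replace
(y, X, S, theta) by the study's quantities, and the sum of the K independent
study deviances gives a joint specification test on n - K p degrees of
freedom.  Cochran's multivariate Q and I^2 quantify residual between-study
heterogeneity of the first-stage coefficients around the pooled model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats

from .estimation import PooledFit, StudyFit

__all__ = [
    "GofReport",
    "HeterogeneityReport",
    "deviance",
    "fit_deviance",
    "specification_test",
    "deviance_difference_test",
    "r_squared",
    "adjusted_r_squared",
    "gof_report",
    "study_gof",
    "joint_specification_test",
    "cochran_q",
    "i_squared",
    "format_p",
    "gof_table",
]


@dataclass
class GofReport:
    """Deviance-based goodness-of-fit summary for one fitted model."""

    deviance: float
    df: int
    p_value: float
    r2: float
    r2_adj: float            # raw adjusted value; may be negative
    scope: str               # 'pooled', 'study', or 'joint'

    @property
    def r2_adj_reported(self) -> float:
        """Adjusted R^2 clamped at 0 for reporting."""
        return max(0.0, self.r2_adj)


@dataclass
class HeterogeneityReport:
    """Cochran Q test and I^2 for residual between-study heterogeneity."""

    Q: float
    df: int
    p_value: float
    i2: float                # percent


def _quad_form_inv(e: np.ndarray, S: np.ndarray) -> float:
    """e' S^-1 e through a Cholesky solve (S is never inverted)."""
    e = np.asarray(e, dtype=float).ravel()
    C = linalg.cholesky(np.asarray(S, dtype=float), lower=True)
    z = linalg.solve_triangular(C, e, lower=True)
    return float(z @ z)


def deviance(residuals, S) -> float:
    """Generalized residual sum of squares e' S^-1 e (the deviance D)."""
    return _quad_form_inv(residuals, S)


def fit_deviance(fit: PooledFit) -> float:
    """Deviance of a pooled fit.

    For a one-stage fit this is the quadratic form of its stacked residuals.
    A two-stage fit decomposes identically: the sum of the study deviances
    plus the second-stage quadratic form of beta_hat_i around Z_i theta_hat
    equals the one-stage deviance, so both routes report the same D.
    """
    if fit.stage == "one":
        return deviance(fit.residuals, fit.S)
    within = sum(deviance(f.residuals, f.S) for f in fit.first_stage)
    between = deviance(fit.residuals, fit.S)
    return within + between


def specification_test(D: float, n: int, p: int) -> tuple[int, float]:
    """Chi-square test of model specification: D ~ chi2(n - p) under the null."""
    if n <= p:
        raise ValueError(f"need n > p for the specification test (n={n}, p={p})")
    df = n - p
    return df, float(stats.chi2.sf(D, df))


def deviance_difference_test(D1: float, D2: float, q: int) -> float:
    """Relative fit of nested models: D(M1) - D(M2) ~ chi2(q) under the null.

    M1 is the smaller model; q is the number of extra parameters in M2.
    A negative difference (only possible on non-nested misuse) is clamped
    to zero with a warning.
    """
    if q <= 0:
        raise ValueError("q must be a positive number of extra parameters")
    diff = D1 - D2
    if diff < 0:
        warnings.warn(
            "negative deviance difference clamped to 0; are the models nested?",
            stacklevel=2,
        )
        diff = 0.0
    return float(stats.chi2.sf(diff, q))


def r_squared(y, X, theta_hat, S) -> float:
    """Generalized coefficient of determination 1 - GRSS/GTSS (no intercept)."""
    y = np.asarray(y, dtype=float).ravel()
    gtss = _quad_form_inv(y, S)
    if gtss == 0.0:
        raise ValueError("R^2 undefined: y' S^-1 y is zero")
    e = y - np.atleast_2d(X) @ np.asarray(theta_hat, dtype=float)
    grss = _quad_form_inv(e, S)
    return 1.0 - grss / gtss


def adjusted_r_squared(r2: float, n: int, p: int) -> float:
    """Sample-size adjusted R^2 = 1 - (n / (n - p)) (1 - R^2); may be negative."""
    if n <= p:
        raise ValueError(f"need n > p to adjust R^2 (n={n}, p={p})")
    return 1.0 - (n / (n - p)) * (1.0 - r2)


def _gtss_of(fit: PooledFit) -> float:
    if fit.stage == "one":
        return _quad_form_inv(fit.y, fit.S)
    return sum(_quad_form_inv(f.y, f.S) for f in fit.first_stage)


def gof_report(fit: PooledFit) -> GofReport:
    """Pooled deviance, specification test, R^2, and adjusted R^2 for a fit."""
    D = fit_deviance(fit)
    n, p = fit.n, fit.r
    df, pval = specification_test(D, n, p)
    gtss = _gtss_of(fit)
    r2 = 1.0 - D / gtss
    return GofReport(deviance=D, df=df, p_value=pval, r2=r2,
                     r2_adj=adjusted_r_squared(r2, n, p), scope="pooled")


def study_gof(fit: StudyFit) -> GofReport:
    """Study-specific deviance and R^2 (saturated studies get df 0, p NaN)."""
    D = deviance(fit.residuals, fit.S)
    df = fit.n_i - fit.p
    if df > 0:
        pval = float(stats.chi2.sf(D, df))
    else:
        pval = float("nan")  # saturated: the test is undefined
    gtss = _quad_form_inv(fit.y, fit.S)
    r2 = 1.0 - D / gtss if gtss > 0 else float("nan")
    n, p = fit.n_i, fit.p
    r2_adj = adjusted_r_squared(r2, n, p) if n > p else float("nan")
    return GofReport(deviance=D, df=df, p_value=pval, r2=r2,
                     r2_adj=r2_adj, scope="study")


def joint_specification_test(fits: list[StudyFit]) -> GofReport:
    """Joint test that every study-specific model is correctly specified.

    The studies are independent, so the sum of their deviances is chi-square
    with sum(n_i - p) = n - K p degrees of freedom under the joint null.
    """
    p = fits[0].p
    short = [f.study_id for f in fits if f.n_i < p]
    if short:
        raise ValueError(f"studies with n_i < p: {short}")
    D = sum(deviance(f.residuals, f.S) for f in fits)
    n = sum(f.n_i for f in fits)
    df = n - len(fits) * p
    if df <= 0:
        raise ValueError("joint test undefined: no residual degrees of freedom")
    return GofReport(deviance=D, df=df, p_value=float(stats.chi2.sf(D, df)),
                     r2=float("nan"), r2_adj=float("nan"), scope="joint")


def cochran_q(fits: list[StudyFit], pooled: PooledFit) -> HeterogeneityReport:
    """Multivariate Cochran Q for heterogeneity of first-stage coefficients.

    Q sums the quadratic forms of beta_hat_i - Z_i theta_hat weighted by the
    inverse first-stage covariances; degrees of freedom are G p - r where G
    is the number of data series contributing first-stage fits, p the
    first-stage dimension, and r the number of pooled parameters.
    """
    if pooled.stage == "two":
        Zs = np.split(pooled.X, np.cumsum(
            [f.p for f in pooled.first_stage])[:-1], axis=0)
    else:
        # map the one-stage fit to its second-stage form: identity plus
        # interaction blocks from each study's covariates
        from .estimation import interaction_Z
        covs = (pooled.design_info.spec.interaction_covariates
                if pooled.design_info is not None else ())
        Zs = interaction_Z(fits, covs) if covs else [np.eye(fits[0].p)
                                                     for _ in fits]
    G, p, r = len(fits), fits[0].p, pooled.r
    df = G * p - r
    if df <= 0:
        raise ValueError("Q test undefined: G p - r <= 0")
    Q = 0.0
    for f, Z in zip(fits, Zs):
        resid = f.beta - np.atleast_2d(Z) @ pooled.theta
        Q += _quad_form_inv(resid, f.vbeta)
    return HeterogeneityReport(Q=Q, df=df,
                               p_value=float(stats.chi2.sf(Q, df)),
                               i2=i_squared(Q, df))


def i_squared(Q: float, df: int) -> float:
    """I^2 = max(0, (Q - df) / Q) * 100, the percent of variability
    attributed to between-study heterogeneity."""
    if Q < 0:
        raise ValueError("Q must be non-negative")
    if df < 1:
        raise ValueError("df must be >= 1")
    if Q == 0:
        return 0.0
    return max(0.0, (Q - df) / Q) * 100.0


def format_p(p: float, digits: int = 3) -> str:
    """Display rule for p-values: three decimals, '<0.001' below that."""
    if np.isnan(p):
        return "-"
    floor = 10.0 ** (-digits)
    if p < floor:
        return f"<{floor:.{digits}f}"
    return f"{p:.{digits}f}"


def gof_table(labeled_fits, first_stage=None) -> "pandas.DataFrame":
    """Summary table for a sequence of (label, PooledFit) models.

    Mirrors the usual reporting layout: deviance, its df and specification
    p-value, the relative-fit p-value against the previous model (treated as
    nested), R^2 and adjusted R^2 in percent, and — when the first-stage
    fits are supplied as a parallel list — Q, its df, p-value and I^2.
    """
    import pandas as pd

    rows = []
    prev = None
    for idx, (label, fit) in enumerate(labeled_fits):
        rep = gof_report(fit)
        row = {
            "model": label,
            "deviance": rep.deviance,
            "df": rep.df,
            "p_specification": rep.p_value,
            "p_relative": float("nan"),
            "r2_pct": 100.0 * rep.r2,
            "r2_adj_pct": 100.0 * rep.r2_adj_reported,
        }
        if prev is not None:
            q = prev[1].df - rep.df
            if q > 0:
                row["p_relative"] = deviance_difference_test(
                    prev[0], rep.deviance, q)
        if first_stage is not None:
            het = cochran_q(first_stage[idx], fit)
            row.update({"Q": het.Q, "Q_df": het.df,
                        "p_heterogeneity": het.p_value, "i2_pct": het.i2})
        rows.append(row)
        prev = (rep.deviance, rep)
    return pd.DataFrame(rows)
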