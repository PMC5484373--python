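"""Generalized least squares estimation of pooled dose-response trends.

Two equivalent routes are provided.  The two-stage route first fits the
no-intercept linear model

    y_i = X_i beta_i + eps_i,   V(eps_i) = S_i

within each study by GLS and then pools the estimated coefficient vectors by
multivariate fixed-effects meta-analysis (optionally meta-regression on
study-level covariates).  The one-stage ("pool-first") route stacks all
studies' outcomes, design matrices, and covariances (block-diagonal S) and
runs a single GLS fit.  Under fixed effects the two routes give identical
pooled coefficients, covariance, and deviance.

All solves go through Cholesky whitening; the error covariance is never
inverted explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .covariance import StudyCovariance, get_covariance
from .data_io import ExposureDataset, Z_95
from .design_basis import DesignMatrices, TransformSpec, build_design

__all__ = [
    "GLSResult",
    "StudyFit",
    "PooledFit",
    "gls_fit",
    "fit_first_stage",
    "pool_two_stage",
    "fit_one_stage",
    "interaction_Z",
    "RankError",
]


class RankError(np.linalg.LinAlgError):
    """Design matrix is rank deficient after whitening."""


@dataclass
class GLSResult:
    coef: np.ndarray
    vcov: np.ndarray
    residuals: np.ndarray


def _chol_lower(S: np.ndarray, what: str = "covariance") -> np.ndarray:
    try:
        return linalg.cholesky(np.asarray(S, dtype=float), lower=True)
    except linalg.LinAlgError as exc:
        raise linalg.LinAlgError(f"{what} matrix is not positive definite") from exc


def gls_fit(y, X, S, columns=None) -> GLSResult:
    """GLS estimate (X'S^-1 X)^-1 X'S^-1 y via Cholesky whitening.

    The lower Cholesky factor C of S whitens the problem (solve C W = X,
    C z = y); the estimate is then the ordinary least-squares solution of
    the whitened system, and its covariance is (W'W)^-1.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.shape[0]:
        raise ValueError("y and X have incompatible shapes")
    C = _chol_lower(S)
    Wx = linalg.solve_triangular(C, X, lower=True)
    wy = linalg.solve_triangular(C, y, lower=True)
    Q, R = np.linalg.qr(Wx)
    rdiag = np.abs(np.diag(R))
    tol = max(Wx.shape) * np.finfo(float).eps * (rdiag.max() if rdiag.size else 0.0)
    if np.any(rdiag <= tol):
        bad = [
            (columns[j] if columns is not None else f"column {j}")
            for j in np.flatnonzero(rdiag <= tol)
        ]
        raise RankError(f"design is rank deficient; collinear: {bad}")
    coef = linalg.solve_triangular(R, Q.T @ wy, lower=False)
    Rinv = linalg.solve_triangular(R, np.eye(R.shape[0]), lower=False)
    vcov = Rinv @ Rinv.T
    residuals = y - X @ coef
    return GLSResult(coef=coef, vcov=vcov, residuals=residuals)


@dataclass
class StudyFit:
    """First-stage GLS fit of one study's dose-response model."""

    study_id: str
    beta: np.ndarray
    vbeta: np.ndarray
    cov: StudyCovariance
    residuals: np.ndarray
    x: np.ndarray                     # non-referent doses
    y: np.ndarray                     # non-referent log RRs
    X: np.ndarray                     # study design matrix (n_i x p)
    design: str
    covariates: dict = field(default_factory=dict)

    @property
    def n_i(self) -> int:
        return len(self.y)

    @property
    def p(self) -> int:
        return len(self.beta)

    @property
    def S(self) -> np.ndarray:
        return self.cov.S

    def ci(self, level_z: float = Z_95):
        se = np.sqrt(np.diag(self.vbeta))
        return self.beta - level_z * se, self.beta + level_z * se


@dataclass
class PooledFit:
    """Pooled dose-response fit (one-stage, or second-stage meta-analysis)."""

    theta: np.ndarray
    vtheta: np.ndarray
    stage: str                         # 'one' or 'two'
    y: np.ndarray                      # stacked outcome of the GLS solved
    X: np.ndarray                      # stacked design of the GLS solved
    S: np.ndarray                      # its block-diagonal covariance
    residuals: np.ndarray
    columns: list
    doses: np.ndarray | None = None    # per-row dose (one-stage only)
    row_study: list | None = None      # per-row study id (one-stage only)
    first_stage: list | None = None    # StudyFits behind a two-stage fit
    design_info: DesignMatrices | None = field(repr=False, default=None)
    dataset: ExposureDataset | None = field(repr=False, default=None)

    @property
    def r(self) -> int:
        """Number of pooled parameters."""
        return len(self.theta)

    @property
    def n(self) -> int:
        """Number of non-referent log RRs behind the fit."""
        if self.stage == "one":
            return len(self.y)
        return int(sum(f.n_i for f in self.first_stage))

    def ci(self, level_z: float = Z_95):
        se = np.sqrt(np.diag(self.vtheta))
        return self.theta - level_z * se, self.theta + level_z * se


def fit_first_stage(dataset: ExposureDataset, spec: TransformSpec,
                    cov_method: str = "gl", knots=None) -> list[StudyFit]:
    """Study-specific GLS fits; studies with n_i < p are skipped with a warning."""
    design = build_design(dataset, spec, knots=knots)
    basis_p = design.p // (1 + len(spec.interaction_covariates))
    fits = []
    for s, (sid, X_i) in zip(dataset.studies, design.per_study):
        # first stage uses the exposure basis only; interactions with
        # study-level covariates belong to the second stage
        X_i = X_i[:, :basis_p]
        if s.n_i < basis_p:
            warnings.warn(
                f"study {s.study_id!r} has {s.n_i} non-referent records but "
                f"the model needs {basis_p}; excluded from the first stage",
                stacklevel=2,
            )
            continue
        cov = get_covariance(s, cov_method)
        res = gls_fit(s.y, X_i, cov.S, columns=design.columns[:basis_p])
        fits.append(StudyFit(
            study_id=s.study_id, beta=res.coef, vbeta=res.vcov, cov=cov,
            residuals=res.residuals, x=s.x, y=s.y, X=X_i, design=s.design,
            covariates=dict(s.covariates),
        ))
    if not fits:
        raise ValueError("no study is estimable under this specification")
    return fits


def interaction_Z(fits: list[StudyFit], covariates) -> list[np.ndarray]:
    """Second-stage design rows Z_i = [I_p, z_i1 I_p, ...] for meta-regression.

    The column order matches the one-stage design (basis columns first, then
    basis x covariate blocks), so the pooled parameter vectors of the two
    routes line up entry by entry.
    """
    covariates = tuple(covariates)
    Zs = []
    for f in fits:
        p = f.p
        blocks = [np.eye(p)]
        for cov in covariates:
            if cov not in f.covariates:
                raise KeyError(f"study {f.study_id!r} lacks covariate {cov!r}")
            blocks.append(f.covariates[cov] * np.eye(p))
        Zs.append(np.hstack(blocks))
    return Zs


def pool_two_stage(fits: list[StudyFit], Z=None,
                   columns=None) -> PooledFit:
    """Multivariate fixed-effects meta-analysis of first-stage coefficients.

    ``Z`` is a list of per-study second-stage design matrices (default:
    identity, i.e. plain pooling); each beta_hat_i is modelled as
    N(Z_i theta, V(beta_hat_i)) and theta is the GLS solution weighting by
    the inverse first-stage covariances.
    """
    p = fits[0].p
    if any(f.p != p for f in fits):
        raise ValueError("first-stage fits have inconsistent dimension")
    if Z is None:
        Z = [np.eye(p) for _ in fits]
    Z = [np.atleast_2d(np.asarray(z, dtype=float)) for z in Z]
    r = Z[0].shape[1]
    if len(fits) * p < r:
        raise ValueError("fewer first-stage coefficients than pooled parameters")
    ystack = np.concatenate([f.beta for f in fits])
    Xstack = np.vstack(Z)
    Sstack = linalg.block_diag(*[f.vbeta for f in fits])
    res = gls_fit(ystack, Xstack, Sstack, columns=columns)
    return PooledFit(
        theta=res.coef, vtheta=res.vcov, stage="two",
        y=ystack, X=Xstack, S=Sstack, residuals=res.residuals,
        columns=list(columns) if columns is not None
        else [f"theta{j}" for j in range(r)],
        first_stage=list(fits),
    )


def two_stage(dataset: ExposureDataset, spec: TransformSpec,
              cov_method: str = "gl", knots=None) -> PooledFit:
    """Convenience: first stage plus pooling, with meta-regression taken
    from ``spec.interaction_covariates``."""
    fits = fit_first_stage(dataset, spec, cov_method, knots=knots)
    design = build_design(dataset, spec, knots=knots)
    Z = (interaction_Z(fits, spec.interaction_covariates)
         if spec.interaction_covariates else None)
    pooled = pool_two_stage(fits, Z=Z, columns=design.columns)
    pooled.design_info = design
    pooled.dataset = dataset
    return pooled


def fit_one_stage(dataset: ExposureDataset, spec: TransformSpec,
                  cov_method: str = "gl", knots=None) -> PooledFit:
    """Single GLS fit on the stacked data with block-diagonal covariance."""
    design = build_design(dataset, spec, knots=knots)
    y = np.concatenate([s.y for s in dataset.studies])
    covs = [get_covariance(s, cov_method) for s in dataset.studies]
    S = linalg.block_diag(*[c.S for c in covs])
    res = gls_fit(y, design.X, S, columns=design.columns)
    doses = np.concatenate([s.x for s in dataset.studies])
    row_study = [s.study_id for s in dataset.studies for _ in range(s.n_i)]
    return PooledFit(
        theta=res.coef, vtheta=res.vcov, stage="one",
        y=y, X=design.X, S=S, residuals=res.residuals,
        columns=design.columns, doses=doses, row_study=row_study,
        design_info=design, dataset=dataset,
    )
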