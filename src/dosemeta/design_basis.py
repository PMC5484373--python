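"""Dose transformations and no-intercept design matrices.

The model for a study's non-referent log RRs has no intercept: the log RR is
identically zero at the study's reference dose, so every basis column is
centred by subtracting its value at that reference dose.  Supported
transformations are linear, polynomial, and restricted cubic splines (RCS)
in the Harrell truncated-power form, optionally interacted with study-level
covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import ExposureDataset

__all__ = [
    "TransformSpec",
    "select_knots",
    "rcs_basis",
    "build_design",
    "DesignMatrices",
]


@dataclass
class TransformSpec:
    """Specification of the dose transformation and interactions.

    kind
        ``linear``, ``polynomial`` (degree ``degree``), or ``rcs``.
    knots
        Explicit knot locations for ``rcs``; if None they are placed at
        ``knot_percentiles`` of the pooled non-referent dose distribution.
    normalize_rcs
        Divide the nonlinear RCS columns by the squared knot range (the
        scaling used by some software); off by default so coefficients are
        on the raw truncated-power scale.
    interaction_covariates
        Study-level covariate names whose product with every basis column is
        appended to the design (basis-major, covariate-minor order).
    """

    kind: str = "linear"
    degree: int = 2
    knots: np.ndarray | None = None
    knot_percentiles: tuple = (25.0, 50.0, 75.0)
    normalize_rcs: bool = False
    interaction_covariates: tuple = ()

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "polynomial", "rcs"):
            raise ValueError(f"unknown transform kind {self.kind!r}")
        if self.kind == "polynomial" and self.degree < 1:
            raise ValueError("polynomial degree must be >= 1")
        if self.knots is not None:
            self.knots = np.asarray(self.knots, dtype=float)
        self.interaction_covariates = tuple(self.interaction_covariates)

    @property
    def n_basis(self) -> int:
        """Number of basis columns before interactions."""
        if self.kind == "linear":
            return 1
        if self.kind == "polynomial":
            return self.degree
        if self.knots is None:
            return len(self.knot_percentiles) - 1
        return len(self.knots) - 1


def select_knots(doses, percentiles=(25.0, 50.0, 75.0)) -> np.ndarray:
    """Empirical percentiles of the dose values, used as RCS knots.

    Percentiles are computed with linear interpolation between order
    statistics.  Knots must come out strictly increasing; heavily tied dose
    distributions may need fewer knots.
    """
    doses = np.asarray(doses, dtype=float)
    percentiles = np.asarray(percentiles, dtype=float)
    if np.any(percentiles <= 0) or np.any(percentiles >= 100):
        raise ValueError("percentiles must lie strictly inside (0, 100)")
    if np.any(np.diff(percentiles) <= 0):
        raise ValueError("percentiles must be strictly increasing")
    knots = np.percentile(doses, percentiles, method="linear")
    knots = np.atleast_1d(knots)
    if len(knots) > 1 and np.any(np.diff(knots) <= 0):
        raise ValueError(
            "tied doses produce non-increasing knots; use fewer knots or "
            "different percentiles"
        )
    return knots


def rcs_basis(x, knots, normalize: bool = False) -> np.ndarray:
    """Restricted cubic spline basis (Harrell truncated-power form).

    With k knots t_1 < ... < t_k the basis has k - 1 columns: the identity
    ``x`` plus, for j = 1..k-2,

        f_j(x) = (x - t_j)_+^3
                 - (x - t_{k-1})_+^3 (t_k - t_j) / (t_k - t_{k-1})
                 + (x - t_k)_+^3 (t_{k-1} - t_j) / (t_k - t_{k-1})

    which is cubic between the boundary knots and linear outside them.
    ``normalize`` divides the nonlinear columns by (t_k - t_1)^2.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    knots = np.asarray(knots, dtype=float)
    if len(knots) < 3:
        raise ValueError("restricted cubic splines need at least 3 knots")
    if np.any(np.diff(knots) <= 0):
        raise ValueError("knots must be strictly increasing")
    k = len(knots)
    t_last, t_pen = knots[-1], knots[-2]
    span = t_last - t_pen
    cols = [x]
    for j in range(k - 2):
        t_j = knots[j]
        col = (
            np.clip(x - t_j, 0, None) ** 3
            - np.clip(x - t_pen, 0, None) ** 3 * (t_last - t_j) / span
            + np.clip(x - t_last, 0, None) ** 3 * (t_pen - t_j) / span
        )
        if normalize:
            col = col / (t_last - knots[0]) ** 2
        cols.append(col)
    return np.column_stack(cols)


def _raw_basis(x, spec: TransformSpec, knots) -> np.ndarray:
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if spec.kind == "linear":
        return x[:, None]
    if spec.kind == "polynomial":
        return np.column_stack([x ** d for d in range(1, spec.degree + 1)])
    return rcs_basis(x, knots, normalize=spec.normalize_rcs)


def basis_matrix(x, spec: TransformSpec, reference_dose: float,
                 knots=None) -> np.ndarray:
    """Basis evaluated at ``x`` and centred at the reference dose.

    Centring makes every row vanish at the reference dose, so the fitted
    log RR there is exactly 0 (RR = 1) without an intercept.
    """
    B = _raw_basis(x, spec, knots)
    B0 = _raw_basis([reference_dose], spec, knots)
    return B - B0


@dataclass
class DesignMatrices:
    """Stacked and per-study design matrices for the non-referent records."""

    X: np.ndarray                       # stacked (n x p)
    per_study: list                     # list of (study_id, X_i)
    columns: list                       # column labels
    knots: np.ndarray | None            # knots actually used (rcs only)
    spec: TransformSpec = field(repr=False, default=None)

    @property
    def p(self) -> int:
        return self.X.shape[1]


def build_design(dataset: ExposureDataset, spec: TransformSpec,
                 knots=None) -> DesignMatrices:
    """Design matrix for every non-referent record of the dataset.

    Rows follow dataset order (studies, then dose order within study).  For
    ``rcs`` with no explicit knots, knots are placed at the configured
    percentiles of the pooled non-referent doses (all studies, unweighted).
    Interaction columns are the basis columns multiplied by each study-level
    covariate, appended after the main basis columns.
    """
    if spec.kind == "rcs" and knots is None:
        knots = spec.knots
        if knots is None:
            pooled = np.concatenate([s.x for s in dataset.studies])
            knots = select_knots(pooled, spec.knot_percentiles)

    basis_labels = _basis_labels(spec)
    columns = list(basis_labels)
    for cov in spec.interaction_covariates:
        columns += [f"{b}:{cov}" for b in basis_labels]

    per_study = []
    blocks = []
    for s in dataset.studies:
        B = basis_matrix(s.x, spec, s.ref_dose, knots)
        parts = [B]
        for cov in spec.interaction_covariates:
            if cov not in s.covariates:
                raise KeyError(
                    f"study {s.study_id!r} lacks covariate {cov!r}"
                )
            parts.append(B * s.covariates[cov])
        X_i = np.hstack(parts)
        per_study.append((s.study_id, X_i))
        blocks.append(X_i)
    X = np.vstack(blocks)
    return DesignMatrices(X=X, per_study=per_study, columns=columns,
                          knots=None if spec.kind != "rcs" else np.asarray(knots),
                          spec=spec)


def _basis_labels(spec: TransformSpec) -> list:
    if spec.kind == "linear":
        return ["dose"]
    if spec.kind == "polynomial":
        return [f"dose^{d}" for d in range(1, spec.degree + 1)]
    return ["dose"] + [f"rcs{j}" for j in range(2, spec.n_basis + 1)]
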