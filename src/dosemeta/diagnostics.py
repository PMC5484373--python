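"""Decorrelated residual diagnostics and dose-response curve prediction.

Because the log RRs within a study share a reference group, raw residuals
are correlated and a fitted curve need not pass through the data points, so
plotting one against the other is misleading.  Decorrelating the residuals
through the Cholesky factor of the error covariance (S = C C', e* = C^-1 e)
yields points that, under a correct model, scatter independently around the
zero line; plotting e* against exposure with a LOWESS smoother is the
residual-versus-predictor plot appropriate to this setting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import linalg
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .data_io import Z_95
from .design_basis import basis_matrix
from .estimation import PooledFit, StudyFit

__all__ = [
    "decorrelate",
    "lowess",
    "residual_plot",
    "residual_plot_data",
    "predict_curve",
    "predict_rr",
]


def decorrelate(residuals, S) -> np.ndarray:
    """Solve C e* = e for the lower-triangular Cholesky factor C of S.

    For diagonal S this reduces to dividing each residual by its standard
    deviation; in general the forward substitution removes the correlation
    induced by the shared reference categories.
    """
    e = np.asarray(residuals, dtype=float).ravel()
    C = linalg.cholesky(np.asarray(S, dtype=float), lower=True)
    return linalg.solve_triangular(C, e, lower=True)


def lowess(x, y, frac: float = 2.0 / 3.0, iterations: int = 3) -> np.ndarray:
    """Tricube-weighted robust local linear smoother.

    Returns an array of shape (m, 2) with sorted x and fitted values.
    ``frac`` is the fraction of points in each local window; ``iterations``
    counts the robustifying reweighting passes.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if not 0.0 < frac <= 1.0:
        raise ValueError("frac must be in (0, 1]")
    if len(x) < 5:
        raise ValueError("need at least 5 points to smooth")
    return _sm_lowess(y, x, frac=frac, it=iterations, return_sorted=True)


def _fit_plot_frame(fit, group_by: str | None) -> pd.DataFrame:
    if isinstance(fit, StudyFit):
        e_star = decorrelate(fit.residuals, fit.S)
        frame = pd.DataFrame({"exposure": fit.x, "e_star": e_star})
        if group_by is not None:
            if group_by not in fit.covariates:
                raise KeyError(f"unknown covariate {group_by!r}")
            frame["group"] = fit.covariates[group_by]
        return frame
    if fit.stage != "one":
        raise ValueError(
            "residual diagnostics need the stacked residuals of a one-stage "
            "fit (or a StudyFit)"
        )
    e_star = decorrelate(fit.residuals, fit.S)
    frame = pd.DataFrame({
        "exposure": fit.doses,
        "e_star": e_star,
        "study": fit.row_study,
    })
    if group_by is not None:
        values = {}
        for s in fit.dataset.studies:
            if group_by not in s.covariates:
                raise KeyError(f"unknown covariate {group_by!r}")
            values[s.study_id] = s.covariates[group_by]
        frame["group"] = frame["study"].map(values)
    return frame


def residual_plot_data(fit, group_by: str | None = None) -> pd.DataFrame:
    """Plot-ready table of decorrelated residuals versus exposure."""
    return _fit_plot_frame(fit, group_by)


def residual_plot(fit, group_by: str | None = None, frac: float = 2.0 / 3.0,
                  ax=None):
    """Decorrelated residuals-versus-exposure plot with LOWESS smoothers.

    One smoother per covariate level when ``group_by`` is given (groups with
    fewer than 5 points get markers only).  Returns (frame, figure).
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    frame = _fit_plot_frame(fit, group_by)
    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 4))
    else:
        fig = ax.figure
    ax.axhline(0.0, color="0.4", lw=1)

    markers = ["o", "s", "^", "D", "v", "P", "X"]
    linestyles = ["-", "--", "-.", ":"]
    if "group" in frame.columns:
        levels = sorted(frame["group"].unique())
        for k, level in enumerate(levels):
            sub = frame[frame["group"] == level]
            ax.scatter(sub["exposure"], sub["e_star"],
                       marker=markers[k % len(markers)],
                       facecolors="black" if k == 0 else "none",
                       edgecolors="black", label=f"{group_by}={level}")
            if len(sub) >= 5:
                sm = lowess(sub["exposure"], sub["e_star"], frac=frac)
                ax.plot(sm[:, 0], sm[:, 1], color="black",
                        ls=linestyles[k % len(linestyles)])
        ax.legend(frameon=False, fontsize=8)
    else:
        ax.scatter(frame["exposure"], frame["e_star"], marker="o",
                   facecolors="black", edgecolors="black")
        if len(frame) >= 5:
            sm = lowess(frame["exposure"], frame["e_star"], frac=frac)
            ax.plot(sm[:, 0], sm[:, 1], color="black")
    ax.set_xlabel("Exposure")
    ax.set_ylabel("Decorrelated residuals e*")
    # vertical distances after decorrelation have no direct scale
    ax.set_title("Decorrelated residuals vs exposure\n"
                 "(vertical distances not directly interpretable)",
                 fontsize=9)
    return frame, fig


def predict_rr(basis_row, theta) -> float:
    """Relative risk exp(x' theta) for one centred basis row."""
    return float(np.exp(np.asarray(basis_row, dtype=float)
                        @ np.asarray(theta, dtype=float)))


def predict_curve(fit: PooledFit, doses, covariate_pattern: dict | None = None,
                  reference_dose: float | None = None) -> pd.DataFrame:
    """Pooled dose-response curve with pointwise 95% CI.

    The basis is re-centred at ``reference_dose`` (default: the lowest
    reference dose among the studies), so RR(reference_dose) = 1 exactly.
    ``covariate_pattern`` fixes the study-level covariates entering
    interaction terms.  CIs come from the delta method on x(d)' theta; rows
    outside the observed dose range are flagged ``extrapolated``.
    """
    if fit.design_info is None or fit.dataset is None:
        raise ValueError("fit carries no design information for prediction")
    spec = fit.design_info.spec
    knots = fit.design_info.knots
    if reference_dose is None:
        reference_dose = min(s.ref_dose for s in fit.dataset.studies)
    doses = np.atleast_1d(np.asarray(doses, dtype=float))
    B = basis_matrix(doses, spec, reference_dose, knots)
    parts = [B]
    for cov in spec.interaction_covariates:
        if covariate_pattern is None or cov not in covariate_pattern:
            raise ValueError(f"covariate pattern must set {cov!r}")
        parts.append(B * covariate_pattern[cov])
    Xp = np.hstack(parts)
    eta = Xp @ fit.theta
    se = np.sqrt(np.einsum("ij,jk,ik->i", Xp, fit.vtheta, Xp))
    all_doses = np.concatenate([s.dose for s in fit.dataset.studies])
    lo, hi = all_doses.min(), all_doses.max()
    return pd.DataFrame({
        "dose": doses,
        "rr": np.exp(eta),
        "rr_low": np.exp(eta - Z_95 * se),
        "rr_high": np.exp(eta + Z_95 * se),
        "extrapolated": (doses < lo) | (doses > hi),
    })
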