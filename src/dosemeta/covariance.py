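"""Within-study covariance of correlated log relative risks.

All non-referent relative risks of a study share the same reference
category, so their log RRs are positively correlated.  This module
approximates the covariance matrix ``S_i`` of a study's non-referent log RRs
from the aggregated data, using either of the two established pseudo-count
reconstructions:

* Greenland-Longnecker (``gl``): reconstruct a fitted 2 x (n_i + 1) table of
  pseudo-counts consistent with the reported (possibly adjusted) RRs and the
  table margins; the shared-reference variance term of that table gives the
  covariance between any two non-referent log RRs.
* Hamling (``hamling``): solve for "effective" counts that reproduce each
  reported variance and the RR ratio structure exactly, anchored to the
  observed table margins.

The design determines the variance decomposition of a crude log RR:

=====================  =======================================
incidence-rate (ir)    1/a_j + 1/a_0
cumulative-inc. (ci)   1/a_j - 1/N_j + 1/a_0 - 1/N_0
case-control (cc)      1/a_j + 1/b_j + 1/a_0 + 1/b_0
=====================  =======================================

where ``a`` are cases, ``b`` non-cases, ``N`` totals; the terms involving
the reference category (subscript 0) are common to all non-referent log RRs
and constitute the off-diagonal covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .data_io import Study

__all__ = [
    "StudyCovariance",
    "PseudoTable",
    "gl_covariance",
    "hamling_covariance",
    "independence_covariance",
    "get_covariance",
    "reconstruct_gl_counts",
    "logrr_variance",
    "ConvergenceError",
    "InconsistentDataError",
]

GL_TOL = 1e-8
GL_MAX_ITER = 200


class ConvergenceError(RuntimeError):
    """Pseudo-count reconstruction failed to converge.

    Carries the last iterate (``last_table``) and the iteration count.
    """

    def __init__(self, message, last_table=None, iterations=None):
        super().__init__(message)
        self.last_table = last_table
        self.iterations = iterations


class InconsistentDataError(ValueError):
    """Reported RRs/SEs admit no positive pseudo-count table."""


@dataclass
class PseudoTable:
    """Reconstructed 2 x (n_i + 1) table of pseudo-counts.

    ``a`` holds pseudo-cases per category; ``b`` holds the second margin:
    non-cases for case-control, totals for cumulative incidence, person-time
    for incidence rate.  Categories are in the study's dose order.
    """

    design: str
    a: np.ndarray
    b: np.ndarray
    iterations: int = 0

    def as_array(self) -> np.ndarray:
        return np.vstack([self.a, self.b])


@dataclass
class StudyCovariance:
    """Covariance matrix of one study's non-referent log RRs."""

    study_id: str
    S: np.ndarray
    method: str
    pseudo_counts: PseudoTable | None = None

    def __post_init__(self) -> None:
        self.S = np.atleast_2d(np.asarray(self.S, dtype=float))
        if not np.allclose(self.S, self.S.T):
            raise InconsistentDataError(
                f"study {self.study_id!r}: covariance not symmetric"
            )
        if np.linalg.eigvalsh(self.S)[0] <= 0:
            raise InconsistentDataError(
                f"study {self.study_id!r}: covariance not positive definite "
                f"(reported SEs inconsistent with the reconstructed table)"
            )


def logrr_variance(design: str, pseudo: PseudoTable, j: int, ref: int) -> float:
    """Variance of the log RR of category ``j`` versus category ``ref``."""
    a, b = pseudo.a, pseudo.b
    if design == "ir":
        return 1.0 / a[j] + 1.0 / a[ref]
    if design == "ci":
        return 1.0 / a[j] - 1.0 / b[j] + 1.0 / a[ref] - 1.0 / b[ref]
    if design == "cc":
        nc_j = b[j] - a[j]
        nc_r = b[ref] - a[ref]
        return 1.0 / a[j] + 1.0 / nc_j + 1.0 / a[ref] + 1.0 / nc_r
    raise ValueError(design)


def _shared_term(design: str, pseudo: PseudoTable, ref: int) -> float:
    """Reference-category variance contribution (the covariance term)."""
    a, b = pseudo.a, pseudo.b
    if design == "ir":
        return 1.0 / a[ref]
    if design == "ci":
        return 1.0 / a[ref] - 1.0 / b[ref]
    if design == "cc":
        return 1.0 / a[ref] + 1.0 / (b[ref] - a[ref])
    raise ValueError(design)


def reconstruct_gl_counts(study: Study) -> PseudoTable:
    """Greenland-Longnecker reconstruction of pseudo-counts.

    Finds fitted cases ``a*_j`` such that the crude association measures of
    the fitted table equal the reported (adjusted) RRs while the category
    denominators and the total number of cases match the observed margins.
    For rate and risk ratios the solution is available in closed form; for
    odds ratios (case-control) the reference cell is found by a safeguarded
    Newton iteration on the total-cases constraint, stopping when successive
    pseudo-count tables change by less than 1e-8 (sup norm) or after 200
    iterations.
    """
    if not study.has_counts():
        raise InconsistentDataError(
            f"study {study.study_id!r}: reconstruction requires cases and "
            f"denominators for every category"
        )
    design = study.design
    L = study.logrr
    M1 = float(study.cases.sum())

    if design in ("ir", "ci"):
        T = study.denom  # person-time (ir) or totals (ci)
        w = np.exp(L) * T
        a = M1 * w / w.sum()
        if design == "ci" and np.any(a >= T):
            raise InconsistentDataError(
                f"study {study.study_id!r}: fitted risks exceed 1; reported "
                f"RRs are inconsistent with the category totals"
            )
        return PseudoTable(design=design, a=a, b=T.copy(), iterations=0)

    # case-control: denominators are non-cases, totals N_j = a_j + b_j
    N = study.cases + study.denom
    r0 = study.ref_index

    def table_for(a0: float) -> np.ndarray:
        phi = a0 / (N[r0] - a0)
        r = np.exp(L) * phi
        return N * r / (1.0 + r)

    def f(a0: float) -> float:
        return float(table_for(a0).sum() - M1)

    # f is strictly increasing on (0, N0) with f(0+) = -M1 < 0 and
    # f(N0-) = sum(N) - M1 >= 0, so Newton with bisection safeguard is safe.
    lo, hi = 1e-10, N[r0] * (1.0 - 1e-10)
    a0 = min(max(float(study.cases[r0]), lo), hi)
    prev = table_for(a0)
    for it in range(1, GL_MAX_ITER + 1):
        phi = a0 / (N[r0] - a0)
        r = np.exp(L) * phi
        dphi = N[r0] / (N[r0] - a0) ** 2
        deriv = float((N * np.exp(L) * dphi / (1.0 + r) ** 2).sum())
        fval = f(a0)
        if fval > 0:
            hi = min(hi, a0)
        else:
            lo = max(lo, a0)
        step = fval / deriv if deriv > 0 else 0.0
        a0_new = a0 - step
        if not (lo < a0_new < hi):
            a0_new = 0.5 * (lo + hi)
        cur = table_for(a0_new)
        change = float(np.max(np.abs(cur - prev)))
        a0, prev = a0_new, cur
        if change < GL_TOL:
            return PseudoTable(design="cc", a=cur, b=N.astype(float),
                               iterations=it)
    raise ConvergenceError(
        f"study {study.study_id!r}: Greenland-Longnecker reconstruction did "
        f"not converge in {GL_MAX_ITER} iterations",
        last_table=np.vstack([prev, N]),
        iterations=GL_MAX_ITER,
    )


def _assemble(study: Study, pseudo: PseudoTable, method: str,
              rescale_to_reported: bool) -> StudyCovariance:
    """Build S_i from a pseudo-count table.

    With ``rescale_to_reported`` the pseudo-count variances act only through
    the implied correlations, and the diagonal carries the reported
    variances exactly (the Greenland-Longnecker convention).  Otherwise the
    pseudo-count covariance is used as is (the Hamling convention, whose
    counts already reproduce the reported variances).
    """
    ref = study.ref_index
    nonref = np.flatnonzero(study.nonref_mask)
    c0 = _shared_term(study.design, pseudo, ref)
    vstar = np.array([
        logrr_variance(study.design, pseudo, j, ref) for j in nonref
    ])
    if c0 <= 0 or np.any(vstar <= c0):
        raise InconsistentDataError(
            f"study {study.study_id!r}: reconstructed table implies "
            f"non-positive variance components"
        )
    m = len(nonref)
    S = np.full((m, m), c0)
    np.fill_diagonal(S, vstar)
    if rescale_to_reported:
        v_rep = study.v
        scale = np.sqrt(v_rep / vstar)
        S = S * np.outer(scale, scale)
        np.fill_diagonal(S, v_rep)
    return StudyCovariance(study_id=study.study_id, S=S, method=method,
                           pseudo_counts=pseudo)


def gl_covariance(study: Study) -> StudyCovariance:
    """Greenland-Longnecker covariance of a study's non-referent log RRs."""
    if study.n_i == 0:
        raise InconsistentDataError(
            f"study {study.study_id!r}: no non-referent categories"
        )
    if study.n_i == 1:
        pseudo = reconstruct_gl_counts(study) if study.has_counts() else None
        return StudyCovariance(study.study_id, np.array([[study.v[0]]]),
                               "gl", pseudo)
    pseudo = reconstruct_gl_counts(study)
    return _assemble(study, pseudo, "gl", rescale_to_reported=True)


def _hamling_tables(study: Study):
    """Solve for Hamling effective counts matching reported SEs and RRs."""
    design = study.design
    ref = study.ref_index
    nonref = np.flatnonzero(study.nonref_mask)
    L = study.logrr[nonref]
    v = study.v
    if not study.has_counts():
        raise InconsistentDataError(
            f"study {study.study_id!r}: Hamling reconstruction needs the "
            f"observed margins (cases and denominators)"
        )
    m = study.n_categories

    if design == "ir":
        M1 = float(study.cases.sum())

        def cases_for(a0):
            a = np.empty(m)
            a[ref] = a0
            a[nonref] = 1.0 / (v - 1.0 / a0)
            return a

        def f(a0):
            return float(cases_for(a0).sum() - M1)

        a0_min = 1.0 / v.min() * (1.0 + 1e-10)
        sol = optimize.root_scalar(
            f, x0=max(float(study.cases[ref]), a0_min * 1.01),
            fprime=None, method="secant",
            x1=max(float(study.cases[ref]) * 1.01, a0_min * 1.02),
        )
        if not sol.converged or sol.root <= a0_min / (1 + 1e-10):
            raise ConvergenceError(
                f"study {study.study_id!r}: Hamling solver failed (ir); "
                f"last estimate {getattr(sol, 'root', None)}"
            )
        a = cases_for(sol.root)
        pt = np.empty(m)
        pt[ref] = float(study.denom[ref])
        pt[nonref] = a[nonref] * pt[ref] / (np.exp(L) * a[ref])
        return PseudoTable(design="ir", a=a, b=pt,
                           iterations=sol.iterations)

    if design == "ci":
        M1 = float(study.cases.sum())
        Ntot = float(study.denom.sum())

        def tables_for(u):
            a0, N0 = u
            c = 1.0 / a0 - 1.0 / N0
            k = np.exp(L) * a0 / N0          # fitted risks
            w = v - c
            a_non = (1.0 - k) / w
            N_non = a_non / k
            a = np.empty(m)
            N = np.empty(m)
            a[ref], N[ref] = a0, N0
            a[nonref], N[nonref] = a_non, N_non
            return a, N

        def f(u):
            a, N = tables_for(u)
            return [a.sum() - M1, N.sum() - Ntot]

        x0 = [float(study.cases[ref]), float(study.denom[ref])]
        sol = optimize.root(f, x0, method="hybr")
        a, N = tables_for(sol.x)
        ok = (sol.success and np.all(a > 0) and np.all(N > a)
              and (1.0 / sol.x[0] - 1.0 / sol.x[1]) > 0)
        if not ok:
            raise ConvergenceError(
                f"study {study.study_id!r}: Hamling solver failed (ci); "
                f"residual {sol.fun if hasattr(sol, 'fun') else None}"
            )
        return PseudoTable(design="ci", a=a, b=N, iterations=int(sol.nfev))

    # case-control
    M1 = float(study.cases.sum())
    M0 = float(study.denom.sum())

    def tables_for(u):
        a0, b0 = u
        c = 1.0 / a0 + 1.0 / b0
        k = np.exp(L) * a0 / b0              # fitted odds
        w = v - c
        b_non = (1.0 + 1.0 / k) / w
        a_non = k * b_non
        a = np.empty(m)
        b = np.empty(m)
        a[ref], b[ref] = a0, b0
        a[nonref], b[nonref] = a_non, b_non
        return a, b

    def f(u):
        a, b = tables_for(u)
        return [a.sum() - M1, b.sum() - M0]

    x0 = [float(study.cases[ref]), float(study.denom[ref])]
    sol = optimize.root(f, x0, method="hybr")
    a, b = tables_for(sol.x)
    ok = sol.success and np.all(a > 0) and np.all(b > 0)
    if not ok:
        raise ConvergenceError(
            f"study {study.study_id!r}: Hamling solver failed (cc); "
            f"residual {sol.fun if hasattr(sol, 'fun') else None}"
        )
    # store totals in b (cc convention of PseudoTable)
    return PseudoTable(design="cc", a=a, b=a + b, iterations=int(sol.nfev))


def hamling_covariance(study: Study) -> StudyCovariance:
    """Hamling effective-count covariance of non-referent log RRs."""
    if study.n_i == 0:
        raise InconsistentDataError(
            f"study {study.study_id!r}: no non-referent categories"
        )
    if study.n_i == 1:
        return StudyCovariance(study.study_id, np.array([[study.v[0]]]),
                               "hamling", None)
    pseudo = _hamling_tables(study)
    return _assemble(study, pseudo, "hamling", rescale_to_reported=False)


def independence_covariance(study: Study) -> StudyCovariance:
    """Diagonal covariance ignoring the shared reference (baseline method)."""
    return StudyCovariance(study.study_id, np.diag(study.v), "independence")


_METHODS = {
    "gl": gl_covariance,
    "hamling": hamling_covariance,
    "independence": independence_covariance,
}


def get_covariance(study: Study, method: str = "gl") -> StudyCovariance:
    """Dispatch to a covariance method by name (``gl`` is the default)."""
    try:
        fn = _METHODS[method]
    except KeyError:
        raise ValueError(
            f"unknown covariance method {method!r}; choose from "
            f"{sorted(_METHODS)}"
        ) from None
    return fn(study)
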