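"""Reading, validation and normalization of aggregated dose-response tables.

The input is the long format commonly used to report dose-response results
for binary outcomes: one row per exposure category with the assigned dose,
the number of cases, a denominator (non-cases for case-control studies,
total subjects for cumulative-incidence studies, person-time for
incidence-rate studies), and the reported relative risk with its 95%
confidence interval (or standard error of the log relative risk).  Within a
study every relative risk is taken against the same reference category, whose
log RR is identically 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Study",
    "ExposureDataset",
    "read_dataset",
    "write_dataset",
    "dataset_from_frame",
    "rescale_reference",
    "se_from_ci",
    "ci_from_se",
    "SchemaError",
    "ValidationError",
    "Z_95",
]

#: Normal quantile used for 95% confidence intervals, fixed for reproducibility.
Z_95 = 1.959964

#: Canonical design codes and accepted aliases.
DESIGN_ALIASES = {
    "cc": "cc",
    "case-control": "cc",
    "case control": "cc",
    "ci": "ci",
    "cumulative-incidence": "ci",
    "cumulative incidence": "ci",
    "cohort": "ci",
    "ir": "ir",
    "incidence-rate": "ir",
    "incidence rate": "ir",
}

REQUIRED_COLUMNS = ("id", "design", "dose")


class SchemaError(ValueError):
    """A required column is missing or has an unusable type."""


class ValidationError(ValueError):
    """The table violates an invariant of the aggregated data model."""


def se_from_ci(lower: float, upper: float) -> float:
    """Standard error of the log RR from a 95% CI on the RR scale."""
    return (np.log(upper) - np.log(lower)) / (2.0 * Z_95)


def ci_from_se(log_rr: float, se: float) -> tuple[float, float]:
    """95% CI on the RR scale from a log RR and its standard error."""
    return float(np.exp(log_rr - Z_95 * se)), float(np.exp(log_rr + Z_95 * se))


@dataclass
class Study:
    """All exposure categories of one study, sorted by dose.

    Arrays cover every category including the reference; ``ref_index`` points
    at the reference row (log RR 0, SE 0).  ``cases`` and ``denom`` may be
    None when the study reported no counts, which restricts the covariance
    methods that can be applied to it.
    """

    study_id: str
    design: str
    dose: np.ndarray
    logrr: np.ndarray
    se: np.ndarray
    ref_index: int
    cases: np.ndarray | None = None
    denom: np.ndarray | None = None
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        self.logrr = np.asarray(self.logrr, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        if self.cases is not None:
            self.cases = np.asarray(self.cases, dtype=float)
        if self.denom is not None:
            self.denom = np.asarray(self.denom, dtype=float)
        if self.design not in ("cc", "ci", "ir"):
            raise ValidationError(
                f"study {self.study_id!r}: unknown design {self.design!r}"
            )
        if len(np.unique(self.dose)) != len(self.dose):
            raise ValidationError(f"study {self.study_id!r}: duplicated doses")
        nonref = self.nonref_mask
        if np.any(self.se[nonref] <= 0):
            raise ValidationError(
                f"study {self.study_id!r}: non-reference rows need se > 0"
            )

    @property
    def n_categories(self) -> int:
        return len(self.dose)

    @property
    def n_i(self) -> int:
        """Number of non-referent categories (data points contributed)."""
        return len(self.dose) - 1

    @property
    def nonref_mask(self) -> np.ndarray:
        mask = np.ones(len(self.dose), dtype=bool)
        mask[self.ref_index] = False
        return mask

    @property
    def x(self) -> np.ndarray:
        """Non-referent doses."""
        return self.dose[self.nonref_mask]

    @property
    def y(self) -> np.ndarray:
        """Non-referent log RRs (the outcome vector of the study)."""
        return self.logrr[self.nonref_mask]

    @property
    def v(self) -> np.ndarray:
        """Non-referent variances of the log RRs."""
        return self.se[self.nonref_mask] ** 2

    @property
    def ref_dose(self) -> float:
        return float(self.dose[self.ref_index])

    def has_counts(self) -> bool:
        return self.cases is not None and self.denom is not None


@dataclass
class ExposureDataset:
    """Ordered collection of studies forming the analytical dataset."""

    studies: list[Study]

    def __post_init__(self) -> None:
        if len(self.studies) == 0:
            raise ValidationError("dataset must contain at least one study")
        ids = [s.study_id for s in self.studies]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicated study ids")

    @property
    def K(self) -> int:
        return len(self.studies)

    @property
    def n_i(self) -> np.ndarray:
        return np.array([s.n_i for s in self.studies], dtype=int)

    @property
    def n(self) -> int:
        return int(self.n_i.sum())

    def study(self, study_id: str) -> Study:
        for s in self.studies:
            if s.study_id == study_id:
                return s
        raise KeyError(study_id)

    @property
    def covariate_names(self) -> list[str]:
        names: list[str] = []
        for s in self.studies:
            for k in s.covariates:
                if k not in names:
                    names.append(k)
        return names

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.studies:
            for j in range(s.n_categories):
                row = {
                    "id": s.study_id,
                    "design": s.design,
                    "dose": s.dose[j],
                    "cases": s.cases[j] if s.cases is not None else np.nan,
                    "n": s.denom[j] if s.denom is not None else np.nan,
                    "logrr": s.logrr[j],
                    "se": s.se[j],
                    "ref": int(j == s.ref_index),
                }
                row.update(s.covariates)
                rows.append(row)
        return pd.DataFrame(rows)


def _study_from_rows(study_id: str, rows: pd.DataFrame,
                     covariate_cols: list[str]) -> Study:
    rows = rows.sort_values("dose", kind="mergesort").reset_index(drop=True)
    ref_flags = rows["ref"].astype(bool)
    if ref_flags.sum() != 1:
        raise ValidationError(
            f"study {study_id!r}: expected exactly one reference row, "
            f"found {int(ref_flags.sum())}"
        )
    ref_index = int(np.flatnonzero(ref_flags.to_numpy())[0])
    logrr = rows["logrr"].to_numpy(dtype=float)
    se = rows["se"].to_numpy(dtype=float)
    logrr[ref_index] = 0.0
    se[ref_index] = 0.0
    if np.any(~np.isfinite(logrr)) or np.any(~np.isfinite(se)):
        raise ValidationError(f"study {study_id!r}: non-finite log RR or SE")
    cases = denom = None
    if rows["cases"].notna().all() and rows["n"].notna().all():
        cases = rows["cases"].to_numpy(dtype=float)
        denom = rows["n"].to_numpy(dtype=float)
    covariates = {}
    for c in covariate_cols:
        vals = rows[c].unique()
        if len(vals) != 1:
            raise ValidationError(
                f"study {study_id!r}: covariate {c!r} must be study-level "
                f"(constant within study)"
            )
        covariates[c] = float(vals[0])
    return Study(
        study_id=str(study_id),
        design=rows["design"].iloc[0],
        dose=rows["dose"].to_numpy(dtype=float),
        logrr=logrr,
        se=se,
        ref_index=ref_index,
        cases=cases,
        denom=denom,
        covariates=covariates,
    )


def dataset_from_frame(df: pd.DataFrame,
                       auto_reference: bool = False) -> ExposureDataset:
    """Validate and normalize a long-format table into an ExposureDataset.

    The frame needs columns ``id, design, dose`` plus either ``logrr`` or
    ``rr``, and for non-reference rows either ``se`` or the CI bounds
    ``lci, uci``.  The reference category is flagged by a truthy ``ref``
    column; with ``auto_reference=True`` a missing flag falls back to the
    row with RR = 1 and no CI (an explicit flag always wins).
    """
    df = df.copy()
    df.columns = [str(c).strip().lower() for c in df.columns]
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    if "logrr" not in df.columns and "rr" not in df.columns:
        raise SchemaError("need a 'rr' or 'logrr' column")

    df["design"] = (
        df["design"].astype(str).str.strip().str.lower().map(DESIGN_ALIASES)
    )
    if df["design"].isna().any():
        raise ValidationError("unrecognized study design value")

    for col in ("cases", "n"):
        if col not in df.columns:
            df[col] = np.nan

    # Reference flag: explicit column wins; auto-detection is opt-in.
    if "ref" in df.columns:
        df["ref"] = (
            df["ref"].replace({"true": 1, "false": 0, "True": 1, "False": 0})
            .fillna(0).astype(float).astype(int)
        )
    elif auto_reference:
        rr = df["rr"] if "rr" in df.columns else np.exp(df["logrr"])
        no_ci = df["lci"].isna() if "lci" in df.columns else True
        df["ref"] = ((rr == 1.0) & no_ci).astype(int)
    else:
        raise SchemaError(
            "missing 'ref' column (pass auto_reference=True to detect the "
            "RR=1 row without CI)"
        )

    # Log RR: from rr column when logrr absent.
    if "logrr" not in df.columns:
        rr = df["rr"].to_numpy(dtype=float)
        bad = (~df["ref"].astype(bool)) & ~(rr > 0)
        if bad.any():
            raise ValidationError(
                f"non-positive RR in rows {list(df.index[bad])}"
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            df["logrr"] = np.log(rr)

    # SE: direct or derived from the 95% CI.
    if "se" not in df.columns:
        df["se"] = np.nan
    need_se = df["se"].isna() & ~df["ref"].astype(bool)
    if need_se.any():
        if "lci" not in df.columns or "uci" not in df.columns:
            raise SchemaError("need 'se' or both 'lci' and 'uci' columns")
        lci = df.loc[need_se, "lci"].to_numpy(dtype=float)
        uci = df.loc[need_se, "uci"].to_numpy(dtype=float)
        bad = ~((lci > 0) & (uci > lci))
        if bad.any():
            rows = list(df.index[need_se][bad])
            raise ValidationError(f"non-positive or inverted CI in rows {rows}")
        df.loc[need_se, "se"] = (np.log(uci) - np.log(lci)) / (2.0 * Z_95)
    df.loc[df["ref"].astype(bool), "se"] = 0.0
    df.loc[df["ref"].astype(bool), "logrr"] = 0.0

    known = {"id", "design", "dose", "cases", "n", "rr", "logrr",
             "lci", "uci", "se", "ref"}
    covariate_cols = [c for c in df.columns if c not in known]

    studies = [
        _study_from_rows(sid, rows, covariate_cols)
        for sid, rows in df.groupby("id", sort=False)
    ]
    return ExposureDataset(studies)


def read_dataset(path, auto_reference: bool = False, **csv_options
                 ) -> ExposureDataset:
    """Read a CSV file of aggregated dose-response records.

    See :func:`dataset_from_frame` for the expected columns.
    """
    df = pd.read_csv(path, **csv_options)
    return dataset_from_frame(df, auto_reference=auto_reference)


def write_dataset(dataset: ExposureDataset, path) -> None:
    """Write a dataset back to CSV, preserving numeric fields to full precision."""
    dataset.to_frame().to_csv(path, index=False, float_format="%.17g")


def rescale_reference(dataset: ExposureDataset, study_id: str,
                      new_reference_dose: float) -> ExposureDataset:
    """Re-express one study's log RRs against a different reference category.

    Point estimates shift by the log RR of the new reference
    (log RR'_j = log RR_j - log RR_ref').  Standard errors cannot simply be
    carried over, because they are tied to the old shared reference group:
    they are re-derived from the pseudo-counts reconstructed by the
    Greenland-Longnecker method, which requires the study to report counts.
    """
    from . import covariance as _cov  # deferred: covariance uses Study

    study = dataset.study(study_id)
    matches = np.flatnonzero(np.isclose(study.dose, new_reference_dose))
    if len(matches) == 0:
        raise ValidationError(
            f"study {study_id!r}: dose {new_reference_dose} is not one of "
            f"the study's category doses"
        )
    new_ref = int(matches[0])
    if new_ref == study.ref_index:
        return dataset
    if not study.has_counts():
        raise ValidationError(
            f"study {study_id!r}: rescaling the reference requires case "
            f"counts and denominators to re-derive the standard errors"
        )

    pseudo = _cov.reconstruct_gl_counts(study)
    logrr = study.logrr - study.logrr[new_ref]
    var = np.array([
        _cov.logrr_variance(study.design, pseudo, j, new_ref)
        for j in range(study.n_categories)
    ])
    se = np.sqrt(np.clip(var, 0.0, None))
    logrr = logrr.copy()
    logrr[new_ref] = 0.0
    se[new_ref] = 0.0
    rescaled = replace(study, logrr=logrr, se=se, ref_index=new_ref)
    studies = [rescaled if s.study_id == study_id else s
               for s in dataset.studies]
    return ExposureDataset(studies)
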