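import numpy as np
import pytest

from dosemeta.data_io import Study


def crude_study(design, cases, denom, doses, study_id="s1", covariates=None):
    """Study whose log RRs and SEs are computed directly from a full table.

    The reference is the first category.  Crude measures make the
    pseudo-count reconstructions exactly identifiable, so these studies
    serve as ground truth for the covariance oracles.
    """
    cases = np.asarray(cases, dtype=float)
    denom = np.asarray(denom, dtype=float)
    doses = np.asarray(doses, dtype=float)
    if design == "ci":
        ratio = (cases / denom) / (cases[0] / denom[0])
        var = (1 / cases - 1 / denom) + (1 / cases[0] - 1 / denom[0])
    elif design == "ir":
        ratio = (cases / denom) / (cases[0] / denom[0])
        var = 1 / cases + 1 / cases[0]
    elif design == "cc":
        ratio = (cases / denom) / (cases[0] / denom[0])
        var = (1 / cases + 1 / denom) + (1 / cases[0] + 1 / denom[0])
    else:
        raise ValueError(design)
    logrr = np.log(ratio)
    se = np.sqrt(var)
    logrr[0] = 0.0
    se[0] = 0.0
    return Study(
        study_id=study_id, design=design, dose=doses, logrr=logrr, se=se,
        ref_index=0, cases=cases, denom=denom,
        covariates=covariates or {},
    )


def analytic_covariance(study):
    """Delta-method covariance of crude log RRs sharing a reference group."""
    c, d = study.cases, study.denom
    if study.design == "ci":
        shared = 1 / c[0] - 1 / d[0]
        own = 1 / c[1:] - 1 / d[1:]
    elif study.design == "ir":
        shared = 1 / c[0]
        own = 1 / c[1:]
    else:
        shared = 1 / c[0] + 1 / d[0]
        own = 1 / c[1:] + 1 / d[1:]
    S = np.full((study.n_i, study.n_i), shared)
    np.fill_diagonal(S, own + shared)
    return S


@pytest.fixture
def ci_table():
    """Fully counted cumulative-incidence study, 2 non-referent categories."""
    return crude_study("ci", cases=[50, 80, 120], denom=[1000, 1000, 1000],
                       doses=[0.0, 4.0, 8.0])


@pytest.fixture
def default_dataset():
    from dosemeta.simulate import SimulationConfig, simulate_dataset

    dataset, truth = simulate_dataset(SimulationConfig(seed=2024))
    return dataset, truth
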