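import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dosemeta.data_io import ExposureDataset
from dosemeta.design_basis import TransformSpec, select_knots
from dosemeta.estimation import (
    RankError,
    StudyFit,
    fit_first_stage,
    fit_one_stage,
    gls_fit,
    interaction_Z,
    pool_two_stage,
    two_stage,
)
from dosemeta.covariance import StudyCovariance
from dosemeta.gof import fit_deviance
from dosemeta.simulate import SimulationConfig, simulate_dataset

from conftest import crude_study


class TestGlsFit:
    def test_hand_solved_regression_through_origin(self):
        # X = (1, 2)', y = (1, 3)', S = I: slope = (1 + 6)/(1 + 4) = 1.4
        res = gls_fit([1.0, 3.0], [[1.0], [2.0]], np.eye(2))
        assert res.coef[0] == pytest.approx(1.4, rel=1e-12)
        np.testing.assert_allclose(res.residuals, [-0.4, 0.2], rtol=1e-12)
        assert res.vcov[0, 0] == pytest.approx(0.2, rel=1e-12)

    def test_perfect_fit_recovers_coefficients(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(6, 2))
        theta = np.array([0.3, -1.2])
        A = rng.normal(size=(6, 6))
        S = A @ A.T + 6 * np.eye(6)
        res = gls_fit(X @ theta, X, S)
        np.testing.assert_allclose(res.coef, theta, rtol=1e-10)
        np.testing.assert_allclose(res.residuals, 0.0, atol=1e-10)

    @given(c=st.floats(min_value=1e-3, max_value=1e3))
    @settings(deadline=None, max_examples=25)
    def test_coef_invariant_to_covariance_scale(self, c):
        X = np.array([[1.0, 0.5], [2.0, -1.0], [3.0, 0.2], [1.5, 2.0]])
        y = np.array([1.0, 0.5, 2.0, -0.3])
        S = np.array([[2.0, 0.5, 0, 0], [0.5, 1.0, 0.2, 0],
                      [0, 0.2, 1.5, 0.3], [0, 0, 0.3, 1.2]])
        base = gls_fit(y, X, S)
        scaled = gls_fit(y, X, c * S)
        np.testing.assert_allclose(scaled.coef, base.coef, rtol=1e-8)
        np.testing.assert_allclose(scaled.vcov, c * base.vcov, rtol=1e-8)

    def test_rank_deficiency_names_columns(self):
        X = np.column_stack([np.arange(4.0), 2 * np.arange(4.0)])
        with pytest.raises(RankError, match="x2"):
            gls_fit(np.arange(4.0), X, np.eye(4), columns=["x1", "x2"])

    def test_residuals_orthogonal_in_whitened_metric(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(8, 2))
        y = rng.normal(size=8)
        A = rng.normal(size=(8, 8))
        S = A @ A.T + 8 * np.eye(8)
        res = gls_fit(y, X, S)
        ortho = X.T @ np.linalg.solve(S, res.residuals)
        np.testing.assert_allclose(ortho, 0.0, atol=1e-10)


class TestFirstStage:
    def test_single_nonreferent_point_gives_ratio_slope(self):
        s = crude_study("ir", [40, 80], [500, 500], [0.0, 4.0])
        fits = fit_first_stage(ExposureDataset([s]), TransformSpec(),
                               cov_method="independence")
        assert fits[0].beta[0] == pytest.approx(s.y[0] / 4.0, rel=1e-12)

    def test_underdetermined_study_skipped_with_warning(self):
        s1 = crude_study("ir", [40, 80], [500, 500], [0.0, 4.0],
                         study_id="tiny")
        s2 = crude_study("ir", [40, 60, 80, 90], [500] * 4,
                         [0.0, 2.0, 5.0, 8.0], study_id="big")
        ds = ExposureDataset([s1, s2])
        spec = TransformSpec(kind="polynomial", degree=2)
        with pytest.warns(UserWarning, match="tiny"):
            fits = fit_first_stage(ds, spec)
        assert [f.study_id for f in fits] == ["big"]

    def test_correlated_errors_pull_fit_off_the_points(self):
        """With positive residual correlation the GLS line need not pass
        through any data point even when it minimizes the deviance."""
        s = crude_study("cc", [30, 60, 45], [100, 100, 100], [0.0, 3.0, 6.0])
        fits = fit_first_stage(ExposureDataset([s]), TransformSpec(),
                               cov_method="gl")
        assert np.all(np.abs(fits[0].residuals) > 1e-3)


class TestTwoStage:
    def test_single_study_pooling_is_identity(self):
        s = crude_study("ci", [50, 70, 90], [1000] * 3, [0.0, 3.0, 7.0])
        fits = fit_first_stage(ExposureDataset([s]), TransformSpec())
        pooled = pool_two_stage(fits)
        np.testing.assert_allclose(pooled.theta, fits[0].beta)
        np.testing.assert_allclose(pooled.vtheta, fits[0].vbeta)

    def test_two_studies_unit_variance_average(self):
        def fake_fit(sid, beta):
            cov = StudyCovariance(sid, np.eye(1), "independence")
            return StudyFit(study_id=sid, beta=np.array([beta]),
                            vbeta=np.eye(1), cov=cov,
                            residuals=np.zeros(1), x=np.ones(1),
                            y=np.array([beta]), X=np.ones((1, 1)),
                            design="ci")

        pooled = pool_two_stage([fake_fit("a", 1.0), fake_fit("b", 3.0)])
        assert pooled.theta[0] == pytest.approx(2.0)
        assert pooled.vtheta[0, 0] == pytest.approx(0.5)

    def test_more_parameters_than_coefficients_rejected(self):
        s = crude_study("ci", [50, 70, 90], [1000] * 3, [0.0, 3.0, 7.0])
        fits = fit_first_stage(ExposureDataset([s]), TransformSpec())
        with pytest.raises(ValueError, match="fewer"):
            pool_two_stage(fits, Z=[np.ones((1, 3))])


def _random_case(seed):
    rng = np.random.default_rng(seed)
    K = int(rng.integers(3, 13))
    kind = rng.choice(["linear", "rcs"])
    interact = bool(rng.integers(0, 2))
    cfg = SimulationConfig(
        K=K, seed=int(rng.integers(0, 2 ** 31 - 1)),
        categories_per_study=int(rng.integers(4, 7)),
        covariate_effects={"z": (0.02,)} if interact else None,
        heterogeneity_sd=0.01,
    )
    dataset, _ = simulate_dataset(cfg)
    knots = (select_knots(np.concatenate([s.x for s in dataset.studies]))
             if kind == "rcs" else None)
    spec = TransformSpec(kind=kind, knots=knots,
                         interaction_covariates=("z",) if interact else ())
    cov = ["gl", "hamling", "independence"][int(rng.integers(0, 3))]
    return dataset, spec, cov


@pytest.mark.parametrize("seed", [101, 202, 303, 404, 505, 606])
def test_one_stage_equals_two_stage(seed):
    """Pooling first-stage coefficients and pooling the raw data give the
    same estimate, covariance, and deviance under fixed effects."""
    dataset, spec, cov = _random_case(seed)
    one = fit_one_stage(dataset, spec, cov)
    two = two_stage(dataset, spec, cov)
    np.testing.assert_allclose(one.theta, two.theta, rtol=1e-8)
    np.testing.assert_allclose(one.vtheta, two.vtheta, rtol=1e-8)
    assert fit_deviance(one) == pytest.approx(fit_deviance(two), rel=1e-8)


def test_parameter_recovery_large_counts():
    cfg = SimulationConfig(seed=77, K=10, subjects_per_category=5000)
    dataset, truth = simulate_dataset(cfg)
    fit = fit_one_stage(dataset, TransformSpec(), "gl")
    se = np.sqrt(fit.vtheta[0, 0])
    assert abs(fit.theta[0] - truth.theta[0]) < 3 * se


def test_interaction_Z_matches_one_stage_columns():
    cfg = SimulationConfig(seed=9, K=5, covariate_effects={"z": (0.03,)})
    dataset, _ = simulate_dataset(cfg)
    fits = fit_first_stage(dataset, TransformSpec())
    Zs = interaction_Z(fits, ("z",))
    for f, Z in zip(fits, Zs):
        np.testing.assert_allclose(Z, [[1.0, f.covariates["z"]]])
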