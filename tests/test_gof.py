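import numpy as np
import pytest

from dosemeta.covariance import StudyCovariance
from dosemeta.data_io import ExposureDataset
from dosemeta.design_basis import TransformSpec
from dosemeta.estimation import (
    StudyFit,
    fit_first_stage,
    fit_one_stage,
    gls_fit,
    pool_two_stage,
)
from dosemeta.gof import (
    adjusted_r_squared,
    cochran_q,
    deviance,
    deviance_difference_test,
    fit_deviance,
    format_p,
    gof_report,
    gof_table,
    i_squared,
    joint_specification_test,
    r_squared,
    specification_test,
    study_gof,
)
from dosemeta.simulate import SimulationConfig, simulate_dataset

from conftest import crude_study


class TestDeviance:
    def test_zero_residuals_zero_deviance(self):
        assert deviance(np.zeros(3), np.eye(3)) == 0.0

    def test_hand_example_continues_gls_fixture(self):
        # residuals of the through-origin fit of y=(1,3) on x=(1,2)
        assert deviance([-0.4, 0.2], np.eye(2)) == pytest.approx(0.2)

    def test_nonnegative_quadratic_form(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            e = rng.normal(size=4)
            A = rng.normal(size=(4, 4))
            S = A @ A.T + 4 * np.eye(4)
            assert deviance(e, S) >= 0


class TestSpecificationTest:
    def test_degrees_of_freedom_and_tail(self):
        df, p = specification_test(0.0, 10, 2)
        assert df == 8 and p == 1.0

    def test_n_not_larger_than_p_rejected(self):
        with pytest.raises(ValueError):
            specification_test(1.0, 2, 2)

    def test_mean_deviance_matches_df_on_simulation(self):
        cfg = SimulationConfig(seed=314)
        Ds, df = [], None
        for s in range(150):
            ds, _ = simulate_dataset(SimulationConfig(seed=1000 + s))
            fit = fit_one_stage(ds, TransformSpec(), "gl")
            Ds.append(fit_deviance(fit))
            df = fit.n - fit.r
        Ds = np.asarray(Ds)
        mc_se = np.sqrt(Ds.var(ddof=1) / len(Ds))
        assert abs(Ds.mean() - df) < 3 * mc_se


class TestDevianceDifference:
    def test_equal_deviances_give_p_one(self):
        assert deviance_difference_test(5.0, 5.0, 1) == 1.0

    def test_negative_difference_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            p = deviance_difference_test(3.0, 5.0, 1)
        assert p == 1.0

    def test_nonpositive_q_rejected(self):
        with pytest.raises(ValueError):
            deviance_difference_test(5.0, 3.0, 0)


class TestRSquared:
    def test_hand_example(self):
        # GTSS = 1 + 9 = 10, GRSS = 0.2
        r2 = r_squared([1.0, 3.0], [[1.0], [2.0]], [1.4], np.eye(2))
        assert r2 == pytest.approx(0.98)

    def test_perfect_fit_is_one(self):
        r2 = r_squared([1.0, 2.0], [[1.0], [2.0]], [1.0], np.eye(2))
        assert r2 == pytest.approx(1.0)

    def test_zero_coefficients_give_zero(self):
        r2 = r_squared([1.0, 3.0], [[1.0], [2.0]], [0.0], np.eye(2))
        assert r2 == 0.0

    def test_zero_outcome_rejected(self):
        with pytest.raises(ValueError):
            r_squared([0.0, 0.0], [[1.0], [2.0]], [1.0], np.eye(2))

    def test_adjusted_below_r2_and_equal_at_one(self):
        assert adjusted_r_squared(1.0, 30, 3) == pytest.approx(1.0)
        for r2 in (0.0, 0.3, 0.9):
            assert adjusted_r_squared(r2, 30, 3) < r2


class TestStudyAndJoint:
    def test_saturated_study_flagged(self):
        s = crude_study("ir", [40, 80], [500, 500], [0.0, 4.0])
        fits = fit_first_stage(ExposureDataset([s]), TransformSpec())
        rep = study_gof(fits[0])
        assert rep.df == 0
        assert rep.deviance == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(rep.p_value)

    def test_joint_is_sum_of_study_deviances(self):
        ds, _ = simulate_dataset(SimulationConfig(seed=21))
        fits = fit_first_stage(ds, TransformSpec())
        joint = joint_specification_test(fits)
        total = sum(study_gof(f).deviance for f in fits)
        assert joint.deviance == pytest.approx(total, rel=1e-12)
        assert joint.df == sum(f.n_i for f in fits) - len(fits)

    def test_joint_df_for_nine_study_configuration(self):
        # 9 studies contributing 28 non-referent log RRs, linear model:
        # the joint test runs on n - K p = 28 - 9 = 19 degrees of freedom
        studies = [
            crude_study("ir", [40, 60, 75, 90], [500] * 4,
                        [0.0, 2.0, 5.0, 8.0], study_id=f"s{i}")
            for i in range(8)
        ]
        studies.append(crude_study("ir", [40, 55, 65, 80, 95], [500] * 5,
                                   [0.0, 1.0, 3.0, 6.0, 9.0], study_id="s8"))
        ds = ExposureDataset(studies)
        assert ds.n == 28 and ds.K == 9
        fits = fit_first_stage(ds, TransformSpec())
        assert joint_specification_test(fits).df == 19


class TestHeterogeneity:
    @staticmethod
    def _fake_fit(sid, beta, var=1.0):
        cov = StudyCovariance(sid, np.eye(1), "independence")
        return StudyFit(study_id=sid, beta=np.array([beta]),
                        vbeta=np.array([[var]]), cov=cov,
                        residuals=np.zeros(1), x=np.ones(1),
                        y=np.array([beta]), X=np.ones((1, 1)), design="ci")

    def test_identical_coefficients_give_zero_q(self):
        fits = [self._fake_fit(s, 0.5) for s in "abc"]
        het = cochran_q(fits, pool_two_stage(fits))
        assert het.Q == pytest.approx(0.0, abs=1e-20)
        assert het.i2 == 0.0

    def test_hand_computed_q(self):
        # beta = (0, 2), unit variances -> theta = 1, Q = 1 + 1 = 2
        fits = [self._fake_fit("a", 0.0), self._fake_fit("b", 2.0)]
        het = cochran_q(fits, pool_two_stage(fits))
        assert het.Q == pytest.approx(2.0)
        assert het.df == 1

    def test_df_counts_series_and_pooled_parameters(self):
        fits = [self._fake_fit(str(i), 0.1 * i) for i in range(9)]
        het = cochran_q(fits, pool_two_stage(fits))
        assert het.df == 9 * 1 - 1

    def test_i_squared_values(self):
        assert i_squared(10.0, 10) == 0.0
        assert i_squared(20.0, 10) == pytest.approx(50.0)
        with pytest.raises(ValueError):
            i_squared(-1.0, 5)
        with pytest.raises(ValueError):
            i_squared(5.0, 0)


class TestMonotoneNesting:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_adding_columns_never_hurts_fit(self, seed):
        ds, _ = simulate_dataset(SimulationConfig(seed=seed))
        small = fit_one_stage(ds, TransformSpec(), "gl")
        big = fit_one_stage(ds, TransformSpec(kind="polynomial", degree=2),
                            "gl")
        assert fit_deviance(big) <= fit_deviance(small) + 1e-10
        assert gof_report(big).r2 >= gof_report(small).r2 - 1e-10


def test_format_p_floor():
    assert format_p(0.0004) == "<0.001"
    assert format_p(0.04) == "0.040"


def test_gof_table_contains_relative_fit_column():
    ds, _ = simulate_dataset(SimulationConfig(seed=8))
    m1 = fit_one_stage(ds, TransformSpec(), "gl")
    m2 = fit_one_stage(ds, TransformSpec(kind="polynomial", degree=2), "gl")
    f1 = fit_first_stage(ds, TransformSpec(), "gl")
    f2 = fit_first_stage(ds, TransformSpec(kind="polynomial", degree=2), "gl")
    table = gof_table([("linear", m1), ("quadratic", m2)], [f1, f2])
    assert np.isnan(table.loc[0, "p_relative"])
    assert 0 <= table.loc[1, "p_relative"] <= 1
    assert {"Q", "i2_pct"} <= set(table.columns)
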