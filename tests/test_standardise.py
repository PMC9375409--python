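import numpy as np
import pandas as pd
import pytest

from standcomp import (
    AtSpec,
    CauseModelSet,
    ContrastSpec,
    FPMSpec,
    SurvivalDataset,
    contrast,
    default_timevar,
    delta_method,
    fit,
    separable,
    std_cif,
    std_failure,
    std_rmft,
    std_survival,
)
from standcomp.nonparam import aalen_johansen
from standcomp.simulate import default_spec, simulate

AT0 = AtSpec({"x": 0.0})
AT1 = AtSpec({"x": 1.0})


class TestDeltaMethod:
    def test_linear_function_exact(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(4, 4))
        vcov = A @ A.T + np.eye(4)
        a = np.array([1.0, -2.0, 0.5, 3.0])
        theta = rng.normal(size=4)
        se = delta_method(lambda th: np.array([a @ th]), theta, vcov)
        assert se[0] == pytest.approx(np.sqrt(a @ vcov @ a), rel=1e-8)

    def test_exp_closed_form(self):
        vcov = np.array([[0.04]])
        theta = np.array([1.3])
        se = delta_method(lambda th: np.array([np.exp(th[0])]), theta, vcov)
        assert se[0] == pytest.approx(np.exp(1.3) * 0.2, rel=1e-8)

    def test_nonfinite_jacobian_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            delta_method(
                lambda th: np.array([np.sqrt(th[0])]), np.array([0.0]), np.eye(1)
            )


class TestStdFailure:
    def test_zero_time_exact(self, fitted_pair, sim_data):
        curve = std_failure(fitted_pair["c1"], sim_data, AT1, np.array([0.0, 30.0]))
        assert curve.estimate[0] == 0.0
        assert curve.se[0] == 0.0

    def test_single_subject_equals_conditional(self, fitted_pair, sim_data):
        model = fitted_pair["c1"]
        one = sim_data.subset(np.arange(sim_data.n) == 0)
        t = np.array([0.0, 12.0, 36.0, 60.0])
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore", RuntimeWarning)  # 1-row support check
            curve = std_failure(model, one, AT1, t)
        z = one.covariates.iloc[0].to_dict()
        z["x"] = 1.0
        expected = 1.0 - model.predict_survival(t, z)
        assert np.array_equal(curve.estimate, expected)

    def test_nonmarginal_mode_equals_conditional(self, fitted_pair, sim_data):
        model = fitted_pair["c1"]
        at = AtSpec(
            {"x": 1.0, "age1": 0.0, "age2": 1.0, "comorb": 0.0}, subset="first"
        )
        t = np.array([24.0, 48.0])
        curve = std_failure(model, sim_data, at, t)
        expected = 1.0 - model.predict_survival(
            t, {"x": 1.0, "age1": 0.0, "age2": 1.0, "comorb": 0.0}
        )
        assert np.allclose(curve.estimate, expected, atol=1e-14)

    def test_unknown_at_name_rejected(self, fitted_pair, sim_data):
        with pytest.raises(ValueError, match="does not appear"):
            std_failure(
                fitted_pair["c1"], sim_data, AtSpec({"nope": 1.0}), np.array([10.0])
            )

    def test_out_of_support_assignment_warns(self, fitted_pair, sim_data):
        with pytest.warns(RuntimeWarning, match="support"):
            std_failure(
                fitted_pair["c1"], sim_data, AtSpec({"x": 7.0}), np.array([10.0])
            )

    def test_monotone_and_bounded(self, fitted_pair, sim_data):
        curve = std_failure(fitted_pair["c1"], sim_data, AT0, default_timevar())
        assert np.all(curve.estimate >= 0) and np.all(curve.estimate <= 1)
        assert np.all(np.diff(curve.estimate) >= -1e-12)
        assert np.all(curve.ci_low <= curve.estimate + 1e-12)
        assert np.all(curve.estimate <= curve.ci_high + 1e-12)

    def test_order_invariance(self, fitted_pair, sim_data):
        rng = np.random.default_rng(5)
        perm = rng.permutation(sim_data.n)
        shuffled = sim_data.subset(perm)
        t = np.array([12.0, 36.0, 60.0])
        c1 = std_failure(fitted_pair["c1"], sim_data, AT1, t)
        c2 = std_failure(fitted_pair["c1"], shuffled, AT1, t)
        assert np.allclose(c1.estimate, c2.estimate, atol=1e-14)
        assert np.allclose(c1.se, c2.se, atol=1e-12)


class TestStdCif:
    def test_zero_time_exact(self, fitted_pair, sim_data):
        curve = std_cif(
            fitted_pair, sim_data, AT1, np.array([0.0, 36.0]), "c1",
            check_quadrature=False,
        )
        assert curve.estimate[0] == 0.0

    def test_requires_two_models(self, fitted_pair, sim_data):
        single = CauseModelSet((fitted_pair["c1"],), ("c1",))
        with pytest.raises(ValueError, match="at least 2"):
            std_cif(single, sim_data, AT1, np.array([10.0]), "c1")

    def test_additivity_with_all_cause_survival(self, fitted_pair, sim_data):
        t = default_timevar()
        c1 = std_cif(fitted_pair, sim_data, AT1, t, "c1", check_quadrature=False)
        c2 = std_cif(fitted_pair, sim_data, AT1, t, "c2", check_quadrature=False)
        s = std_survival(fitted_pair, sim_data, AT1, t)
        assert np.max(np.abs(c1.estimate + c2.estimate + s.estimate - 1.0)) < 1e-6

    def test_monotone_nondecreasing(self, fitted_pair, sim_data):
        curve = std_cif(
            fitted_pair, sim_data, AT0, default_timevar(), "c2",
            check_quadrature=False,
        )
        assert np.all(np.diff(curve.estimate) >= -1e-10)

    def test_covariate_free_matches_aalen_johansen(self):
        spec = default_spec(n=10000, seed=21)
        data = simulate(spec)
        m1 = fit(data, FPMSpec(df=3), event_cause=1)
        m2 = fit(data, FPMSpec(df=3), event_cause=2)
        models = CauseModelSet((m1, m2), ("c1", "c2"))
        aj = aalen_johansen(data.time, data.cause)
        t = np.linspace(1.0, 59.0, 30)
        curve = std_cif(
            models, data, AtSpec({}), t, "c1", check_quadrature=False
        )
        assert np.max(np.abs(curve.estimate - aj[1](t))) < 0.01

    def test_order_invariance(self, fitted_pair, sim_data):
        rng = np.random.default_rng(6)
        perm = rng.permutation(sim_data.n)
        t = np.array([36.0])
        a = std_cif(fitted_pair, sim_data, AT1, t, "c1", check_quadrature=False)
        b = std_cif(
            fitted_pair, sim_data.subset(perm), AT1, t, "c1", check_quadrature=False
        )
        assert a.estimate[0] == pytest.approx(b.estimate[0], abs=1e-14)
        assert a.se[0] == pytest.approx(b.se[0], abs=1e-12)


@pytest.mark.filterwarnings("ignore:t_star=.*linear tail:RuntimeWarning")
class TestStdRmft:
    def test_zero_horizon_exact(self, fitted_pair, sim_data):
        r = std_rmft(fitted_pair, sim_data, AT1, 0.0, "c1")
        assert r.estimate[0] == 0.0

    def test_matches_trapezoid_of_cif(self, fitted_pair, sim_data):
        t_star = 60.0
        grid = np.arange(0.0, t_star + 1e-9, 0.05)
        cif = std_cif(
            fitted_pair, sim_data, AT1, grid, "c2", nodes=50, check_quadrature=False
        )
        trapz = np.trapezoid(cif.estimate, grid)
        r = std_rmft(fitted_pair, sim_data, AT1, t_star, "c2")
        assert r.estimate[0] == pytest.approx(trapz, abs=0.01)

    def test_monotone_in_horizon(self, fitted_pair, sim_data):
        vals = [
            std_rmft(fitted_pair, sim_data, AT0, ts, "c1").estimate[0]
            for ts in (12.0, 36.0, 60.0)
        ]
        assert vals[0] < vals[1] < vals[2]

    def test_warns_beyond_last_knot(self, fitted_pair, sim_data):
        with pytest.warns(RuntimeWarning, match="linear tail"):
            std_rmft(fitted_pair, sim_data, AT0, 2000.0, "c1")


@pytest.mark.filterwarnings("ignore:t_star=.*linear tail:RuntimeWarning")
class TestContrast:
    def test_self_difference_identically_zero(self, fitted_pair, sim_data):
        t = np.array([0.0, 12.0, 36.0, 60.0])
        a = std_cif(fitted_pair, sim_data, AT1, t, "c1", check_quadrature=False)
        b = std_cif(fitted_pair, sim_data, AT1, t, "c1", check_quadrature=False)
        res = contrast([a, b], ContrastSpec(kind="difference"))
        assert np.all(res.estimate == 0.0)
        assert np.all(res.se == 0.0)

    def test_ratio_of_identical_curves_is_one(self, fitted_pair, sim_data):
        t = np.array([12.0, 36.0])
        a = std_cif(fitted_pair, sim_data, AT1, t, "c1", check_quadrature=False)
        res = contrast([a, a], ContrastSpec(kind="ratio"))
        assert np.allclose(res.estimate, 1.0)

    def test_ratio_zero_reference_flagged_nan(self, fitted_pair, sim_data):
        t = np.array([0.0, 36.0])
        a = std_cif(fitted_pair, sim_data, AT1, t, "c1", check_quadrature=False)
        b = std_cif(fitted_pair, sim_data, AT0, t, "c1", check_quadrature=False)
        res = contrast([b, a], ContrastSpec(kind="ratio", ref=0))
        assert np.isnan(res.estimate[0])  # 0/0 at t=0
        assert np.isfinite(res.estimate[1])

    def test_lincom_additivity(self, fitted_pair, sim_data):
        r1 = std_rmft(fitted_pair, sim_data, AT0, 60.0, "c1")
        r2 = std_rmft(fitted_pair, sim_data, AT0, 60.0, "c2")
        total = contrast(
            [r1, r2], ContrastSpec(kind="lincom", coefficients=(1.0, 1.0))
        )
        assert total.estimate[0] == pytest.approx(
            r1.estimate[0] + r2.estimate[0], abs=1e-10
        )
        assert total.se[0] > 0

    def test_mismatched_grids_rejected(self, fitted_pair, sim_data):
        a = std_cif(
            fitted_pair, sim_data, AT1, np.array([10.0]), "c1", check_quadrature=False
        )
        b = std_cif(
            fitted_pair, sim_data, AT0, np.array([20.0]), "c1", check_quadrature=False
        )
        with pytest.raises(ValueError, match="mismatched"):
            contrast([a, b], ContrastSpec(kind="difference"))

    def test_different_models_rejected(self, fitted_pair, sim_data):
        t = np.array([36.0])
        a = std_cif(fitted_pair, sim_data, AT1, t, "c1", check_quadrature=False)
        b = std_failure(fitted_pair["c1"], sim_data, AT0, t)
        with pytest.raises(ValueError, match="same fitted models"):
            contrast([a, b], ContrastSpec(kind="difference"))

    def test_treatment_effect_detected(self, fitted_pair, sim_data):
        t = np.array([36.0, 60.0])
        a = std_cif(fitted_pair, sim_data, AT0, t, "c1", check_quadrature=False)
        b = std_cif(fitted_pair, sim_data, AT1, t, "c1", check_quadrature=False)
        res = contrast([a, b], ContrastSpec(kind="difference", ref=0))
        # truth: protective effect on cause 1 (log HR -0.5)
        assert np.all(res.estimate < 0)


@pytest.fixture(scope="module")
def cloned_setup(sim_data):
    data = sim_data.with_cloned_treatment(["x_c", "x_o"])
    spec_c = FPMSpec(df=2, covariates=("x_c", "age1", "age2", "comorb"))
    spec_o = FPMSpec(df=2, covariates=("x_o", "age1", "age2", "comorb"))
    mc = fit(data, spec_c, event_cause=1)
    mo = fit(data, spec_o, event_cause=2)
    return data, CauseModelSet((mc, mo), ("c1", "c2"))


class TestSeparable:
    def test_collapsed_clones_reproduce_total_effect(
        self, cloned_setup, fitted_pair, sim_data
    ):
        data, models = cloned_setup
        t = np.array([12.0, 36.0, 60.0])
        res = separable(
            models, data, "x_c", "x_o", [(1.0, 1.0)], t, cause="c1"
        )
        total = std_cif(
            fitted_pair, sim_data, AT1, t, "c1", check_quadrature=False
        )
        assert np.allclose(
            res.curves[(1.0, 1.0)].estimate, total.estimate, atol=1e-12
        )

    def test_direct_and_indirect_contrasts(self, cloned_setup):
        data, models = cloned_setup
        t = np.array([36.0])
        res = separable(
            models,
            data,
            "x_c",
            "x_o",
            [(0.0, 0.0), (1.0, 0.0), (1.0, 1.0)],
            t,
            cause="c1",
        )
        assert 0.0 in res.direct  # CIF(1,0) - CIF(0,0)
        assert 1.0 in res.indirect  # CIF(1,1) - CIF(1,0)
        d = res.direct[0.0].estimate[0]
        i = res.indirect[1.0].estimate[0]
        total = (
            res.curves[(1.0, 1.0)].estimate[0] - res.curves[(0.0, 0.0)].estimate[0]
        )
        assert d + i == pytest.approx(total, abs=1e-12)

    def test_unequal_clone_rejected(self, cloned_setup):
        data, models = cloned_setup
        cov = data.covariates.copy()
        cov.loc[0, "x_o"] = 1.0 - cov.loc[0, "x_o"]
        tampered = SurvivalDataset(data.time, data.cause, cov, data.treatment)
        with pytest.raises(ValueError, match="exact copy"):
            separable(
                models, tampered, "x_c", "x_o", [(1.0, 1.0)], np.array([36.0]),
                cause="c1",
            )

    def test_model_clone_structure_enforced(self, cloned_setup, fitted_pair):
        data, _ = cloned_setup
        with pytest.raises(ValueError):
            separable(
                fitted_pair, data, "x_c", "x_o", [(1.0, 1.0)], np.array([36.0]),
                cause="c1",
            )


class TestUserContrast:
    def test_reproduces_builtin_difference(self, fitted_pair, sim_data):
        from standcomp import user_contrast

        t = np.array([12.0, 36.0, 60.0])
        a = std_cif(fitted_pair, sim_data, AT0, t, "c1", check_quadrature=False)
        b = std_cif(fitted_pair, sim_data, AT1, t, "c1", check_quadrature=False)
        builtin = contrast([a, b], ContrastSpec(kind="difference", ref=0))
        custom = user_contrast([a, b], lambda f0, f1: f1 - f0)
        assert np.allclose(custom.estimate, builtin.estimate, atol=1e-14)
        assert np.allclose(custom.se, builtin.se, rtol=1e-10)

    def test_nonlinear_functional(self, fitted_pair, sim_data):
        from standcomp import user_contrast

        t = np.array([36.0])
        a = std_cif(fitted_pair, sim_data, AT0, t, "c1", check_quadrature=False)
        b = std_cif(fitted_pair, sim_data, AT1, t, "c1", check_quadrature=False)
        nnt = user_contrast([a, b], lambda f0, f1: 1.0 / (f0 - f1), label="NNT")
        assert nnt.estimate[0] == pytest.approx(
            1.0 / (a.estimate[0] - b.estimate[0])
        )
        assert nnt.se[0] > 0


class TestCurveOutputs:
    def test_tidy_frame(self, fitted_pair, sim_data):
        curve = std_cif(
            fitted_pair, sim_data, AT1, np.array([0.0, 36.0]), "c1",
            check_quadrature=False,
        )
        f = curve.to_frame()
        assert list(f.columns) == [
            "time", "at", "kind", "cause", "estimate", "se", "ci_low", "ci_high",
        ]
        assert (f["kind"] == "cif").all()

    def test_at_time_lookup(self, fitted_pair, sim_data):
        curve = std_cif(
            fitted_pair, sim_data, AT1, default_timevar(), "c1",
            check_quadrature=False,
        )
        row = curve.at_time(36.0)
        assert row["time"] == 36.0
        with pytest.raises(ValueError, match="not on the prediction grid"):
            curve.at_time(36.2)

    def test_loglog_ci_transform(self, fitted_pair, sim_data):
        curve = std_failure(
            fitted_pair["c1"], sim_data, AT1, np.array([0.0, 36.0]),
            transform="loglog",
        )
        assert 0.0 <= curve.ci_low[1] <= curve.estimate[1] <= curve.ci_high[1] <= 1.0
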