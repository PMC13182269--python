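import numpy as np
import pytest
from scipy import stats

import dynrisk.joint as J
from dynrisk.datasets import ScenarioConfig
from dynrisk.joint import (
    JointModelSpec,
    conditional_survival,
    fit_joint_model,
    fit_null_weibull,
    joint_loglik,
    wald_test,
    weibull_surv_loglik,
)
from dynrisk.lmm import lmm_loglik
from dynrisk.simulate import simulate_dataset, simulate_joint_law


def random_theta(rng):
    a = rng.uniform(0.05, 0.6)
    c = rng.uniform(0.01, 0.2)
    rho = rng.uniform(-0.5, 0.5)
    D = np.array([[a, rho * np.sqrt(a * c)], [rho * np.sqrt(a * c), c]])
    return {
        "beta": rng.normal([5.0, 0.0], [1.0, 0.1]),
        "D": D,
        "sigma2": rng.uniform(0.05, 1.0),
        "log_kappa": rng.uniform(-0.5, 1.0),
        "log_lambda": rng.uniform(-8, -3),
        "alpha": 0.0,
    }


class TestSeparability:
    def test_alpha_zero_separates_on_20_random_instances(self):
        rng = np.random.default_rng(0)
        for k in range(20):
            cfg = ScenarioConfig(
                n_per_group=int(rng.integers(3, 8)),
                n_visits=int(rng.integers(2, 6)),
                slope_coef=float(rng.uniform(0, 0.1)),
                resid_sd=float(rng.uniform(0.3, 1.5)),
            )
            data = simulate_dataset(cfg, seed=k)
            theta = random_theta(rng)
            prep = J._Prepared(data)
            expected = lmm_loglik(theta, data) + weibull_surv_loglik(
                theta["log_kappa"], theta["log_lambda"], prep.T, prep.delta
            )
            assert joint_loglik(theta, data) == pytest.approx(expected, abs=1e-6)

    def test_exponential_baseline_closed_form(self):
        # kappa = 1, alpha = 0: survival part is a censored exponential
        data = simulate_dataset(ScenarioConfig(n_per_group=10), seed=3)
        theta = {"beta": np.array([6.0, 0.0]), "D": np.diag([0.01, 0.001]),
                 "sigma2": 0.25, "log_kappa": 0.0, "log_lambda": np.log(0.02),
                 "alpha": 0.0}
        prep = J._Prepared(data)
        lam = 0.02
        expected_surv = np.sum(prep.delta * np.log(lam) - lam * prep.T)
        got = joint_loglik(theta, data) - lmm_loglik(theta, data)
        assert got == pytest.approx(expected_surv, abs=1e-6)


class TestMonteCarloOracle:
    def test_matches_mc_integration(self):
        cfg = ScenarioConfig(n_per_group=2, n_visits=2, slope_coef=0.1)
        data = simulate_dataset(cfg, seed=7)
        theta = {"beta": np.array([6.0, 0.05]), "D": np.array([[0.04, 0.002],
                 [0.002, 0.01]]), "sigma2": 0.25, "log_kappa": np.log(1.5),
                 "log_lambda": np.log(1e-3), "alpha": 0.5}
        got = joint_loglik(theta, data)
        rng = np.random.default_rng(123)
        prep = J._Prepared(data)
        L = np.linalg.cholesky(theta["D"])
        total, total_var = 0.0, 0.0
        ndraw = 100_000
        for i in range(len(prep)):
            t = prep.t[i][prep.mask[i]]
            y = prep.y[i][prep.mask[i]]
            T, d = prep.T[i], prep.delta[i]
            b = rng.standard_normal((ndraw, 2)) @ L.T
            m = theta["beta"][0] + b[:, :1] + (theta["beta"][1] + b[:, 1:]) * t
            ll_long = stats.norm.logpdf(y, m, np.sqrt(theta["sigma2"])).sum(axis=1)
            kappa = np.exp(theta["log_kappa"])
            lam = np.exp(theta["log_lambda"])
            grid = np.linspace(1e-8, T, 300)
            mu = theta["beta"][0] + b[:, :1] + (theta["beta"][1] + b[:, 1:]) * grid
            haz = kappa * lam * grid ** (kappa - 1) * np.exp(theta["alpha"] * mu)
            cum = np.trapezoid(haz, grid, axis=1)
            logh = (np.log(kappa * lam) + (kappa - 1) * np.log(T)
                    + theta["alpha"] * (theta["beta"][0] + b[:, 0]
                                        + (theta["beta"][1] + b[:, 1]) * T))
            w = np.exp(ll_long + d * logh - cum)
            total += np.log(w.mean())
            total_var += w.var(ddof=1) / (ndraw * w.mean() ** 2)  # delta method
        mc_se = np.sqrt(total_var)
        assert got == pytest.approx(total, abs=max(3 * mc_se, 5e-3))


class TestQuadrature:
    def test_gh_convergence_9_to_15(self, small_scenario_data):
        theta = {"beta": np.array([6.0, 0.05]), "D": np.diag([0.01, 0.002]),
                 "sigma2": 0.25, "log_kappa": np.log(1.2),
                 "log_lambda": np.log(5e-3), "alpha": 0.3}
        ll9 = joint_loglik(theta, small_scenario_data, JointModelSpec(n_gh=9))
        ll15 = joint_loglik(theta, small_scenario_data, JointModelSpec(n_gh=15))
        assert abs(ll9 - ll15) < 1e-4

    def test_min_nodes_enforced(self):
        with pytest.raises(ValueError):
            JointModelSpec(n_gh=3)


class TestNullWeibull:
    def test_recovers_shape_and_rate(self):
        rng = np.random.default_rng(5)
        kappa, lam = 1.7, 0.01
        T = (rng.exponential(1, 2000) / lam) ** (1 / kappa)
        cens = np.minimum(T, 25.0)
        delta = (T <= 25.0).astype(int)
        lk, ll = fit_null_weibull(cens, delta)
        assert np.exp(lk) == pytest.approx(kappa, rel=0.1)
        assert np.exp(ll) == pytest.approx(lam, rel=0.3)

    def test_no_events_refused(self):
        with pytest.raises(ValueError):
            fit_null_weibull(np.ones(10), np.zeros(10))


class TestFitJointModel:
    def test_parameter_recovery_within_3se(self, joint_theta):
        theta = dict(joint_theta)  # alpha = 0.8
        data = simulate_joint_law(theta, 500, np.linspace(0, 15, 10), 20.0, seed=11)
        fit = fit_joint_model(data)
        assert fit.converged
        true_packed = J.pack_theta(theta)
        for name, tv, ev in zip(J.PACKED_NAMES, true_packed, fit.packed):
            se = fit.se[name]
            assert abs(ev - tv) < 3 * se, f"{name}: {ev} vs {tv} (se {se})"

    def test_loglik_improves_over_init(self, small_scenario_data):
        from dynrisk.lmm import fit_lmm

        lfit = fit_lmm(small_scenario_data)
        prep = J._Prepared(small_scenario_data)
        lk, ll = fit_null_weibull(prep.T, prep.delta)
        init_ll = lfit.loglik + weibull_surv_loglik(lk, ll, prep.T, prep.delta)
        fit = fit_joint_model(small_scenario_data)
        assert fit.loglik >= init_ll - 1e-6

    def test_no_events_refused(self):
        data = simulate_dataset(ScenarioConfig(n_per_group=5), seed=0)
        only_controls = data.subjects["group"] == "control"
        from dynrisk.datasets import LongitudinalDataset

        sub = LongitudinalDataset(
            data.measurements[data.measurements["subject_id"].isin(
                data.subjects.loc[only_controls, "subject_id"])],
            data.subjects[only_controls],
            data.features,
        )
        with pytest.raises(ValueError, match="no observed events"):
            fit_joint_model(sub)

    def test_serializable_on_hard_data(self, fast_spec):
        # near-zero signal, huge noise: result may not converge but must exist
        cfg = ScenarioConfig(n_per_group=5, n_visits=3, slope_coef=0.0, resid_sd=1.5)
        data = simulate_dataset(cfg, seed=13)
        fit = fit_joint_model(data, spec=fast_spec, max_iter=20)
        assert isinstance(fit.loglik, float)
        assert isinstance(fit.converged, bool)
        d = {"alpha": fit.alpha, "loglik": fit.loglik, "converged": fit.converged}
        import json

        json.dumps(d)


class TestWaldTest:
    def test_zero_alpha_gives_p_one(self, jm_fit_small):
        fit = J.JointModelFit(
            theta=dict(jm_fit_small.theta, alpha=0.0), se={"alpha": 0.5},
            loglik=0.0, converged=True, n_subjects=10, n_events=5,
        )
        z, p = wald_test(fit)
        assert z == 0.0 and p == 1.0

    def test_z_1959964_gives_p_005(self):
        fit = J.JointModelFit(
            theta={"alpha": 1.959964, "beta": np.zeros(2), "D": np.eye(2),
                   "sigma2": 1.0, "log_kappa": 0.0, "log_lambda": 0.0},
            se={"alpha": 1.0}, loglik=0.0, converged=True,
            n_subjects=10, n_events=5,
        )
        _, p = wald_test(fit)
        assert p == pytest.approx(0.05, abs=1e-6)

    def test_unconverged_flagged(self):
        fit = J.JointModelFit(
            theta={"alpha": 1.0, "beta": np.zeros(2), "D": np.eye(2),
                   "sigma2": 1.0, "log_kappa": 0.0, "log_lambda": 0.0},
            se={"alpha": 0.1}, loglik=0.0, converged=False,
            n_subjects=10, n_events=5,
        )
        z, p = wald_test(fit)
        assert np.isnan(z) and np.isnan(p)


class TestConditionalSurvival:
    def test_t_equals_s_is_one(self, jm_fit_small):
        assert conditional_survival(jm_fit_small, (0.0, 0.0), 5.0, 5.0) == 1.0

    def test_t_less_than_s_rejected(self, jm_fit_small):
        with pytest.raises(ValueError):
            conditional_survival(jm_fit_small, (0.0, 0.0), 5.0, 4.0)

    def test_exponential_closed_form(self):
        theta = {"beta": np.zeros(2), "D": np.eye(2), "sigma2": 1.0,
                 "log_kappa": 0.0, "log_lambda": np.log(0.05), "alpha": 0.0}
        fit = J.JointModelFit(theta=theta, se={}, loglik=0.0, converged=True,
                              n_subjects=1, n_events=1)
        got = conditional_survival(fit, (0.3, -0.2), 2.0, 7.0)
        assert got == pytest.approx(np.exp(-0.05 * 5.0), abs=1e-10)

    def test_matches_dense_trapezoid(self, jm_fit_small):
        b = (0.05, -0.01)
        s, t = 3.0, 18.0
        th = jm_fit_small.theta
        kappa = np.exp(th["log_kappa"])
        lam = np.exp(th["log_lambda"])
        grid = np.linspace(s, t, 200_001)
        m = th["beta"][0] + b[0] + (th["beta"][1] + b[1]) * grid
        haz = kappa * lam * grid ** (kappa - 1) * np.exp(th["alpha"] * m)
        expected = np.exp(-np.trapezoid(haz, grid))
        assert conditional_survival(jm_fit_small, b, s, t, n_gl=80) == pytest.approx(
            expected, abs=1e-6
        )

    def test_non_increasing_in_t(self, jm_fit_small):
        vals = [conditional_survival(jm_fit_small, (0.1, 0.02), 2.0, t)
                for t in np.linspace(2, 20, 12)]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))
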