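"""Bilinear DCM simulation, linearized state space and Kalman inversion."""

import numpy as np
import pytest
from scipy.linalg import expm as scipy_expm, solve_discrete_lyapunov

from restdcm import _fast, dcm, models, synth
from restdcm.config import FitConfig, GroundTruth, ScanConfig
from conftest import brute_force_loglik, random_state_space


def _params(b=None, **kw):
    return dcm.DCMParams(a_forward=0.12, a_backward=0.12, b=b or {}, **kw)


class TestEffectiveMatrix:
    def test_null_model_keeps_average_coupling(self):
        spec = models.make_spec("null")
        p = _params()
        for run in (1, 2, 3, 4):
            np.testing.assert_allclose(
                dcm.effective_matrix(p, spec, run), p.a_matrix)

    def test_adaptation_weights_toggle_change(self):
        spec = models.make_spec("adaptation", ("forward",))
        p = _params(b={("adaptation", "forward"): 0.1})
        a1 = dcm.effective_matrix(p, spec, 1)
        a2 = dcm.effective_matrix(p, spec, 2)
        np.testing.assert_allclose(a1, p.a_matrix)
        assert a2[1, 0] - a1[1, 0] == pytest.approx(0.1)

    def test_consolidation_run2_weight_doubles_parameter(self):
        spec = models.make_spec("consolidation", ("forward",))
        p = _params(b={("consolidation", "forward"): 0.1,
                       ("adaptation", "forward"): 0.0})
        a2 = dcm.effective_matrix(p, spec, 2)
        assert a2[1, 0] - p.a_matrix[1, 0] == pytest.approx(0.2)

    def test_unstable_matrix_names_run(self):
        spec = models.make_spec("adaptation", ("forward", "backward"))
        p = _params(b={("adaptation", "forward"): 0.5,
                       ("adaptation", "backward"): 0.5})
        with pytest.raises(dcm.StabilityError, match="run 2"):
            dcm.effective_matrix(p, spec, 2)

    def test_invalid_run_rejected(self):
        with pytest.raises(ValueError):
            dcm.effective_matrix(_params(), models.make_spec("null"), 5)


class TestSimulate:
    def test_zero_noise_stays_at_fixed_point(self, scan):
        p = _params(neural_noise_sd=0.0)
        out = dcm.simulate(p, models.make_spec("null"), scan, seed=0,
                           n_volumes=40)
        np.testing.assert_allclose(
            out[["hippocampus", "striatum"]].to_numpy(), 0.0, atol=1e-12)

    def test_shapes_and_run_labels(self, scan):
        out = dcm.simulate(_params(neural_noise_sd=0.02),
                           models.make_spec("null"), scan, seed=1,
                           n_volumes=30)
        assert sorted(out["run"].unique()) == [1, 2, 3, 4]
        assert (out.groupby("run").size() == 30).all()

    def test_impulse_response_peaks_then_undershoots(self):
        # a brief neuronal impulse produces a BOLD response peaking
        # 4-8 s later, followed by a post-stimulus undershoot
        dt = 0.05
        n = int(40 / dt)
        u = np.zeros((n, 2))
        u[: int(1.0 / dt), 0] = 1.0
        h = dcm.HemoParams()
        y = _fast.simulate_bold_run(
            np.array([[-0.5, 0.0], [0.0, -0.5]]),
            np.zeros((n, 2)), 0.0, 0.0, u, dt, 0,
            np.arange(n, dtype=np.int64), h.kappa, h.gamma, h.tau,
            h.alpha, h.e0, h.v0, h.k1, h.k2, h.k3)
        peak_t = np.argmax(y[:, 0]) * dt
        assert 4.0 <= peak_t <= 8.0
        assert y[int(12 / dt):, 0].min() < 0  # undershoot

    def test_integration_self_convergence(self):
        # halving the step changes the sampled output by well under 1% RMS
        h = dcm.HemoParams()
        a = np.array([[-0.5, 0.12], [0.12, -0.5]])
        outs = []
        for dt in (0.1, 0.05):
            n = int(60 / dt)
            u = np.zeros((n, 2))
            u[: int(1.0 / dt), :] = 0.5
            sample = (np.arange(0, 60, 2.0) / dt).astype(np.int64)
            y = _fast.simulate_bold_run(
                a, np.zeros((n, 2)), 0.0, 0.0, u, dt, 0, sample,
                h.kappa, h.gamma, h.tau, h.alpha, h.e0, h.v0,
                h.k1, h.k2, h.k3)
            outs.append(y)
        rms_diff = np.sqrt(np.mean((outs[0] - outs[1]) ** 2))
        rms = np.sqrt(np.mean(outs[1] ** 2))
        assert rms_diff < 0.01 * rms

    def test_stationarity_after_burn_in(self, null_truth, scan):
        # fixed coupling: variance of the first and second half of a run
        # should agree within 3 SE over replicates
        rng = np.random.default_rng(8)
        d1, d2 = [], []
        for rep in range(24):
            out = synth.gen_rest_bold(null_truth, scan, rng, n_volumes=276)
            y = out[out["run"] == 1]["hippocampus"].to_numpy()
            d1.append(np.var(y[:138]))
            d2.append(np.var(y[138:]))
        diff = np.array(d1) - np.array(d2)
        se = diff.std(ddof=1) / np.sqrt(len(diff))
        assert abs(diff.mean()) < 3 * se


class TestLinearizedHemo:
    def test_small_impulse_matches_nonlinear_within_5pct(self):
        # drive both the nonlinear balloon cascade and its linearization
        # with the identical small neuronal trajectory (impulse through a
        # leaky integrator); outputs should agree within 5% RMS
        hemo = dcm.HemoParams()
        hm, g, c = dcm.hemo_linear_approx(hemo)
        dt = 0.01
        n = int(40 / dt)
        amp = 0.01
        u = np.zeros((n, 2))
        u[: int(1.0 / dt), 0] = amp
        a_eff = np.array([[-0.5, 0.0], [0.0, -0.5]])
        y_nl = _fast.simulate_bold_run(
            a_eff, np.zeros((n, 2)), 0.0, 0.0, u, dt, 0,
            np.arange(n, dtype=np.int64), hemo.kappa, hemo.gamma,
            hemo.tau, hemo.alpha, hemo.e0, hemo.v0, hemo.k1, hemo.k2,
            hemo.k3)
        # same neuronal path through the linear hemodynamic operator,
        # integrated with the same Heun scheme as the nonlinear cascade
        f5 = np.zeros((5, 5))
        f5[0, 0] = -0.5
        f5[1:, 1:] = hm
        f5[1, 0] = g[0]
        x = np.zeros(5)
        y_lin = np.zeros(n)
        for i in range(n):
            drive = np.array([u[i, 0], 0.0, 0.0, 0.0, 0.0])
            d1 = f5 @ x + drive
            d2 = f5 @ (x + dt * d1) + drive
            x = x + 0.5 * dt * (d1 + d2)
            y_lin[i] = c @ x[1:]
        rms = np.sqrt(np.mean((y_lin - y_nl[:, 0]) ** 2))
        scale = np.sqrt(np.mean(y_nl[:, 0] ** 2))
        assert rms < 0.05 * scale

    def test_dc_gain_positive_and_finite(self):
        hm, g, c = dcm.hemo_linear_approx(dcm.HemoParams())
        gain = -c @ np.linalg.solve(hm, g)
        assert np.isfinite(gain) and gain > 0

    def test_linear_operator_scaling_equivariance(self):
        hm, g, c = dcm.hemo_linear_approx(dcm.HemoParams())
        dt, n = 0.02, 1000
        def respond(amp):
            x = np.zeros(4)
            out = np.zeros(n)
            for i in range(n):
                u = amp if i < 50 else 0.0
                x = x + dt * (hm @ x + g * u)
                out[i] = c @ x
            return out
        np.testing.assert_allclose(respond(2.0), 2 * respond(1.0),
                                   rtol=1e-10)


class TestKalmanLoglik:
    def test_matches_brute_force_gaussian_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            y, ad, qd, h, r, p0 = random_state_space(rng)
            ll_b = brute_force_loglik(y, ad, qd, h, r, p0)
            ll_k = _fast.kalman_loglik(np.ascontiguousarray(y), ad, qd, h,
                                       r, np.zeros(ad.shape[0]), p0)
            assert ll_k == pytest.approx(ll_b, abs=1e-8)

    def test_scalar_state_five_samples(self):
        rng = np.random.default_rng(3)
        y, ad, qd, h, r, p0 = random_state_space(rng, n=1, p=1, T=5)
        ll_b = brute_force_loglik(y, ad, qd, h, r, p0)
        ss = {"Ad": ad, "Qd": qd, "H": h, "R": r, "x0": np.zeros(1),
              "P0": p0}
        assert dcm.loglik_kalman(y, ss) == pytest.approx(ll_b, abs=1e-8)

    def test_degenerate_state_reduces_to_iid_normal(self, scan):
        # zero process noise and zero initial state variance: the series
        # is pure observation noise, so the log-likelihood is the iid
        # normal log density
        ss = dcm.build_state_space(
            np.array([[-0.5, 0.1], [0.1, -0.5]]), sigma_z=0.0,
            sigma_e=np.array([0.3, 0.4]), tr=scan.tr_s)
        rng = np.random.default_rng(5)
        y = rng.standard_normal((20, 2))
        ll = dcm.loglik_kalman(y, ss)
        expect = sum(
            -0.5 * (np.log(2 * np.pi * sd ** 2) + (y[:, i] / sd) ** 2).sum()
            for i, sd in enumerate((0.3, 0.4)))
        assert ll == pytest.approx(expect, abs=1e-8)

    def test_doubling_obs_noise_on_zero_data(self, scan):
        # with y = 0 the innovation quadratic form scales as 1/sigma^2:
        # per-sample NLL increases by log(2) per dimension asymptotically
        # as the noise dominates
        a = np.array([[-0.5, 0.0], [0.0, -0.5]])
        T = 500
        y = np.zeros((T, 2))
        lls = []
        for sd in (50.0, 100.0):  # obs noise >> state-driven signal
            ss = dcm.build_state_space(a, 0.05, np.array([sd, sd]),
                                       scan.tr_s)
            lls.append(dcm.loglik_kalman(y, ss))
        per_sample = (lls[0] - lls[1]) / T
        assert per_sample == pytest.approx(2 * np.log(2.0), rel=1e-3)

    def test_discretization_against_quadrature(self):
        # Van Loan Qd equals the numerically integrated innovation
        # covariance, and Ad the scipy matrix exponential
        rng = np.random.default_rng(2)
        f = rng.normal(size=(4, 4))
        f -= 2.0 * np.eye(4)
        qc = np.zeros((4, 4))
        qc[0, 0] = qc[1, 1] = 0.3
        dt = 2.176
        ad, qd = _fast.discretize(f, qc, dt)
        np.testing.assert_allclose(ad, scipy_expm(f * dt), atol=1e-10)
        ts = np.linspace(0, dt, 4001)
        acc = np.zeros((4, 4))
        for i in range(len(ts) - 1):
            mid = 0.5 * (ts[i] + ts[i + 1])
            e = scipy_expm(f * mid)
            acc += e @ qc @ e.T * (ts[i + 1] - ts[i])
        np.testing.assert_allclose(qd, acc, atol=1e-6)

    def test_stationary_cov_matches_scipy(self):
        rng = np.random.default_rng(4)
        y, ad, qd, *_ = random_state_space(rng, n=3, p=1, T=2)
        p_doubling = _fast.stationary_cov(ad, qd)
        p_scipy = solve_discrete_lyapunov(ad, qd)
        np.testing.assert_allclose(p_doubling, p_scipy, atol=1e-9)


@pytest.fixture(scope="module")
def subject(truth, scan):
    rest = synth.gen_rest_bold(truth, scan, 2024)
    return dcm.prepare_rest_series(rest, scan)


class TestFit:
    def test_consolidation_fit_recovers_parameter_signs(self, subject,
                                                        scan):
        spec = models.make_spec("consolidation", ("forward", "backward"))
        fit = dcm.fit(subject, spec, scan, FitConfig(), seed=0)
        assert fit.converged
        assert np.isfinite(fit.log_evidence)
        for conn in ("forward", "backward"):
            assert fit.map_params.b[("consolidation", conn)] > 0

    def test_average_coupling_recovered_within_posterior_sd(self, subject,
                                                            scan, truth):
        spec = models.make_spec("consolidation", ("forward", "backward"))
        fit = dcm.fit(subject, spec, scan, FitConfig(), seed=0)
        for name, true_val in (("a_forward", truth.a_forward),
                               ("a_backward", truth.a_backward)):
            est = fit.param(name)
            sd = fit.posterior_sd[fit.param_names.index(name)]
            assert abs(est - true_val) < 3 * sd

    def test_nested_model_has_higher_maximized_posterior(self, subject,
                                                         scan):
        null_fit = dcm.fit(subject, models.make_spec("null"), scan,
                           FitConfig(), seed=0)
        cons_fit = dcm.fit(subject,
                           models.make_spec("consolidation",
                                            ("forward", "backward")),
                           scan, FitConfig(), seed=0)
        # the larger model nests the null, so its maximized joint
        # (likelihood + prior quadratic) cannot be lower
        assert cons_fit.loglik + cons_fit.log_prior >= \
            null_fit.loglik + null_fit.log_prior - 1e-3

    def test_label_symmetry(self, scan, truth):
        # swapping the two regions in data and model leaves the evidence
        # unchanged
        rest = synth.gen_rest_bold(truth, scan, 77, n_volumes=120)
        ys = dcm.prepare_rest_series(rest, scan)
        ys_swapped = ys[:, :, ::-1].copy()
        fwd = models.make_spec("consolidation", ("forward",))
        bwd = models.make_spec("consolidation", ("backward",))
        f1 = dcm.fit(ys, fwd, scan, FitConfig(n_starts=1), seed=0)
        f2 = dcm.fit(ys_swapped, bwd, scan, FitConfig(n_starts=1), seed=0)
        assert f2.log_evidence == pytest.approx(f1.log_evidence, abs=1e-4)


class TestCouplingTimecourse:
    def _fake_fit(self, b):
        spec = models.make_spec("consolidation", ("forward",))
        params = dcm.DCMParams(b=b)
        return dcm.DCMFit(
            spec=spec, theta=np.zeros(1), param_names=("x",),
            map_params=params, loglik=0.0, log_prior=0.0,
            log_evidence=0.0, posterior_sd=np.zeros(1), converged=True,
            hessian_ok=True, n_starts_used=1)

    def test_consolidation_arithmetic(self):
        fit = self._fake_fit({("adaptation", "forward"): 0.2,
                              ("consolidation", "forward"): 0.4})
        tc = dcm.coupling_timecourse(fit)
        np.testing.assert_allclose(tc["forward"], [0.0, 1.0, 0.4, 0.6])

    def test_null_model_is_flat(self):
        spec = models.make_spec("null")
        fit = dcm.DCMFit(
            spec=spec, theta=np.zeros(1), param_names=("x",),
            map_params=dcm.DCMParams(), loglik=0.0, log_prior=0.0,
            log_evidence=0.0, posterior_sd=np.zeros(1), converged=True,
            hessian_ok=True, n_starts_used=1)
        tc = dcm.coupling_timecourse(fit)
        np.testing.assert_allclose(tc["forward"], np.zeros(4))
        np.testing.assert_allclose(tc["backward"], np.zeros(4))

    def test_profile_shape_for_positive_parameters(self):
        # consolidation: big change after learning (run 2), preserved at
        # a lower level on day 2
        for b_a, b_c in ((0.05, 0.1), (0.2, 0.4), (0.01, 0.3)):
            fit = self._fake_fit({("adaptation", "forward"): b_a,
                                  ("consolidation", "forward"): b_c})
            tc = dcm.coupling_timecourse(fit)["forward"]
            assert tc[0] == 0.0
            assert tc[1] == max(tc)
            assert 0 < tc[2] <= tc[3] < tc[1]
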