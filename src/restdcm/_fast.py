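"""Numba kernels for the state-space likelihood and the balloon simulator.

These are the hot paths of the package: they run inside optimizer loops
(thousands of likelihood evaluations per model fit) and inside Monte-Carlo
calibration loops (tens of thousands of simulated runs), so they are
compiled with numba.  Everything here is plain numerics on small dense
matrices; the public API lives in :mod:`restdcm.dcm`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_LOG2PI = float(np.log(2.0 * np.pi))


@njit(cache=True)
def expm(a):
    """Matrix exponential by scaling-and-squaring with a Taylor core.

    The argument is scaled until its 1-norm is below 0.5, the exponential
    of the scaled matrix is computed by a degree-18 Taylor polynomial
    (truncation error ~1e-23 at norm 0.5), and the result squared back.
    Adequate for the small, moderately normed generators used here.
    """
    n = a.shape[0]
    norm = 0.0
    for j in range(n):
        s = 0.0
        for i in range(n):
            s += abs(a[i, j])
        if s > norm:
            norm = s
    n_sq = 0
    if norm > 0.5:
        n_sq = int(np.ceil(np.log2(norm / 0.5)))
    b = a / (2.0 ** n_sq)
    out = np.eye(n)
    term = np.eye(n)
    for k in range(1, 19):
        term = (term @ b) / k
        out = out + term
    for _ in range(n_sq):
        out = out @ out
    return out


@njit(cache=True)
def discretize(f, qc, dt):
    """Exact discretization of dx = F x dt + dW, Cov(dW) = Qc dt.

    Van Loan's method: Ad = expm(F dt) and
    Qd = integral_0^dt expm(F s) Qc expm(F' s) ds, read off the exponential
    of the doubled block matrix [[-F, Qc], [0, F']] dt.
    """
    n = f.shape[0]
    m = np.zeros((2 * n, 2 * n))
    m[:n, :n] = -f * dt
    m[:n, n:] = qc * dt
    m[n:, n:] = f.T * dt
    e = expm(m)
    ad = np.ascontiguousarray(e[n:, n:].T)
    qd = ad @ np.ascontiguousarray(e[:n, n:])
    # enforce exact symmetry against roundoff
    qd = 0.5 * (qd + qd.T)
    return ad, qd


@njit(cache=True)
def stationary_cov(ad, qd, tol=1e-12, max_doublings=60):
    """Stationary covariance of x+ = Ad x + w, Cov(w) = Qd, by doubling.

    Requires spectral radius(Ad) < 1.  Each iteration doubles the horizon:
    P_{k+1} = P_k + A_k P_k A_k', A_{k+1} = A_k A_k.
    """
    p = qd.copy()
    a = ad.copy()
    for _ in range(max_doublings):
        inc = a @ p @ a.T
        p = p + inc
        a = a @ a
        if np.max(np.abs(inc)) < tol * max(1e-30, np.max(np.abs(p))):
            break
    return 0.5 * (p + p.T)


@njit(cache=True)
def kalman_loglik(y, ad, qd, h, r_diag, x0, p0):
    """Gaussian marginal log-likelihood by the prediction-error
    decomposition (standard covariance Kalman filter).

    ``y`` is (T, p) with p observed channels, ``h`` the (p, n) observation
    matrix, ``r_diag`` the observation noise variances.  The initial state
    is x0 ~ N(x0, p0) *before* the first transition is applied, i.e. the
    first observation is y_0 = H x_0 + e.
    """
    t_len, p_dim = y.shape
    x = x0.copy()
    p = p0.copy()
    h_t = np.ascontiguousarray(h.T)
    ad_t = np.ascontiguousarray(ad.T)
    ll = 0.0
    n_dim = p0.shape[0]
    # once the Riccati recursion has converged, gain and innovation
    # covariance are frozen and the mean recursion x+ = M x + G y_t is
    # carried with hand-rolled loops (BLAS call overhead dominates at
    # these dimensions)
    steady = False
    w = p @ h_t
    s = h @ w
    s_inv = np.empty((p_dim, p_dim))
    k = np.empty((n_dim, p_dim))
    m_mat = np.empty((n_dim, n_dim))
    g_mat = np.empty((n_dim, p_dim))
    innov = np.empty(p_dim)
    x_new = np.empty(n_dim)
    det = 1.0
    log_norm = 0.0
    for t in range(t_len):
        if steady:
            for i in range(p_dim):
                acc = y[t, i]
                for j in range(n_dim):
                    acc -= h[i, j] * x[j]
                innov[i] = acc
            quad = 0.0
            for i in range(p_dim):
                for j in range(p_dim):
                    quad += innov[i] * s_inv[i, j] * innov[j]
            ll += log_norm - 0.5 * quad
            for i in range(n_dim):
                acc = 0.0
                for j in range(n_dim):
                    acc += m_mat[i, j] * x[j]
                for j in range(p_dim):
                    acc += g_mat[i, j] * y[t, j]
                x_new[i] = acc
            for i in range(n_dim):
                x[i] = x_new[i]
            continue
        w = p @ h_t                    # (n, p) cross covariance
        s = h @ w                      # (p, p) innovation covariance
        for i in range(p_dim):
            s[i, i] += r_diag[i]
        innov = y[t] - h @ x
        s_inv = np.empty((p_dim, p_dim))
        if p_dim == 1:
            det = s[0, 0]
        elif p_dim == 2:
            det = s[0, 0] * s[1, 1] - s[0, 1] * s[1, 0]
        else:
            det = np.linalg.det(s)
        if det <= 0.0 or not np.isfinite(det):
            return -np.inf
        if p_dim == 1:
            s_inv[0, 0] = 1.0 / det
        elif p_dim == 2:
            inv_det = 1.0 / det
            s_inv[0, 0] = s[1, 1] * inv_det
            s_inv[1, 1] = s[0, 0] * inv_det
            s_inv[0, 1] = -s[0, 1] * inv_det
            s_inv[1, 0] = -s[1, 0] * inv_det
        else:
            s_inv = np.linalg.inv(s)
        alpha = s_inv @ innov
        log_norm = -0.5 * (p_dim * _LOG2PI + np.log(det))
        ll += log_norm - 0.5 * (innov @ alpha)
        k = w @ s_inv                  # Kalman gain (n, p)
        # measurement update: x + K innov, P - K S K' (= P - K W')
        x = x + k @ innov
        p_new = p - k @ w.T
        # time update
        x = ad @ x
        p_new = ad @ p_new @ ad_t + qd
        p_new = 0.5 * (p_new + p_new.T)
        diff = np.max(np.abs(p_new - p))
        scale = np.max(np.abs(p_new))
        p = p_new
        # freeze threshold: relative covariance change ~1e-11 perturbs the
        # remaining log-likelihood terms far below any tolerance used here
        if diff <= 1e-11 * max(scale, 1e-300):
            steady = True
            m_mat = ad @ (np.eye(n_dim) - k @ h)
            g_mat = ad @ k
    return ll


@njit(cache=True)
def loglik_runs(ys, a_runs, sigma_z, sigma_e, f_template, h, tr):
    """Summed Kalman log-likelihood of all rest runs.

    One parameter vector across runs (couplings differ between runs only
    through the bilinear run weights already folded into ``a_runs``);
    state is re-initialized at its stationary distribution at the start of
    every run, since runs are separate acquisitions.
    """
    n_runs = ys.shape[0]
    n = f_template.shape[0]
    total = 0.0
    for r in range(n_runs):
        f = f_template.copy()
        f[0, 0] = a_runs[r, 0, 0]
        f[0, 1] = a_runs[r, 0, 1]
        f[1, 0] = a_runs[r, 1, 0]
        f[1, 1] = a_runs[r, 1, 1]
        qc = np.zeros((n, n))
        qc[0, 0] = sigma_z * sigma_z
        qc[1, 1] = sigma_z * sigma_z
        ad, qd = discretize(f, qc, tr)
        p0 = stationary_cov(ad, qd)
        x0 = np.zeros(n)
        total += kalman_loglik(ys[r], ad, qd, h, sigma_e ** 2, x0, p0)
    return total


@njit(cache=True)
def neg_log_post(theta, ys, m_fwd, m_bwd, a_self, prior_sd,
                 f_template, h, tr, stab_margin=1e-4):
    """Negative log posterior (up to the prior normalizer) of one model.

    ``m_fwd``/``m_bwd`` map the parameter vector linearly onto the
    run-wise off-diagonal couplings (average coupling plus run-weighted
    bilinear terms).  Unstable parameter regions get a smooth quadratic
    penalty pushing the optimizer back; the last three parameters are log
    noise SDs (neuronal, then one per region).
    """
    off_f = m_fwd @ theta
    off_b = m_bwd @ theta
    lam_worst = -1e30
    for r in range(4):
        prod = off_f[r] * off_b[r]
        lam = a_self + np.sqrt(prod) if prod > 0.0 else a_self
        if lam > lam_worst:
            lam_worst = lam
    if lam_worst > -stab_margin:
        return 1e6 * (lam_worst + stab_margin + 1.0) ** 2
    a_runs = np.empty((4, 2, 2))
    for r in range(4):
        a_runs[r, 0, 0] = a_self
        a_runs[r, 1, 1] = a_self
        a_runs[r, 0, 1] = off_b[r]
        a_runs[r, 1, 0] = off_f[r]
    d = theta.shape[0]
    sigma_z = np.exp(theta[d - 3])
    sigma_e = np.empty(2)
    sigma_e[0] = np.exp(theta[d - 2])
    sigma_e[1] = np.exp(theta[d - 1])
    ll = loglik_runs(ys, a_runs, sigma_z, sigma_e, f_template, h, tr)
    lp = 0.0
    for i in range(d):
        lp -= 0.5 * (theta[i] / prior_sd[i]) ** 2
    if not np.isfinite(ll):
        return 1e8
    return -(ll + lp)


@njit(cache=True)
def _state_deriv(state, drive, a_eff, kappa, gamma, tau, inv_alpha, e0):
    """Time derivative of the stacked neuronal + balloon state.

    ``state`` is (10,): z1, z2, then per region (s, f, v, q).  Flow and
    volume are clamped away from zero before the fractional powers, which
    only matters under pathological noise levels.
    """
    d = np.empty(10)
    d[0] = a_eff[0, 0] * state[0] + a_eff[0, 1] * state[1] + drive[0]
    d[1] = a_eff[1, 0] * state[0] + a_eff[1, 1] * state[1] + drive[1]
    for i in range(2):
        o = 2 + 4 * i
        s, f, v, q = state[o], state[o + 1], state[o + 2], state[o + 3]
        fi = f if f > 0.01 else 0.01
        vi = v if v > 0.01 else 0.01
        e_f = 1.0 - (1.0 - e0) ** (1.0 / fi)
        vexp = vi ** inv_alpha
        d[o] = state[i] - kappa * s - gamma * (f - 1.0)
        d[o + 1] = s
        d[o + 2] = (f - vexp) / tau
        d[o + 3] = (fi * e_f / e0 - vexp * q / vi) / tau
    return d


@njit(cache=True)
def simulate_bold_run(a_eff, eps, rho, sigma_u, u_ext, dt, n_burn,
                      sample_idx, kappa, gamma, tau, alpha, e0, v0,
                      k1, k2, k3):
    """Stochastic integration of the two-region bilinear neuronal model
    driven by AR(1) endogenous fluctuations, through the nonlinear balloon
    hemodynamic cascade, sampled at volume times.

    The drive (endogenous AR(1) plus any deterministic input) is held
    constant within a step; the state update is a Heun (trapezoidal
    predictor-corrector) step, second-order accurate in dt for the
    deterministic flow.

    ``eps`` is (n_burn + n_steps, 2) standard normal innovations;
    ``u_ext`` an optional deterministic neuronal drive on the recorded
    segment (pass zeros for rest).  Returns percent-BOLD at ``sample_idx``
    (indices into the recorded segment).
    """
    n_total = eps.shape[0]
    state = np.zeros(10)
    state[3] = state[4] = state[5] = 1.0   # f, v, q region 1
    state[7] = state[8] = state[9] = 1.0   # f, v, q region 2
    u = np.zeros(2)
    drive = np.zeros(2)
    inv_alpha = 1.0 / alpha
    c_innov = np.sqrt(1.0 - rho * rho) * sigma_u
    n_out = sample_idx.shape[0]
    y = np.zeros((n_out, 2))
    out_ptr = 0
    for step in range(n_total):
        # sample at time (step - n_burn) * dt, before this step's update
        if step >= n_burn:
            rec = step - n_burn
            while out_ptr < n_out and sample_idx[out_ptr] == rec:
                for i in range(2):
                    o = 2 + 4 * i
                    v, q = state[o + 2], state[o + 3]
                    y[out_ptr, i] = 100.0 * v0 * (
                        k1 * (1.0 - q) + k2 * (1.0 - q / v)
                        + k3 * (1.0 - v))
                out_ptr += 1
        # AR(1) endogenous drive, stationary sd sigma_u
        for i in range(2):
            u[i] = rho * u[i] + c_innov * eps[step, i]
            drive[i] = u[i]
            if step >= n_burn:
                drive[i] += u_ext[step - n_burn, i]
        d1 = _state_deriv(state, drive, a_eff, kappa, gamma, tau,
                          inv_alpha, e0)
        pred = state + dt * d1
        d2 = _state_deriv(pred, drive, a_eff, kappa, gamma, tau,
                          inv_alpha, e0)
        state = state + 0.5 * dt * (d1 + d2)
    return y
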