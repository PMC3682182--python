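"""Two-region bilinear DCM: generative simulation and state-space inversion.

Generative model
----------------
Neuronal dynamics are bilinear with run-specific coupling,

    dz/dt = (A + sum_j m_j(r) B_j) z + u(t),

where A is the average 2x2 coupling matrix (Hz; self-connections fixed
negative), B_j the bilinear change matrices, m_j(r) the run-weight vectors
of the modulators, and u endogenous fluctuations.  Each region's neuronal
activity drives a nonlinear balloon hemodynamic cascade (vasodilatory
signal s, inflow f, venous volume v, deoxyhemoglobin q) whose output is the
percent BOLD signal.

Inversion
---------
Fitting linearizes the hemodynamics around the resting fixed point, giving
a linear-Gaussian state space per run (10 states: 2 neuronal + 4 per-region
hemodynamic) whose marginal likelihood is exact via the Kalman filter
prediction-error decomposition.  MAP estimation under Gaussian shrinkage
priors plus a Laplace approximation yields the log model evidence used for
Bayesian model selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import _fast
from .config import REGIONS, FitConfig, ScanConfig
from .glm import dct_highpass_basis, residualize
from .models import DCMSpec

__all__ = [
    "HemoParams",
    "DCMParams",
    "StabilityError",
    "effective_matrix",
    "simulate",
    "hemo_linear_approx",
    "build_state_space",
    "loglik_kalman",
    "prepare_rest_series",
    "fit",
    "DCMFit",
    "coupling_timecourse",
]


class StabilityError(ValueError):
    """Raised when a run-effective coupling matrix is not stable."""


@dataclass(frozen=True)
class HemoParams:
    """Balloon-model constants (standard values for 1.5-3 T BOLD)."""

    kappa: float = 0.64   # signal decay rate (1/s)
    gamma: float = 0.32   # flow-dependent elimination (1/s)
    tau: float = 2.0      # hemodynamic transit time (s)
    alpha: float = 0.32   # Grubb's vessel stiffness exponent
    e0: float = 0.32      # resting oxygen extraction fraction
    v0: float = 0.04      # resting venous blood volume fraction

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        for name in ("kappa", "gamma", "tau", "e0", "v0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def k1(self) -> float:
        return 7.0 * self.e0

    @property
    def k2(self) -> float:
        return 2.0

    @property
    def k3(self) -> float:
        return 2.0 * self.e0 - 0.2


@dataclass(frozen=True)
class DCMParams:
    """Parameters of the two-region model.

    ``a_forward`` couples hippocampus -> striatum, ``a_backward`` the
    reverse; with region order (hippocampus, striatum) the average matrix
    is A = [[a_self, a_backward], [a_forward, a_self]].  ``b`` maps
    (modulator label, connection) -> bilinear parameter in Hz.
    """

    a_forward: float = 0.0
    a_backward: float = 0.0
    a_self: float = -0.5
    b: dict = field(default_factory=dict)
    neural_noise_sd: float = 0.02
    obs_noise_sd: tuple[float, float] = (0.25, 0.25)
    neural_noise_half_life_s: float = 2.0
    hemo: HemoParams = field(default_factory=HemoParams)

    @property
    def a_matrix(self) -> np.ndarray:
        return np.array([[self.a_self, self.a_backward],
                         [self.a_forward, self.a_self]])


_CONN_INDEX = {"forward": (1, 0), "backward": (0, 1)}


def effective_matrix(params: DCMParams, spec: DCMSpec, run: int,
                     check_stability: bool = True) -> np.ndarray:
    """Run-effective coupling matrix A + sum_j m_j(run) B_j (run in 1..4)."""
    if not 1 <= run <= 4:
        raise ValueError("run must be in 1..4")
    a = params.a_matrix.copy()
    for label, weights in spec.modulators:
        w = weights[run - 1]
        if w == 0.0:
            continue
        for conn in spec.connections_modulated:
            i, j = _CONN_INDEX[conn]
            a[i, j] += w * params.b.get((label, conn), 0.0)
    if check_stability:
        lam = np.max(np.linalg.eigvals(a).real)
        if lam >= 0:
            raise StabilityError(
                f"effective coupling matrix of run {run} is unstable "
                f"(max real eigenvalue {lam:.3f} Hz >= 0)")
    return a


def run_effective_matrices(params: DCMParams, spec: DCMSpec,
                           check_stability: bool = True) -> np.ndarray:
    return np.stack([effective_matrix(params, spec, r, check_stability)
                     for r in (1, 2, 3, 4)])


# ---------------------------------------------------------------------------
# forward simulation (nonlinear balloon model)
# ---------------------------------------------------------------------------

#: integration substeps per TR for Euler-Maruyama simulation
_SUBSTEPS = 32
_BURN_IN_S = 60.0


def simulate(params: DCMParams, spec: DCMSpec, scan: ScanConfig,
             seed: int | np.random.Generator,
             n_volumes: int | None = None,
             u_ext: np.ndarray | None = None,
             n_runs: int | None = None) -> pd.DataFrame:
    """Simulate BOLD (percent) for the rest runs of one subject.

    Euler-Maruyama at dt = TR / 32 through the full nonlinear balloon
    cascade.  Neuronal and hemodynamic states are re-initialized per run
    (separate acquisitions) and brought to stationarity by a 60-s burn-in.
    Returns a long-format frame with columns run, volume and one column per
    region.  No observation noise or drift is added here; see
    :mod:`restdcm.synth`.
    """
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    n_vol = scan.rest_volumes if n_volumes is None else n_volumes
    n_runs = scan.n_rest_runs if n_runs is None else n_runs
    dt = scan.tr_s / _SUBSTEPS
    n_steps = (n_vol - 1) * _SUBSTEPS + 1
    n_burn = int(np.ceil(_BURN_IN_S / dt))
    sample_idx = np.arange(n_vol, dtype=np.int64) * _SUBSTEPS
    rho = float(np.exp(-np.log(2.0) * dt / params.neural_noise_half_life_s))
    h = params.hemo
    a_runs = run_effective_matrices(params, spec)

    frames = []
    for r in range(n_runs):
        a_eff = a_runs[min(r, 3)]
        eps = rng.standard_normal((n_burn + n_steps, 2))
        ue = np.zeros((n_steps, 2)) if u_ext is None else u_ext[r]
        y = _fast.simulate_bold_run(
            a_eff, eps, rho, params.neural_noise_sd, ue, dt, n_burn,
            sample_idx, h.kappa, h.gamma, h.tau, h.alpha, h.e0, h.v0,
            h.k1, h.k2, h.k3)
        if not np.all(np.isfinite(y)):
            raise StabilityError(
                f"integration blew up in run {r + 1} "
                f"(max |BOLD| = {np.nanmax(np.abs(y)):.2g})")
        frames.append(pd.DataFrame({
            "run": r + 1, "volume": np.arange(n_vol),
            REGIONS[0]: y[:, 0], REGIONS[1]: y[:, 1]}))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# linearized hemodynamics and state-space construction
# ---------------------------------------------------------------------------

def hemo_linear_approx(hemo: HemoParams
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """First-order expansion of the balloon cascade at its fixed point.

    Returns (Hm, g, c): the 4x4 state matrix over (s, f-1, v-1, q-1), the
    input vector mapping neuronal activity into ds/dt, and the output row
    giving percent BOLD.
    """
    k = hemo
    c_f = 1.0 + (1.0 - k.e0) * np.log(1.0 - k.e0) / k.e0
    hm = np.array([
        [-k.kappa, -k.gamma, 0.0, 0.0],
        [1.0, 0.0, 0.0, 0.0],
        [0.0, 1.0 / k.tau, -1.0 / (k.alpha * k.tau), 0.0],
        [0.0, c_f / k.tau, -(1.0 / k.alpha - 1.0) / k.tau, -1.0 / k.tau],
    ])
    g = np.array([1.0, 0.0, 0.0, 0.0])
    c = 100.0 * k.v0 * np.array(
        [0.0, 0.0, k.k2 - k.k3, -(k.k1 + k.k2)])
    return hm, g, c


def _f_template_and_h(hemo: HemoParams) -> tuple[np.ndarray, np.ndarray]:
    """10x10 generator template (neuronal block zeroed) and 2x10 output."""
    hm, g, c = hemo_linear_approx(hemo)
    f = np.zeros((10, 10))
    h = np.zeros((2, 10))
    for i in range(2):
        sl = slice(2 + 4 * i, 6 + 4 * i)
        f[sl, sl] = hm
        f[2 + 4 * i, i] = g[0]
        h[i, sl] = c
    return f, h


def build_state_space(a_eff: np.ndarray, sigma_z: float,
                      sigma_e: np.ndarray, tr: float,
                      hemo: HemoParams | None = None) -> dict:
    """Discrete linear-Gaussian state space of one run at sampling step TR.

    Discretization uses the matrix exponential with the exact integrated
    innovation covariance (Van Loan), not an Euler step; the initial state
    is the stationary distribution of the discretized system.
    """
    hemo = hemo or HemoParams()
    f, h = _f_template_and_h(hemo)
    f[:2, :2] = a_eff
    qc = np.zeros((10, 10))
    qc[0, 0] = qc[1, 1] = sigma_z ** 2
    ad, qd = _fast.discretize(f, qc, tr)
    if np.max(np.abs(np.linalg.eigvals(ad))) >= 1.0:
        raise StabilityError("transition matrix has spectral radius >= 1")
    p0 = _fast.stationary_cov(ad, qd)
    return {"Ad": ad, "Qd": qd, "H": h,
            "R": np.asarray(sigma_e, dtype=float) ** 2,
            "x0": np.zeros(10), "P0": p0}


def loglik_kalman(y: np.ndarray, ss: dict) -> float:
    """Exact Gaussian marginal log-likelihood of one run (nats)."""
    y = np.ascontiguousarray(y, dtype=float)
    if y.ndim != 2 or y.shape[1] != ss["H"].shape[0]:
        raise ValueError("series shape does not match observation model")
    if np.any(ss["R"] <= 0):
        raise ValueError("observation noise variances must be positive")
    return float(_fast.kalman_loglik(
        y, ss["Ad"], ss["Qd"], ss["H"], ss["R"], ss["x0"], ss["P0"]))


# ---------------------------------------------------------------------------
# MAP fitting and Laplace evidence
# ---------------------------------------------------------------------------

def prepare_rest_series(rest: pd.DataFrame, scan: ScanConfig,
                        highpass_cutoff_s: float = 256.0,
                        max_volumes: int | None = None) -> np.ndarray:
    """Rest TSV frame -> (n_runs, T, 2) array ready for fitting.

    Per run: drop the initial T1-equilibration volumes, optionally truncate,
    then remove mean and discrete-cosine drift terms (256-s cutoff).
    """
    runs = sorted(rest["run"].unique())
    out = []
    for r in runs:
        sub = rest[rest["run"] == r].sort_values("volume")
        y = sub[list(REGIONS)].to_numpy()[scan.discard_initial:]
        if max_volumes is not None:
            y = y[:max_volumes]
        basis = dct_highpass_basis(len(y), scan.tr_s, highpass_cutoff_s)
        y = np.column_stack([residualize(y[:, i], basis) for i in range(2)])
        out.append(y)
    return np.stack(out)


def _param_names(spec: DCMSpec) -> list[str]:
    names = ["a_forward", "a_backward"]
    for label, _ in spec.modulators:
        for conn in spec.connections_modulated:
            names.append(f"b_{label}_{conn}")
    names += ["log_sigma_z", "log_sigma_e_1", "log_sigma_e_2"]
    return names


def _theta_to_params(theta: np.ndarray, spec: DCMSpec,
                     a_self: float) -> DCMParams:
    b = {}
    k = 2
    for label, _ in spec.modulators:
        for conn in spec.connections_modulated:
            b[(label, conn)] = float(theta[k])
            k += 1
    return DCMParams(
        a_forward=float(theta[0]), a_backward=float(theta[1]),
        a_self=a_self, b=b,
        neural_noise_sd=float(np.exp(theta[k])),
        obs_noise_sd=(float(np.exp(theta[k + 1])),
                      float(np.exp(theta[k + 2]))))


@dataclass(frozen=True)
class DCMFit:
    spec: DCMSpec
    theta: np.ndarray
    param_names: tuple[str, ...]
    map_params: DCMParams
    loglik: float
    log_prior: float
    log_evidence: float
    posterior_sd: np.ndarray
    converged: bool
    hessian_ok: bool
    n_starts_used: int

    def param(self, name: str) -> float:
        return float(self.theta[self.param_names.index(name)])


def fit(ys: np.ndarray, spec: DCMSpec, scan: ScanConfig,
        config: FitConfig | None = None,
        seed: int = 0) -> DCMFit:
    """MAP inversion of one model on prepared rest series, with Laplace
    log evidence.

    ``ys`` is (n_runs, T, 2) as returned by :func:`prepare_rest_series`.
    The parameter vector holds the two average couplings, the model's
    bilinear parameters, and log noise SDs; self-connections are fixed.
    Multi-start L-BFGS from the prior mean plus jittered starts.
    """
    config = config or FitConfig()
    ys = np.ascontiguousarray(ys, dtype=float)
    names = _param_names(spec)
    d = len(names)
    n_coupling = d - 3
    prior_sd = np.array(
        [config.prior_sd_coupling] * 2
        + [config.prior_sd_bilinear] * (n_coupling - 2)
        + [config.prior_sd_log_noise] * 3)
    f_template, h_mat = _f_template_and_h(HemoParams())
    tr = scan.tr_s

    # linear maps from the parameter vector onto run-wise off-diagonal
    # couplings: column 0/1 are the average couplings, bilinear columns
    # carry the run weights of their modulator
    m_fwd = np.zeros((4, d))
    m_bwd = np.zeros((4, d))
    m_fwd[:, 0] = 1.0
    m_bwd[:, 1] = 1.0
    k = 2
    for label, weights in spec.modulators:
        for conn in spec.connections_modulated:
            target = m_fwd if conn == "forward" else m_bwd
            target[:, k] = np.asarray(weights)
            k += 1

    def neg_log_post(theta):
        return _fast.neg_log_post(theta, ys, m_fwd, m_bwd, config.a_self,
                                  prior_sd, f_template, h_mat, tr)

    # data-scaled initial noise levels (couplings start at the prior mean)
    y_sd = float(ys.std())
    noise_init = np.array([np.log(max(y_sd, 1e-3) / 30.0),
                           np.log(max(0.3 * y_sd, 1e-3)),
                           np.log(max(0.3 * y_sd, 1e-3))])
    base = np.zeros(d)
    base[-3:] = np.clip(noise_init, -6.0, 2.0)
    rng = np.random.default_rng(seed)
    starts = [base]
    for _ in range(max(0, config.n_starts - 1)):
        starts.append(base + rng.normal(0.0, config.start_jitter_sd,
                                        size=d))

    # generous box bounds keep the optimizer away from numerically
    # degenerate regions (vanishing noise, wildly unstable couplings)
    bounds = [(-2.0, 2.0)] * n_coupling + [(-7.0, 3.0)] * 3
    best = None
    for x0 in starts:
        res = minimize(neg_log_post, x0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": config.maxiter,
                                "ftol": 1e-10, "gtol": 1e-6})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("all optimization starts failed")
    theta = best.x

    hess, hessian_ok = _numeric_hessian(neg_log_post, theta)
    sign, logdet = np.linalg.slogdet(hess)
    if sign <= 0:  # nearest-PD fallback (eigenvalue clipping)
        w, v = np.linalg.eigh(0.5 * (hess + hess.T))
        w = np.clip(w, 1e-8, None)
        hess = v @ np.diag(w) @ v.T
        logdet = float(np.sum(np.log(w)))
        hessian_ok = False
    post_cov = np.linalg.inv(hess)
    nlp = neg_log_post(theta)
    lp_quad = -0.5 * np.sum((theta / prior_sd) ** 2)
    lp = lp_quad - 0.5 * np.sum(np.log(2 * np.pi * prior_sd ** 2))
    ll = -nlp - lp_quad  # nlp = -(loglik + lp_quad)
    log_ev = ll + lp + 0.5 * d * np.log(2 * np.pi) - 0.5 * logdet

    return DCMFit(
        spec=spec, theta=theta, param_names=tuple(names),
        map_params=_theta_to_params(theta, spec, config.a_self),
        loglik=float(ll), log_prior=float(lp), log_evidence=float(log_ev),
        posterior_sd=np.sqrt(np.clip(np.diag(post_cov), 0, None)),
        converged=bool(best.success), hessian_ok=hessian_ok,
        n_starts_used=len(starts))


def _numeric_hessian(fun, x0, rel_step=1e-3):
    """Central-difference Hessian; returns (H, ok)."""
    d = len(x0)
    h = rel_step * np.maximum(1.0, np.abs(x0))
    hess = np.zeros((d, d))
    f0 = fun(x0)
    fp = np.zeros(d)
    fm = np.zeros(d)
    for i in range(d):
        e = np.zeros(d)
        e[i] = h[i]
        fp[i] = fun(x0 + e)
        fm[i] = fun(x0 - e)
        hess[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
    for i in range(d):
        for j in range(i + 1, d):
            ei = np.zeros(d)
            ej = np.zeros(d)
            ei[i] = h[i]
            ej[j] = h[j]
            fpp = fun(x0 + ei + ej)
            fmm = fun(x0 - ei - ej)
            hess[i, j] = hess[j, i] = (
                fpp - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + fmm
            ) / (2 * h[i] * h[j])
    ok = bool(np.all(np.isfinite(hess)))
    return hess, ok


def coupling_timecourse(fit_result: DCMFit,
                        spec: DCMSpec | None = None) -> dict[str, np.ndarray]:
    """Per-connection coupling change over the four runs, relative to run 1.

    change_c(r) = sum_j m_j(r) * b_jc, with the run-1 value subtracted
    (zero under all shipped weight patterns, whose first weight is 0).
    """
    spec = spec or fit_result.spec
    out = {}
    for conn in ("forward", "backward"):
        change = np.zeros(4)
        if conn in spec.connections_modulated:
            for label, weights in spec.modulators:
                b = fit_result.map_params.b.get((label, conn), 0.0)
                change += np.asarray(weights) * b
        out[conn] = change - change[0]
    return out
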