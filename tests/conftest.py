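import numpy as np
import pandas as pd
import pytest

from restdcm import GroundTruth, ScanConfig, TaskDesign


@pytest.fixture(scope="session")
def design():
    return TaskDesign()


@pytest.fixture(scope="session")
def scan():
    return ScanConfig()


@pytest.fixture(scope="session")
def truth():
    return GroundTruth()


@pytest.fixture(scope="session")
def null_truth():
    return GroundTruth(change_type="null", b_adapt=0.0, b_second=0.0)


def make_trials(rts_by_block, condition="motion", correct=None):
    """Small trial table builder for behavioral unit tests."""
    rows = []
    for block, rts in rts_by_block.items():
        for t, rt in enumerate(rts):
            rows.append({
                "subject": 0, "run": 0, "block": block, "trial": t + 1,
                "condition": condition, "rt_s": rt,
                "correct": 1 if correct is None else correct[block][t],
            })
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


def brute_force_loglik(y, ad, qd, h, r_diag, p0):
    """Joint-Gaussian log density of a short linear state-space series.

    Builds the full T*p x T*p observation covariance from the state
    recursion (x_0 ~ N(0, p0); x_{t+1} = Ad x_t + w) and evaluates the
    multivariate normal density directly — the independent oracle for the
    Kalman prediction-error decomposition.
    """
    from scipy.stats import multivariate_normal

    T, p = y.shape
    n = ad.shape[0]
    Ps = [p0]
    for _ in range(1, T):
        Ps.append(ad @ Ps[-1] @ ad.T + qd)
    cov_x = np.zeros((T * n, T * n))
    for t in range(T):
        for s in range(t, T):
            block = np.linalg.matrix_power(ad, s - t) @ Ps[t]
            cov_x[s * n:(s + 1) * n, t * n:(t + 1) * n] = block
            cov_x[t * n:(t + 1) * n, s * n:(s + 1) * n] = block.T
    Hbig = np.kron(np.eye(T), h)
    cov_y = Hbig @ cov_x @ Hbig.T + np.kron(np.eye(T), np.diag(r_diag))
    return float(multivariate_normal.logpdf(
        y.ravel(), mean=np.zeros(T * p), cov=cov_y))


def random_state_space(rng, n=None, p=None, T=None):
    """A random stable discrete linear-Gaussian state space instance."""
    n = n or int(rng.integers(1, 4))
    p = p or int(rng.integers(1, 3))
    T = T or int(rng.integers(2, 11))
    M = rng.normal(size=(n, n)) * 0.5
    ad = M / (np.max(np.abs(np.linalg.eigvals(M))) + 1.0) * 0.9
    L = rng.normal(size=(n, n))
    qd = L @ L.T + 0.1 * np.eye(n)
    h = rng.normal(size=(p, n))
    r = rng.uniform(0.2, 1.0, p)
    Lp = rng.normal(size=(n, n))
    p0 = Lp @ Lp.T + 0.1 * np.eye(n)
    y = rng.normal(size=(T, p))
    return y, ad, qd, h, r, p0
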