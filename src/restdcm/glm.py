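"""ROI-level first-level convolution GLM with an IE parametric modulator.

The design follows the standard block-design convention: condition boxcars
convolved with a canonical double-gamma hemodynamic response function (HRF),
a motion-task regressor parametrically modulated by the fitted inverse
efficiency of each block (mean-centered per run before convolution), a
discrete-cosine high-pass basis per run, and per-run constants.  Estimation
is ordinary least squares on region-averaged time series; subject-level
contrasts feed a one-sample t-test at the group level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .config import MOTION, CONTROL, ScanConfig, TaskDesign

__all__ = [
    "hrf_kernel",
    "dct_highpass_basis",
    "block_events",
    "build_task_design",
    "fit_first_level",
    "group_ttest",
]


def hrf_kernel(dt: float, duration_s: float = 32.0,
               peak_delay_s: float = 6.0, undershoot_delay_s: float = 16.0,
               ratio: float = 6.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at ``dt``, normalized to unit sum.

    Difference of two gamma densities (shape = delay / dispersion with unit
    dispersion), the undershoot scaled down by ``ratio``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0, duration_s + dt / 2, dt)

    def gamma_pdf(x, shape):
        with np.errstate(divide="ignore"):
            logpdf = (shape - 1) * np.log(x) - x - gammaln(shape)
        out = np.exp(logpdf)
        out[x <= 0] = 0.0
        return out

    h = gamma_pdf(t, peak_delay_s) - gamma_pdf(t, undershoot_delay_s) / ratio
    return h / h.sum()


def dct_highpass_basis(n_volumes: int, tr: float, cutoff_s: float
                       ) -> np.ndarray:
    """Orthonormal discrete-cosine drift basis for high-pass filtering.

    Returns the non-constant DCT-II columns with period longer than
    ``cutoff_s``; the number of columns is floor(2 * n * tr / cutoff + 1) - 1
    (the constant term is excluded — regressions should carry their own
    intercept).
    """
    if cutoff_s <= 2 * tr:
        raise ValueError("cutoff must exceed 2 * TR")
    if n_volumes < 2:
        raise ValueError("need at least 2 volumes")
    k = int(np.floor(2.0 * n_volumes * tr / cutoff_s + 1.0))
    n = n_volumes
    t = np.arange(n)
    cols = [np.sqrt(2.0 / n) * np.cos(np.pi * (2 * t + 1) * j / (2 * n))
            for j in range(1, k)]
    if not cols:
        return np.empty((n, 0))
    return np.column_stack(cols)


def residualize(y: np.ndarray, basis: np.ndarray,
                demean: bool = True) -> np.ndarray:
    """Project drift basis (and optionally the mean) out of a series."""
    y = np.asarray(y, dtype=float)
    X = basis
    if demean:
        X = np.column_stack([np.ones(len(y)), basis]) if basis.size \
            else np.ones((len(y), 1))
    if X.size == 0:
        return y.copy()
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def block_events(design: TaskDesign, scan: ScanConfig,
                 start_condition: str = MOTION) -> pd.DataFrame:
    """Block onset table for the task session.

    The 2 x 25 blocks strictly alternate between conditions, starting with
    ``start_condition``, and are spread evenly over the task runs (the
    scanner restarts between runs).  Onsets are seconds from the start of
    each run's acquisition (volume 0).
    """
    other = CONTROL if start_condition == MOTION else MOTION
    n_global = 2 * design.n_blocks_per_condition
    per_run = n_global // scan.n_task_runs
    rows = []
    counters = {MOTION: 0, CONTROL: 0}
    for g in range(n_global):
        cond = start_condition if g % 2 == 0 else other
        counters[cond] += 1
        run = g // per_run
        within = g % per_run
        onset = design.run_lead_in_s + within * (
            design.block_duration_s + design.inter_block_gap_s)
        rows.append({"run": run, "condition": cond,
                     "block": counters[cond], "onset_s": onset,
                     "duration_s": design.block_duration_s})
    return pd.DataFrame(rows)


def _convolved_regressor(onsets, durations, amplitudes, n_volumes, tr,
                         discard, dt=0.1):
    """Boxcar at resolution ``dt`` convolved with the HRF, sampled at
    retained volume times."""
    total_s = n_volumes * tr
    n_fine = int(np.ceil(total_s / dt)) + 1
    u = np.zeros(n_fine)
    for on, dur, amp in zip(onsets, durations, amplitudes):
        i0 = int(round(on / dt))
        i1 = min(int(round((on + dur) / dt)), n_fine)
        u[i0:i1] += amp
    h = hrf_kernel(dt)
    conv = np.convolve(u, h)[:n_fine]
    vol_times = (np.arange(discard, n_volumes) * tr / dt).round().astype(int)
    return conv[np.minimum(vol_times, n_fine - 1)]


@dataclass(frozen=True)
class DesignMatrix:
    """Concatenated multi-run design with named columns."""

    X: np.ndarray
    names: tuple[str, ...]

    def column(self, name: str) -> int:
        return self.names.index(name)

    def contrast_vector(self, name: str) -> np.ndarray:
        c = np.zeros(self.X.shape[1])
        c[self.column(name)] = 1.0
        return c


def build_task_design(design: TaskDesign, scan: ScanConfig,
                      ie_fitted: np.ndarray,
                      start_condition: str = MOTION,
                      highpass_cutoff_s: float = 128.0,
                      dt: float = 0.1) -> DesignMatrix:
    """First-level design for the learning session.

    Columns: motion and control boxcar regressors convolved with the HRF,
    a motion regressor weighted by the per-block fitted IE (mean-centered
    per run before convolution), per-run DCT high-pass columns, per-run
    constants.  Rows cover retained volumes of all task runs, concatenated.
    """
    ie_fitted = np.asarray(ie_fitted, dtype=float)
    if len(ie_fitted) != design.n_blocks_per_condition:
        raise ValueError("one fitted IE value per motion block required")
    events = block_events(design, scan, start_condition)
    n_ret = scan.task_volumes_per_run - scan.discard_initial
    runs = range(scan.n_task_runs)

    task_cols = {MOTION: [], CONTROL: [], "ie_mod": []}
    for r in runs:
        ev = events[events["run"] == r]
        for cond in (MOTION, CONTROL):
            sel = ev[ev["condition"] == cond]
            task_cols[cond].append(_convolved_regressor(
                sel["onset_s"].to_numpy(), sel["duration_s"].to_numpy(),
                np.ones(len(sel)), scan.task_volumes_per_run, scan.tr_s,
                scan.discard_initial, dt))
        mot = ev[ev["condition"] == MOTION]
        amp = ie_fitted[mot["block"].to_numpy() - 1]
        amp = amp - amp.mean()
        task_cols["ie_mod"].append(_convolved_regressor(
            mot["onset_s"].to_numpy(), mot["duration_s"].to_numpy(), amp,
            scan.task_volumes_per_run, scan.tr_s, scan.discard_initial, dt))

    n_runs = scan.n_task_runs
    dct = dct_highpass_basis(n_ret, scan.tr_s, highpass_cutoff_s)
    cols = [np.concatenate(task_cols[MOTION]),
            np.concatenate(task_cols[CONTROL]),
            np.concatenate(task_cols["ie_mod"])]
    names = [MOTION, CONTROL, "ie_mod"]
    for r in runs:
        block = np.zeros((n_ret * n_runs, dct.shape[1] + 1))
        block[r * n_ret:(r + 1) * n_ret, :dct.shape[1]] = dct
        block[r * n_ret:(r + 1) * n_ret, -1] = 1.0
        for j in range(dct.shape[1]):
            cols.append(block[:, j])
            names.append(f"dct{j + 1}_run{r}")
        cols.append(block[:, -1])
        names.append(f"const_run{r}")
    return DesignMatrix(X=np.column_stack(cols), names=tuple(names))


@dataclass(frozen=True)
class FirstLevelFit:
    betas: np.ndarray
    names: tuple[str, ...]
    sigma2: float
    dof: int
    residuals: np.ndarray

    def beta(self, name: str) -> float:
        return float(self.betas[self.names.index(name)])


def fit_first_level(y: np.ndarray, design: DesignMatrix) -> FirstLevelFit:
    """OLS fit of an ROI series on the design matrix."""
    y = np.asarray(y, dtype=float)
    X = design.X
    if y.shape[0] != X.shape[0]:
        raise ValueError("series and design have different lengths")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns for the error message
        q, r = np.linalg.qr(X)
        bad = [design.names[j] for j in range(X.shape[1])
               if abs(r[j, j]) < 1e-8 * abs(r[0, 0])]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (collinear columns: {bad})")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = y.shape[0] - X.shape[1]
    sigma2 = float(resid @ resid / dof) if dof > 0 else 0.0
    return FirstLevelFit(betas=beta, names=design.names, sigma2=sigma2,
                         dof=dof, residuals=resid)


def contrast_t(fit: FirstLevelFit, design: DesignMatrix,
               contrast: np.ndarray | str) -> tuple[float, float, int]:
    """t statistic for a contrast of first-level betas: c'b / SE(c'b)."""
    c = design.contrast_vector(contrast) if isinstance(contrast, str) \
        else np.asarray(contrast, dtype=float)
    XtX_inv = np.linalg.pinv(design.X.T @ design.X)
    var = fit.sigma2 * float(c @ XtX_inv @ c)
    est = float(c @ fit.betas)
    t = est / np.sqrt(var) if var > 0 else np.inf * np.sign(est)
    p = 2 * stats.t.sf(abs(t), fit.dof)
    return float(t), float(p), fit.dof


def group_ttest(values: np.ndarray) -> dict:
    """One-sample t-test of per-subject contrast values against zero."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 subjects")
    if np.allclose(v.std(ddof=1), 0.0):
        if np.allclose(v.mean(), 0.0):
            raise ValueError("degenerate input: all values identically zero")
        raise ValueError("degenerate input: zero between-subject variance "
                         "with nonzero mean (infinite t)")
    t, p = stats.ttest_1samp(v, 0.0)
    return {"t": float(t), "p": float(p), "dof": len(v) - 1,
            "mean": float(v.mean()), "n": len(v)}
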