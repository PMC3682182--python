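"""Seeded synthetic cohorts: behavior plus four-run two-region rest BOLD.

The generator emulates the statistical structure the downstream analysis
assumes: exponentially improving performance over 25 blocks per condition,
and rest BOLD from the bilinear two-region neuronal model (coupling changes
across runs following a configurable pattern, by default consolidation)
passed through the nonlinear balloon hemodynamics, with slow discrete-cosine
drifts and white observation noise added on top.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import behavior as behavior_mod
from . import dcm, glm, io
from .config import (CONTROL, MOTION, REGIONS, GroundTruth, ScanConfig,
                     TaskDesign)
from .models import DCMSpec, make_spec

__all__ = [
    "truth_to_dcm_params",
    "truth_spec",
    "gen_behavior",
    "gen_rest_bold",
    "gen_task_bold",
    "gen_subject",
    "gen_cohort",
]


def truth_spec(truth: GroundTruth) -> DCMSpec:
    """The generative model spec implied by a ground truth."""
    if truth.change_type == "null":
        return make_spec("null")
    return make_spec(truth.change_type, tuple(truth.connections_modulated))


def truth_to_dcm_params(truth: GroundTruth) -> dcm.DCMParams:
    """Map generative ground truth onto neuronal/hemodynamic parameters."""
    b = {}
    spec = truth_spec(truth)
    for label, _ in spec.modulators:
        val = truth.b_adapt if label == "adaptation" else truth.b_second
        for conn in spec.connections_modulated:
            b[(label, conn)] = val
    return dcm.DCMParams(
        a_forward=truth.a_forward, a_backward=truth.a_backward,
        a_self=truth.a_self, b=b,
        neural_noise_sd=truth.neural_noise_sd,
        neural_noise_half_life_s=truth.neural_noise_half_life_s,
        obs_noise_sd=(truth.obs_noise_sd_pct, truth.obs_noise_sd_pct))


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

#: RT learning rate at which the accuracy midpoint/scale are calibrated
_REFERENCE_LEARNING_RATE = 0.15


def _accuracy_curve(block: np.ndarray, bt) -> np.ndarray:
    """Logistic rise of motion-task accuracy toward its asymptote.

    The logistic argument scales with the learning rate ``b`` shared with
    the RT decay, so a non-learning subject (b = 0) has flat accuracy.
    """
    rate = bt.b_per_block / _REFERENCE_LEARNING_RATE
    z = rate * (block - bt.accuracy_midpoint_block) \
        / bt.accuracy_scale_blocks
    return bt.accuracy_floor + (bt.accuracy_asymptote - bt.accuracy_floor) \
        / (1.0 + np.exp(-z))


def _truncated_normal(rng, mean, sd, lo, hi, size):
    if sd == 0:
        return np.full(size, mean, dtype=float)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def gen_behavior(design: TaskDesign, truth: GroundTruth, seed,
                 subject: int = 0) -> pd.DataFrame:
    """Trial table for one subject (columns: subject, run, block, trial,
    condition, rt_s, correct).

    Motion-task reaction times decay exponentially with block toward an
    asymptote and accuracy rises logistically, so block inverse efficiency
    follows an approximately exponential learning curve.  Control blocks
    stay near ceiling.  The starting condition alternates with subject
    parity (counterbalancing); omitted responses carry no RT and count as
    errors.
    """
    design.validate()
    truth.validate()
    bt = truth.behavior
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed

    start = MOTION if subject % 2 == 0 else CONTROL
    events = glm.block_events(design, ScanConfig(), start_condition=start)
    rows = []
    rt_hi = design.stimulus_duration_s + design.response_window_s
    for _, ev in events.iterrows():
        x = ev["block"]
        if ev["condition"] == MOTION:
            p_correct = _accuracy_curve(np.array([x]), bt)[0]
            rt_mean = bt.rt_asymptote_s + bt.a_s * np.exp(
                -bt.b_per_block * x)
        else:
            p_correct = bt.control_accuracy
            rt_mean = bt.control_rt_s
        n = design.trials_per_block
        rts = _truncated_normal(rng, rt_mean, bt.rt_sd_s, 0.05, rt_hi, n)
        correct = rng.random(n) < p_correct
        missed = rng.random(n) < bt.miss_rate
        for t in range(n):
            rows.append({
                "subject": subject, "run": int(ev["run"]),
                "block": int(x), "trial": t + 1,
                "condition": ev["condition"],
                "rt_s": np.nan if missed[t] else float(rts[t]),
                "correct": 0 if missed[t] else int(correct[t]),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rest BOLD
# ---------------------------------------------------------------------------

def _drift(n_vol: int, tr: float, rng, truth: GroundTruth) -> np.ndarray:
    """Slow drift: the lowest-frequency DCT components with random
    amplitudes, removable by the 256-s high-pass filter."""
    basis = glm.dct_highpass_basis(n_vol, tr, cutoff_s=max(
        256.0, 2.5 * tr))[:, :truth.n_drift_components]
    amps = rng.normal(0.0, truth.drift_sd_pct,
                      size=(basis.shape[1], 2)) * np.sqrt(n_vol)
    return basis @ amps


def gen_rest_bold(truth: GroundTruth, scan: ScanConfig, seed,
                  n_volumes: int | None = None) -> pd.DataFrame:
    """Four rest runs of two-region BOLD (percent), long format.

    Per run r the neuronal coupling is A + sum_j m_j(r) B_j under the
    ground-truth change pattern; full nonlinear balloon hemodynamics are
    applied, then slow drift and white observation noise are added.
    """
    truth.validate()
    scan.validate()
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    params = truth_to_dcm_params(truth)
    spec = truth_spec(truth)
    clean = dcm.simulate(params, spec, scan, rng, n_volumes=n_volumes)
    n_vol = scan.rest_volumes if n_volumes is None else n_volumes
    for r in sorted(clean["run"].unique()):
        mask = clean["run"] == r
        d = _drift(n_vol, scan.tr_s, rng, truth)
        noise = rng.normal(0.0, truth.obs_noise_sd_pct, size=(n_vol, 2))
        for i, reg in enumerate(REGIONS):
            clean.loc[mask, reg] = clean.loc[mask, reg].to_numpy() \
                + d[:, i] + noise[:, i]
    return clean


# ---------------------------------------------------------------------------
# task BOLD
# ---------------------------------------------------------------------------

def gen_task_bold(design: TaskDesign, truth: GroundTruth, scan: ScanConfig,
                  seed, ie_fitted: np.ndarray,
                  start_condition: str = MOTION,
                  noise: bool = True) -> pd.DataFrame:
    """Five task runs of two-region BOLD (percent).

    The hippocampus-like region responds to motion blocks with an evoked
    amplitude that scales linearly with the subject's fitted block IE
    (learning-related adaptation); the striatal control region responds to
    the task without learning modulation.  Signals are built with the same
    HRF convolution used by the first-level GLM.
    """
    design.validate()
    scan.validate()
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    full_scan = dataclasses.replace(scan, discard_initial=0)
    dm = glm.build_task_design(design, full_scan, ie_fitted,
                               start_condition=start_condition,
                               highpass_cutoff_s=128.0)
    amp = truth.task_evoked_amplitude
    gain = truth.task_ie_gain
    hip = amp * dm.X[:, dm.column(MOTION)] \
        + gain * dm.X[:, dm.column("ie_mod")]
    stri = amp * dm.X[:, dm.column(MOTION)] \
        + 0.5 * amp * dm.X[:, dm.column(CONTROL)]
    n_vol = scan.task_volumes_per_run
    frames = []
    for r in range(scan.n_task_runs):
        sl = slice(r * n_vol, (r + 1) * n_vol)
        y = np.column_stack([hip[sl], stri[sl]])
        if noise:
            y = y + _drift(n_vol, scan.tr_s, rng, truth)
            y = y + rng.normal(0.0, truth.obs_noise_sd_pct,
                               size=(n_vol, 2))
        frames.append(pd.DataFrame({
            "run": r + 1, "volume": np.arange(n_vol),
            REGIONS[0]: y[:, 0], REGIONS[1]: y[:, 1]}))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def gen_subject(design: TaskDesign, truth: GroundTruth, scan: ScanConfig,
                seed, subject: int = 0,
                rest_volumes: int | None = None,
                include_task: bool = True) -> dict:
    """All per-subject artifacts, in memory."""
    rng = np.random.default_rng(seed)
    trials = gen_behavior(design, truth, rng, subject=subject)
    curve = behavior_mod.analyze_subject(trials)
    out = {
        "behavior": trials,
        "curve": curve,
        "rest": gen_rest_bold(truth, scan, rng, n_volumes=rest_volumes),
    }
    if include_task:
        start = MOTION if subject % 2 == 0 else CONTROL
        out["task"] = gen_task_bold(design, truth, scan, rng,
                                    curve.ie_fitted, start_condition=start)
    return out


def gen_cohort(n_subjects: int, out_dir: str | Path,
               design: TaskDesign | None = None,
               truth: GroundTruth | None = None,
               scan: ScanConfig | None = None,
               master_seed: int = 0, overwrite: bool = False,
               rest_volumes: int | None = None,
               include_task: bool = True) -> Path:
    """Write a cohort dataset: one directory per subject with behavior,
    rest and task TSVs plus a JSON ground-truth sidecar.

    Per-subject seeds are spawned reproducibly from the master seed, so the
    same (master_seed, n_subjects) always yields byte-identical files.
    Refuses to write into an existing non-empty directory unless
    ``overwrite`` is set.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    design = design or TaskDesign()
    truth = truth or GroundTruth()
    scan = scan or ScanConfig()
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(
            f"{out_dir} exists and is not empty (pass overwrite=True)")
    out_dir.mkdir(parents=True, exist_ok=True)

    children = np.random.SeedSequence(master_seed).spawn(n_subjects)
    for s in range(n_subjects):
        sub_dir = out_dir / f"sub-{s + 1:02d}"
        sub_dir.mkdir(parents=True, exist_ok=True)
        data = gen_subject(design, truth, scan, children[s], subject=s,
                           rest_volumes=rest_volumes,
                           include_task=include_task)
        io.write_tsv(data["behavior"], sub_dir / "behavior.tsv")
        io.write_tsv(data["rest"], sub_dir / "rest_bold.tsv")
        if include_task:
            io.write_tsv(data["task"], sub_dir / "task_bold.tsv")
        sidecar = json.loads(truth.to_json())
        sidecar["subject"] = s
        sidecar["modulator_weights"] = {
            label: list(w) for label, w in truth_spec(truth).modulators}
        (sub_dir / "ground_truth.json").write_text(
            json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
    return out_dir
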