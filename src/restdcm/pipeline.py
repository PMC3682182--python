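"""End-to-end replay: simulate -> behavior -> glm -> ppi -> dcm-fit -> bms.

Each stage reads and writes declared files inside a dataset directory, so
the pipeline is restartable at any stage and no stage touches another's
internals.  ``run_all`` executes everything and writes a machine-readable
``report.json`` with the group PPI interaction test, the BMS winner and
criterion status, and the subject-averaged coupling timecourse of the
winning model (with SEM).
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as behavior_mod
from . import dcm, glm, io, ppi, synth
from .config import MOTION, CONTROL, PipelineConfig, REGIONS
from .models import build_model_space, fixed_effects_bms

log = logging.getLogger("restdcm")

__all__ = [
    "stage_simulate", "stage_behavior", "stage_glm", "stage_ppi",
    "stage_dcm_fit", "stage_bms", "run_all",
]


def _subject_dirs(data_dir: Path) -> list[Path]:
    subs = sorted(Path(data_dir).glob("sub-*"))
    if not subs:
        raise FileNotFoundError(f"no sub-* directories under {data_dir}")
    return subs


def stage_simulate(config: PipelineConfig, out_dir: str | Path,
                   overwrite: bool = False,
                   rest_volumes: int | None = None) -> Path:
    config.validate()
    t0 = time.time()
    path = synth.gen_cohort(
        config.n_subjects, out_dir, design=config.design,
        truth=config.truth, scan=config.scan,
        master_seed=config.master_seed, overwrite=overwrite,
        rest_volumes=rest_volumes)
    log.info("stage=simulate subjects=%d seed=%d elapsed=%.1fs",
             config.n_subjects, config.master_seed, time.time() - t0)
    return path


def stage_behavior(config: PipelineConfig, data_dir: str | Path) -> dict:
    results = {}
    for sub in _subject_dirs(data_dir):
        trials = io.read_tsv(sub / "behavior.tsv")
        curve = behavior_mod.analyze_subject(trials)
        flags = behavior_mod.screen_performance(
            trials, ceiling=config.ceiling_accuracy,
            floor=config.floor_accuracy)
        io.write_tsv(curve.to_frame(), sub / "learning_curve.tsv")
        summary = {"a": curve.a, "b": curve.b, "rss": curve.rss,
                   "excluded_trials": curve.excluded_trials, **flags}
        (sub / "learning_curve.json").write_text(
            json.dumps(summary, indent=2) + "\n")
        results[sub.name] = summary
        log.info("stage=behavior subject=%s a=%.3f b=%.3f", sub.name,
                 curve.a, curve.b)
    return results


def stage_glm(config: PipelineConfig, data_dir: str | Path) -> dict:
    scan, design = config.scan, config.design
    betas = {}
    for i, sub in enumerate(_subject_dirs(data_dir)):
        task = io.read_tsv(sub / "task_bold.tsv")
        curve = io.read_tsv(sub / "learning_curve.tsv")
        start = MOTION if i % 2 == 0 else CONTROL
        dm = glm.build_task_design(
            design, scan, curve["ie_fitted"].to_numpy(),
            start_condition=start,
            highpass_cutoff_s=config.task_highpass_cutoff_s)
        y = np.concatenate([
            task[task["run"] == r].sort_values("volume")[REGIONS[0]]
            .to_numpy()[scan.discard_initial:]
            for r in sorted(task["run"].unique())])
        fit = glm.fit_first_level(y, dm)
        t, p, dof = glm.contrast_t(fit, dm, "ie_mod")
        row = {"beta_ie": fit.beta("ie_mod"), "beta_motion": fit.beta(MOTION),
               "t_ie": t, "p_ie": p, "dof": dof}
        (sub / "glm.json").write_text(json.dumps(row, indent=2) + "\n")
        betas[sub.name] = row
        log.info("stage=glm subject=%s beta_ie=%.3f t=%.2f", sub.name,
                 row["beta_ie"], t)
    group = glm.group_ttest([v["beta_ie"] for v in betas.values()])
    return {"per_subject": betas, "group": group}


def stage_ppi(config: PipelineConfig, data_dir: str | Path,
              seed_region: str = REGIONS[0],
              target_region: str = REGIONS[1]) -> dict:
    rows = {}
    for sub in _subject_dirs(data_dir):
        rest = io.read_tsv(sub / "rest_bold.tsv")
        fc = ppi.subject_factorial(
            rest, config.scan, seed_region=seed_region,
            target_region=target_region,
            highpass_cutoff_s=config.fit.highpass_cutoff_s)
        row = {"slopes": list(fc.slopes), "main_day": fc.main_day,
               "main_time": fc.main_time, "interaction": fc.interaction}
        (sub / "ppi.json").write_text(json.dumps(row, indent=2) + "\n")
        rows[sub.name] = row
        log.info("stage=ppi subject=%s interaction=%.3f", sub.name,
                 fc.interaction)
    group = ppi.group_interaction_test(
        [r["interaction"] for r in rows.values()])
    return {"per_subject": rows, "group": group}


def stage_dcm_fit(config: PipelineConfig, data_dir: str | Path,
                  max_volumes: int | None = None) -> dict:
    space = build_model_space()
    out = {}
    for i, sub in enumerate(_subject_dirs(data_dir)):
        rest = io.read_tsv(sub / "rest_bold.tsv")
        ys = dcm.prepare_rest_series(
            rest, config.scan,
            highpass_cutoff_s=config.fit.highpass_cutoff_s,
            max_volumes=max_volumes)
        t0 = time.time()
        fits = {}
        for spec in space:
            f = dcm.fit(ys, spec, config.scan, config.fit,
                        seed=config.master_seed * 1000 + i)
            fits[spec.name] = {
                "log_evidence": f.log_evidence,
                "loglik": f.loglik,
                "theta": dict(zip(f.param_names, f.theta.tolist())),
                "posterior_sd": dict(zip(f.param_names,
                                         f.posterior_sd.tolist())),
                "converged": f.converged,
                "hessian_ok": f.hessian_ok,
                "coupling_timecourse": {
                    c: v.tolist()
                    for c, v in dcm.coupling_timecourse(f).items()},
            }
        (sub / "dcm_fits.json").write_text(
            json.dumps(fits, indent=2) + "\n")
        out[sub.name] = fits
        log.info("stage=dcm-fit subject=%s models=%d elapsed=%.1fs",
                 sub.name, len(space), time.time() - t0)
    return out


def stage_bms(data_dir: str | Path) -> dict:
    space = build_model_space()
    names = [s.name for s in space]
    subs = _subject_dirs(data_dir)
    log_ev = np.array([
        [json.loads((sub / "dcm_fits.json").read_text())[m]["log_evidence"]
         for m in names] for sub in subs])
    res = fixed_effects_bms(log_ev, names)
    # coupling timecourse of the winning model, averaged over subjects
    winner = res.winner
    tc = {c: [] for c in ("forward", "backward")}
    for sub in subs:
        fits = json.loads((sub / "dcm_fits.json").read_text())
        for c, v in fits[winner]["coupling_timecourse"].items():
            tc[c].append(v)
    timecourse = {}
    for c, vals in tc.items():
        if not vals:
            continue
        arr = np.asarray(vals)
        timecourse[c] = {
            "mean": arr.mean(axis=0).tolist(),
            "sem": (arr.std(axis=0, ddof=1)
                    / np.sqrt(arr.shape[0])).tolist(),
        }
    bms_frame = pd.DataFrame({"model": names, "summed": res.summed,
                              "relative": res.relative})
    io.write_tsv(bms_frame, Path(data_dir) / "bms.tsv")
    out = {"bms": res.as_dict(), "coupling_timecourse": timecourse}
    (Path(data_dir) / "bms.json").write_text(
        json.dumps(out, indent=2) + "\n")
    log.info("stage=bms winner=%s criterion_met=%s", res.winner,
             res.criterion_met)
    return out


def make_figures(data_dir: str | Path) -> list[Path]:
    """Render the report figures from stage outputs already on disk."""
    from . import plots

    data_dir = Path(data_dir)
    out = []
    curves = {}
    for sub in _subject_dirs(data_dir):
        if (sub / "learning_curve.tsv").exists():
            curves[sub.name] = io.read_tsv(sub / "learning_curve.tsv")
    if curves:
        p = data_dir / "fig_learning_curve.png"
        plots.plot_learning_curves(curves, p)
        out.append(p)
    if (data_dir / "bms.json").exists():
        res = json.loads((data_dir / "bms.json").read_text())
        p = data_dir / "fig_relative_evidence.png"
        plots.plot_relative_evidence(res["bms"]["model_names"],
                                     res["bms"]["relative"], p)
        out.append(p)
        if res["coupling_timecourse"]:
            p = data_dir / "fig_coupling_timecourse.png"
            plots.plot_coupling_timecourse(res["coupling_timecourse"], p)
            out.append(p)
    return out


def run_all(config: PipelineConfig, out_dir: str | Path,
            overwrite: bool = False,
            rest_volumes: int | None = None,
            max_fit_volumes: int | None = None,
            figures: bool = True) -> dict:
    """Execute every stage in order and write ``report.json``.

    ``rest_volumes`` optionally shortens the simulated rest runs and
    ``max_fit_volumes`` truncates the series used for DCM fitting; both
    default to the full acquisition length.
    """
    out_dir = Path(out_dir)
    stage_simulate(config, out_dir, overwrite=overwrite,
                   rest_volumes=rest_volumes)
    report: dict = {"config": {"n_subjects": config.n_subjects,
                               "master_seed": config.master_seed},
                    "version": 1}
    report["behavior"] = stage_behavior(config, out_dir)
    report["glm"] = stage_glm(config, out_dir)
    report["ppi"] = stage_ppi(config, out_dir)
    stage_dcm_fit(config, out_dir, max_volumes=max_fit_volumes)
    report["bms"] = stage_bms(out_dir)
    if figures:
        make_figures(out_dir)
    (out_dir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
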