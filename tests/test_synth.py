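"""Synthetic cohort generator: behavior, rest/task BOLD, dataset layout."""

import dataclasses
import json

import numpy as np
import pytest
from scipy import stats

from restdcm import behavior, models, synth
from restdcm.config import (MOTION, CONTROL, BehaviorTruth, GroundTruth,
                            ScanConfig, TaskDesign)


class TestBehaviorGenerator:
    def test_trial_counts_and_structure(self, design, truth):
        trials = synth.gen_behavior(design, truth, seed=0)
        assert len(trials) == 800
        counts = trials["condition"].value_counts()
        assert counts[MOTION] == 400 and counts[CONTROL] == 400
        per_block = trials.groupby(["condition", "block"]).size()
        assert (per_block == 16).all()
        assert trials["block"].max() == 25

    def test_blocks_strictly_alternate(self, design, truth):
        trials = synth.gen_behavior(design, truth, seed=0, subject=0)
        order = trials.drop_duplicates(
            subset=["run", "block", "condition"])
        conds = order["condition"].tolist()
        assert all(a != b for a, b in zip(conds, conds[1:]))

    def test_start_condition_counterbalanced(self, design, truth):
        t0 = synth.gen_behavior(design, truth, seed=0, subject=0)
        t1 = synth.gen_behavior(design, truth, seed=0, subject=1)
        assert t0["condition"].iloc[0] != t1["condition"].iloc[0]

    def test_control_accuracy_near_ceiling(self, design, truth):
        trials = synth.gen_behavior(design, truth, seed=3)
        acc = trials[trials["condition"] == CONTROL]["correct"].mean()
        assert acc >= 0.97

    def test_zero_learning_rate_gives_flat_ie(self, design, truth):
        flat = dataclasses.replace(
            truth, behavior=dataclasses.replace(truth.behavior,
                                                b_per_block=0.0))
        trials = synth.gen_behavior(design, flat, seed=1)
        kept, _ = behavior.exclude_rt_outliers(trials)
        ie = behavior.block_inverse_efficiency(kept).to_numpy()
        x = np.arange(len(ie))
        slope, _, _, _, se = stats.linregress(x, ie)[:5]
        assert abs(slope) < 3 * se

    def test_deterministic_rt_equals_block_ie(self, design, truth):
        exact = dataclasses.replace(
            truth, behavior=dataclasses.replace(
                truth.behavior, rt_sd_s=0.0, accuracy_floor=1.0,
                accuracy_asymptote=1.0, control_accuracy=1.0,
                miss_rate=0.0))
        trials = synth.gen_behavior(design, exact, seed=2)
        ie = behavior.block_inverse_efficiency(trials)
        motion = trials[trials["condition"] == MOTION]
        mean_rt = motion.groupby("block")["rt_s"].mean()
        np.testing.assert_allclose(ie.to_numpy(), mean_rt.to_numpy(),
                                   rtol=1e-12)

    def test_learning_curve_close_to_exponential(self, design, truth):
        trials = synth.gen_behavior(design, truth, seed=4)
        curve = behavior.analyze_subject(trials)
        assert curve.b > 0.02  # clear learning
        # raw IE decays: early blocks slower than late blocks
        assert curve.ie_raw[:5].mean() > curve.ie_raw[-5:].mean()

    def test_negative_rt_parameters_rejected(self, design, truth):
        bad = dataclasses.replace(
            truth, behavior=dataclasses.replace(truth.behavior,
                                                rt_asymptote_s=-1.0))
        with pytest.raises(ValueError):
            synth.gen_behavior(design, bad, seed=0)


class TestRestGenerator:
    def test_four_runs_of_276_volumes(self, truth, scan):
        rest = synth.gen_rest_bold(truth, scan, seed=0)
        assert sorted(rest["run"].unique()) == [1, 2, 3, 4]
        assert (rest.groupby("run").size() == 276).all()
        assert list(rest.columns) == ["run", "volume", "hippocampus",
                                      "striatum"]

    def test_unstable_truth_raises(self, scan):
        bad = GroundTruth(a_forward=0.4, a_backward=0.4, b_adapt=0.1,
                          b_second=0.1)
        with pytest.raises(Exception, match="run|unstable"):
            synth.gen_rest_bold(bad, scan, seed=0, n_volumes=20)

    def test_null_truth_runs_exchangeable(self, null_truth, scan):
        # no coupling change: per-run coupling slopes should not differ
        # systematically between runs
        from restdcm import ppi
        rng = np.random.default_rng(6)
        slopes = []
        for s in range(30):
            rest = synth.gen_rest_bold(null_truth, scan, rng,
                                       n_volumes=150)
            slopes.append(ppi.subject_factorial(rest, scan).slopes)
        slopes = np.array(slopes)
        f, p = stats.f_oneway(*[slopes[:, r] for r in range(4)])
        assert p > 0.005

    def test_consolidation_truth_orders_lagged_crosscov(self, truth, scan):
        # long simulation: coupling strength ordering across runs shows up
        # in the lagged cross-covariance (run2 > runs 3-4 > run1)
        rest = synth.gen_rest_bold(
            dataclasses.replace(truth, drift_sd_pct=0.0,
                                obs_noise_sd_pct=0.05),
            scan, seed=9, n_volumes=2760)
        xc = {}
        for r in (1, 2, 3, 4):
            sub = rest[rest["run"] == r]
            h = sub["hippocampus"].to_numpy()
            s = sub["striatum"].to_numpy()
            h = (h - h.mean()) / h.std()
            s = (s - s.mean()) / s.std()
            xc[r] = float(np.mean(h[:-1] * s[1:]) + np.mean(s[:-1] * h[1:]))
        assert xc[2] > max(xc[3], xc[4]) > min(xc[3], xc[4]) > xc[1]

    def test_drift_removed_by_highpass(self, truth, scan):
        from restdcm import glm
        rest = synth.gen_rest_bold(truth, scan, seed=12)
        run1 = rest[rest["run"] == 1]["hippocampus"].to_numpy()
        basis = glm.dct_highpass_basis(len(run1), scan.tr_s, 256.0)
        resid = glm.residualize(run1, basis)
        # high-pass removes a visible share of variance (drift present)
        assert resid.var() < run1.var()


class TestTaskGenerator:
    def test_five_runs_of_246_volumes(self, design, truth, scan):
        ie = 1.0 * np.exp(-0.1 * np.arange(1, 26)) + 0.6
        task = synth.gen_task_bold(design, truth, scan, 0, ie)
        assert sorted(task["run"].unique()) == [1, 2, 3, 4, 5]
        assert (task.groupby("run").size() == 246).all()

    def test_zero_gain_kills_modulation(self, design, scan):
        from restdcm import glm
        truth0 = GroundTruth(task_ie_gain=0.0)
        ie = 1.0 * np.exp(-0.1 * np.arange(1, 26)) + 0.6
        task = synth.gen_task_bold(design, truth0, scan, 0, ie,
                                   noise=False)
        dm = glm.build_task_design(design, scan, ie)
        y = np.concatenate([
            task[task["run"] == r].sort_values("volume")["hippocampus"]
            .to_numpy()[scan.discard_initial:]
            for r in range(1, 6)])
        fit = glm.fit_first_level(y, dm)
        assert fit.beta("ie_mod") == pytest.approx(0.0, abs=1e-10)


class TestCohort:
    def test_dataset_layout_and_sidecar_roundtrip(self, tmp_path, truth):
        out = synth.gen_cohort(2, tmp_path / "ds", master_seed=5,
                               rest_volumes=30, include_task=False)
        subs = sorted(out.glob("sub-*"))
        assert len(subs) == 2
        for sub in subs:
            assert (sub / "behavior.tsv").exists()
            assert (sub / "rest_bold.tsv").exists()
            sidecar = json.loads((sub / "ground_truth.json").read_text())
            assert sidecar["modulator_weights"]["adaptation"] == \
                [0.0, 1.0, 0.0, 1.0]
            assert sidecar["modulator_weights"]["consolidation"] == \
                [0.0, 2.0, 1.0, 1.0]
            # sidecar round-trips losslessly onto the ground-truth object
            sidecar.pop("subject")
            sidecar.pop("modulator_weights")
            assert GroundTruth.from_json(json.dumps(sidecar)) == truth

    def test_byte_identical_reruns(self, tmp_path):
        a = synth.gen_cohort(2, tmp_path / "a", master_seed=9,
                             rest_volumes=25, include_task=False)
        b = synth.gen_cohort(2, tmp_path / "b", master_seed=9,
                             rest_volumes=25, include_task=False)
        for fa in sorted(a.rglob("*")):
            if fa.is_file():
                fb = b / fa.relative_to(a)
                assert fb.read_bytes() == fa.read_bytes(), fa.name

    def test_zero_subjects_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            synth.gen_cohort(0, tmp_path / "x")

    def test_refuses_nonempty_directory(self, tmp_path):
        target = tmp_path / "ds"
        target.mkdir()
        (target / "junk.txt").write_text("hi")
        with pytest.raises(FileExistsError):
            synth.gen_cohort(1, target, rest_volumes=25,
                             include_task=False)
        # overwrite flag allows it
        synth.gen_cohort(1, target, rest_volumes=25, include_task=False,
                         overwrite=True)


class TestTruthMapping:
    def test_truth_spec_matches_change_type(self, truth, null_truth):
        assert synth.truth_spec(truth).name == "C-both"
        assert synth.truth_spec(null_truth).name == "null"

    def test_bilinear_parameters_propagate(self, truth):
        params = synth.truth_to_dcm_params(truth)
        assert params.b[("adaptation", "forward")] == truth.b_adapt
        assert params.b[("consolidation", "backward")] == truth.b_second

    def test_config_yaml_roundtrip(self, tmp_path):
        import yaml
        from restdcm.config import PipelineConfig
        cfg_dict = {"n_subjects": 4, "master_seed": 3,
                    "truth": {"b_adapt": 0.1,
                              "behavior": {"b_per_block": 0.2}}}
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump(cfg_dict))
        cfg = PipelineConfig.from_yaml(path)
        assert cfg.n_subjects == 4
        assert cfg.truth.b_adapt == 0.1
        assert cfg.truth.behavior.b_per_block == 0.2
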