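"""End-to-end replay on a miniature synthetic cohort.

Runs simulate -> behavior -> glm -> ppi -> dcm-fit -> bms into a dataset
directory and prints the report highlights.  Equivalent shell command:

    restdcm all --subjects 3 --seed 21 --out ./cohort
"""

import dataclasses
import tempfile

from restdcm import FitConfig, PipelineConfig, pipeline

config = dataclasses.replace(
    PipelineConfig(), n_subjects=3, master_seed=21,
    fit=FitConfig(n_starts=2))

with tempfile.TemporaryDirectory() as tmp:
    report = pipeline.run_all(config, f"{tmp}/cohort", rest_volumes=150)
    bms = report["bms"]["bms"]
    print(f"group GLM (IE modulator): t = "
          f"{report['glm']['group']['t']:.2f}, "
          f"p = {report['glm']['group']['p']:.3g}")
    print(f"group PPI interaction:    t = "
          f"{report['ppi']['group']['t']:.2f}, "
          f"p = {report['ppi']['group']['p']:.3g}")
    print(f"BMS winner: {bms['winner']} "
          f"(margin {bms['delta_to_runner_up']:.1f} nats)")
    tc = report["bms"]["coupling_timecourse"]
    for conn, st in tc.items():
        means = [f"{m:.3f}" for m in st["mean"]]
        print(f"coupling change ({conn}): {means}")
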