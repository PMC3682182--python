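"""Configuration objects for the synthetic cohort and the analysis pipeline.

All quantities carry explicit units in their field names or docstrings:
times in seconds, coupling rates in Hz (1/s), BOLD in percent signal change.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

MOTION = "motion"
CONTROL = "control"

#: Region labels for the two-node network. "hippocampus" is the learning
#: region (seed of the PPI analysis); "striatum" the coupled target region.
REGIONS = ("hippocampus", "striatum")


@dataclass(frozen=True)
class TaskDesign:
    """Block design of the perceptual learning session.

    Two interleaved conditions (coherent-motion discrimination and a static
    control task), 25 blocks of 16 trials each per condition, alternating
    block order with a counterbalanced starting condition.
    """

    n_blocks_per_condition: int = 25
    trials_per_block: int = 16
    conditions: tuple[str, str] = (MOTION, CONTROL)
    stimulus_duration_s: float = 0.3
    response_window_s: float = 1.5
    coherence: float = 0.20
    #: inter-trial gap (s) used to lay blocks on the scanner timeline
    iti_s: float = 0.2
    #: rest between blocks (s) on the scanner timeline
    inter_block_gap_s: float = 16.0
    #: lead-in fixation at the start of each task run (s)
    run_lead_in_s: float = 10.0

    @property
    def n_trials_total(self) -> int:
        return 2 * self.n_blocks_per_condition * self.trials_per_block

    @property
    def trial_duration_s(self) -> float:
        return self.stimulus_duration_s + self.response_window_s + self.iti_s

    @property
    def block_duration_s(self) -> float:
        return self.trials_per_block * self.trial_duration_s

    def validate(self) -> None:
        if self.n_blocks_per_condition < 1 or self.trials_per_block < 1:
            raise ValueError("block/trial counts must be positive")
        if len(self.conditions) != 2:
            raise ValueError("exactly two conditions required")
        if self.stimulus_duration_s <= 0 or self.response_window_s <= 0:
            raise ValueError("stimulus and response durations must be positive")
        if not 0 < self.coherence <= 1:
            raise ValueError("coherence must lie in (0, 1]")


@dataclass(frozen=True)
class ScanConfig:
    """EPI acquisition geometry shared by task and rest runs.

    Four rest runs are acquired as 2 days x 2 times (pre/post learning on
    day 1; the same pair on day 2), in the fixed order
    day1-pre, day1-post, day2-pre, day2-post.
    """

    tr_s: float = 2.176
    rest_volumes: int = 276
    task_volumes_per_run: int = 246
    discard_initial: int = 5
    n_rest_runs: int = 4
    n_task_runs: int = 5

    REST_RUN_LABELS = ("day1-pre", "day1-post", "day2-pre", "day2-post")

    def validate(self) -> None:
        if self.tr_s <= 0:
            raise ValueError("TR must be positive")
        for name in ("rest_volumes", "task_volumes_per_run", "n_rest_runs",
                     "n_task_runs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.discard_initial < 0:
            raise ValueError("discard_initial must be >= 0")
        if self.discard_initial >= min(self.rest_volumes,
                                       self.task_volumes_per_run):
            raise ValueError("discard_initial must be smaller than run length")

    @property
    def retained_rest_volumes(self) -> int:
        return self.rest_volumes - self.discard_initial


@dataclass(frozen=True)
class BehaviorTruth:
    """Generative parameters of the behavioral learning process.

    Reaction times on the motion task decay exponentially toward an
    asymptote; accuracy rises logistically toward an asymptote.  Inverse
    efficiency (mean RT / accuracy) then follows an approximately
    exponential learning curve with amplitude ``a`` and rate ``b``.
    """

    a_s: float = 0.8              # amplitude of the RT decay (s)
    b_per_block: float = 0.15     # learning rate (1/block)
    rt_asymptote_s: float = 0.55  # asymptotic motion-task RT (s)
    rt_sd_s: float = 0.15         # trial-to-trial RT scatter (s)
    accuracy_floor: float = 0.55
    accuracy_asymptote: float = 0.95
    accuracy_midpoint_block: float = 4.0
    accuracy_scale_blocks: float = 2.0
    control_accuracy: float = 0.995
    control_rt_s: float = 0.5
    miss_rate: float = 0.005      # omitted responses (count as errors, no RT)

    def validate(self) -> None:
        if self.b_per_block < 0:
            raise ValueError("learning rate b must be >= 0")
        if self.a_s < 0 or self.rt_asymptote_s <= 0 or self.control_rt_s <= 0:
            raise ValueError("RT parameters must be positive")
        if self.rt_sd_s < 0:
            raise ValueError("rt_sd must be >= 0")
        for p in (self.accuracy_floor, self.accuracy_asymptote,
                  self.control_accuracy):
            if not 0 < p <= 1:
                raise ValueError("accuracy parameters must lie in (0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """Generative ground truth of a synthetic subject.

    Neuronal couplings in Hz.  ``a_forward`` is hippocampus -> striatum,
    ``a_backward`` striatum -> hippocampus; self-connections are fixed at
    ``a_self``.  ``b_adapt``/``b_second`` are the per-connection bilinear
    parameters of the two modulators of the generative change pattern
    (default: the consolidation pattern on both connections).
    """

    a_forward: float = 0.12
    a_backward: float = 0.12
    a_self: float = -0.5
    #: generative change pattern: "null", "adaptation", "learning",
    #: "consolidation"
    change_type: str = "consolidation"
    #: connections carrying the change: subset of {"forward", "backward"}
    connections_modulated: tuple[str, ...] = ("forward", "backward")
    b_adapt: float = 0.06          # Hz, weights [0,1,0,1]
    b_second: float = 0.13         # Hz, learning [0,1,0,0] or consolidation [0,2,1,1]
    neural_noise_sd: float = 0.02  # a.u., sd of the endogenous neuronal drive
    neural_noise_half_life_s: float = 2.0  # AR(1) correlation half-life
    obs_noise_sd_pct: float = 0.20  # observation noise (percent BOLD)
    drift_sd_pct: float = 0.5      # sd of each low-frequency drift amplitude
    n_drift_components: int = 3
    task_evoked_amplitude: float = 0.4   # neuronal boxcar height (a.u.)
    task_ie_gain: float = 0.5      # neuronal amplitude change per s of fitted IE
    behavior: BehaviorTruth = field(default_factory=BehaviorTruth)

    def validate(self) -> None:
        if self.a_self >= 0:
            raise ValueError("self-connections must be negative")
        if self.neural_noise_sd < 0 or self.obs_noise_sd_pct < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.change_type not in ("null", "adaptation", "learning",
                                    "consolidation"):
            raise ValueError(f"unknown change_type {self.change_type!r}")
        bad = set(self.connections_modulated) - {"forward", "backward"}
        if bad:
            raise ValueError(f"unknown connections {sorted(bad)}")
        self.behavior.validate()

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        d["behavior"] = BehaviorTruth(**d["behavior"])
        d["connections_modulated"] = tuple(d["connections_modulated"])
        return cls(**d)


@dataclass(frozen=True)
class FitConfig:
    """Inversion settings for the state-space DCM."""

    prior_sd_coupling: float = 0.25   # Hz, zero-mean Gaussian on A off-diag
    prior_sd_bilinear: float = 0.25   # Hz, zero-mean Gaussian on b
    prior_sd_log_noise: float = 1.0   # on log noise SDs
    a_self: float = -0.5              # fixed self-decay (Hz), not estimated
    n_starts: int = 3                 # prior mean + jittered restarts
    start_jitter_sd: float = 0.1
    maxiter: int = 200
    highpass_cutoff_s: float = 256.0  # rest-data high-pass before fitting


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to replay the full analysis on synthetic data."""

    n_subjects: int = 11
    master_seed: int = 7
    design: TaskDesign = field(default_factory=TaskDesign)
    scan: ScanConfig = field(default_factory=ScanConfig)
    truth: GroundTruth = field(default_factory=GroundTruth)
    fit: FitConfig = field(default_factory=FitConfig)
    #: behavioral screening thresholds (flag-only by default)
    ceiling_accuracy: float = 0.97
    floor_accuracy: float = 0.60
    task_highpass_cutoff_s: float = 128.0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        self.design.validate()
        self.scan.validate()
        self.truth.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "design" in kwargs:
            kwargs["design"] = TaskDesign(**kwargs["design"])
        if "scan" in kwargs:
            kwargs["scan"] = ScanConfig(**kwargs["scan"])
        if "truth" in kwargs:
            t = dict(kwargs["truth"])
            if "behavior" in t:
                t["behavior"] = BehaviorTruth(**t["behavior"])
            if "connections_modulated" in t:
                t["connections_modulated"] = tuple(t["connections_modulated"])
            kwargs["truth"] = GroundTruth(**t)
        if "fit" in kwargs:
            kwargs["fit"] = FitConfig(**kwargs["fit"])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg
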