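"""The 10-model space of run-specific coupling changes, and fixed-effects BMS.

Each model specifies which extrinsic connections of the two-region network
(forward = hippocampus->striatum, backward = striatum->hippocampus) carry
bilinear modulation, and which temporal pattern the modulation follows over
the four rest runs (day1-pre, day1-post, day2-pre, day2-post):

* adaptation    — non-specific within-day change, run weights [0, 1, 0, 1]
* learning      — adaptation plus a day-1-only learning change [0, 1, 0, 0]
* consolidation — adaptation plus a learning change that persists at half
                  its level on day 2, weights [0, 2, 1, 1]

Learning and consolidation models therefore carry two bilinear parameters
per modulated connection; crossing the three change types with the three
connection patterns and adding the (shared) null model yields exactly ten
unique models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ADAPTATION_WEIGHTS = (0.0, 1.0, 0.0, 1.0)
LEARNING_WEIGHTS = (0.0, 1.0, 0.0, 0.0)
CONSOLIDATION_WEIGHTS = (0.0, 2.0, 1.0, 1.0)

CONNECTIONS = ("forward", "backward")
CHANGE_TYPES = ("adaptation", "learning", "consolidation")
CONNECTION_PATTERNS = (("forward",), ("backward",), ("forward", "backward"))

#: short labels used in reports, mirroring the usual bar-plot axis
_PATTERN_TAG = {("forward",): "fwd", ("backward",): "bwd",
                ("forward", "backward"): "both"}
_TYPE_TAG = {"adaptation": "A", "learning": "L", "consolidation": "C"}


def modulator_weights(change_type: str) -> list[tuple[str, tuple[float, ...]]]:
    """Run-weight rows for a change type.

    Adaptation has a single modulator; learning and consolidation add a
    second modulator on top of the adaptation row.
    """
    if change_type == "adaptation":
        return [("adaptation", ADAPTATION_WEIGHTS)]
    if change_type == "learning":
        return [("adaptation", ADAPTATION_WEIGHTS),
                ("learning", LEARNING_WEIGHTS)]
    if change_type == "consolidation":
        return [("adaptation", ADAPTATION_WEIGHTS),
                ("consolidation", CONSOLIDATION_WEIGHTS)]
    raise ValueError(f"unknown change type {change_type!r}")


@dataclass(frozen=True)
class DCMSpec:
    """One model: which connections are modulated, by which weight rows."""

    name: str
    connections_modulated: tuple[str, ...]
    modulators: tuple[tuple[str, tuple[float, ...]], ...]

    @property
    def n_bilinear(self) -> int:
        return len(self.connections_modulated) * len(self.modulators)

    def structural_key(self):
        return (frozenset(self.connections_modulated) if self.modulators
                else frozenset(), self.modulators)


def make_spec(change_type: str,
              connections: tuple[str, ...] = ("forward", "backward"),
              ) -> DCMSpec:
    """Build a single model spec by change type and connection pattern."""
    if change_type == "null":
        return DCMSpec(name="null", connections_modulated=(), modulators=())
    bad = set(connections) - set(CONNECTIONS)
    if bad:
        raise ValueError(f"unknown connections {sorted(bad)}")
    mods = tuple(modulator_weights(change_type))
    tag = f"{_TYPE_TAG[change_type]}-{_PATTERN_TAG[tuple(connections)]}"
    return DCMSpec(name=tag, connections_modulated=tuple(connections),
                   modulators=mods)


def build_model_space() -> list[DCMSpec]:
    """The full deduplicated model space: null + 3 change types x 3 patterns.

    The null model is identical for every connection pattern (no modulators),
    so only one copy is kept: 1 + 9 = 10 models, in a fixed order
    (null, A-fwd, A-bwd, A-both, L-fwd, L-bwd, L-both, C-fwd, C-bwd, C-both).
    """
    specs: list[DCMSpec] = [make_spec("null")]
    seen = {specs[0].structural_key()}
    for change_type in CHANGE_TYPES:
        for pattern in CONNECTION_PATTERNS:
            spec = make_spec(change_type, pattern)
            key = spec.structural_key()
            if key in seen:
                continue
            seen.add(key)
            specs.append(spec)
    assert len({s.name for s in specs}) == len(specs)
    return specs


def bayes_factor(delta_log_ev: float) -> float:
    """Bayes factor corresponding to a log-evidence difference (nats)."""
    return float(np.exp(delta_log_ev))


@dataclass(frozen=True)
class BMSResult:
    """Fixed-effects Bayesian model selection over subjects."""

    model_names: tuple[str, ...]
    log_ev: np.ndarray              # subjects x models, nats
    summed: np.ndarray              # per-model totals over subjects
    relative: np.ndarray            # summed minus the worst model's sum
    winner: str
    winners: tuple[str, ...]        # all argmax models (ties possible)
    per_subject_winner: tuple[str, ...]
    criterion_met: bool             # winner beats runner-up by >= 3 nats
    delta_to_runner_up: float

    def as_dict(self) -> dict:
        return {
            "model_names": list(self.model_names),
            "summed": self.summed.tolist(),
            "relative": self.relative.tolist(),
            "winner": self.winner,
            "winners": list(self.winners),
            "per_subject_winner": list(self.per_subject_winner),
            "criterion_met": self.criterion_met,
            "delta_to_runner_up": self.delta_to_runner_up,
        }


def fixed_effects_bms(log_ev: np.ndarray,
                      model_names: list[str] | tuple[str, ...],
                      criterion_nats: float = 3.0) -> BMSResult:
    """Sum log evidences over subjects and select the group-level winner.

    ``log_ev`` is subjects x models.  Relative evidences subtract the worst
    model's summed evidence, so the worst model sits at exactly zero.  The
    selection criterion requires the winner to exceed the runner-up by at
    least ``criterion_nats`` (default 3, a Bayes factor of about 20).  Exact
    ties at the top are reported and the criterion is not met.
    """
    log_ev = np.asarray(log_ev, dtype=float)
    if log_ev.ndim != 2 or log_ev.shape[0] < 1:
        raise ValueError("log_ev must be a subjects x models matrix")
    if log_ev.shape[1] != len(model_names):
        raise ValueError("model_names length must match columns of log_ev")
    if not np.all(np.isfinite(log_ev)):
        raise ValueError("log evidences must be finite")

    summed = log_ev.sum(axis=0)
    relative = summed - summed.min()
    order = np.argsort(summed)[::-1]
    best, second = order[0], order[1] if len(order) > 1 else order[0]
    delta = float(summed[best] - summed[second])
    winners = tuple(model_names[j] for j in np.flatnonzero(
        summed == summed[best]))
    tie = len(winners) > 1
    per_subject = tuple(model_names[int(j)] for j in log_ev.argmax(axis=1))
    return BMSResult(
        model_names=tuple(model_names),
        log_ev=log_ev,
        summed=summed,
        relative=relative,
        winner=model_names[int(best)],
        winners=winners,
        per_subject_winner=per_subject,
        criterion_met=(not tie) and delta >= criterion_nats,
        delta_to_runner_up=delta,
    )
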