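"""Psychophysiological-interaction screening of run-dependent coupling.

For each rest run, the coupling between a seed region and a target region
is summarized by the OLS regression slope of the target on the seed after
removing nuisance components (constant plus 256-s discrete-cosine drift
terms) from both series.  The four run slopes form a 2x2 day-by-time
factorial: the interaction contrast detects coupling changes that are
larger on day 1 than on day 2 — the signature of a learning-then-
consolidation process — while pure within-day adaptation ([0,1,0,1])
cancels out of the interaction by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import REGIONS, ScanConfig
from .glm import dct_highpass_basis, group_ttest, residualize

__all__ = [
    "FactorialCoupling",
    "run_coupling_slope",
    "factorial_contrasts",
    "subject_factorial",
    "group_interaction_test",
]


@dataclass(frozen=True)
class FactorialCoupling:
    """Run-wise coupling slopes and their 2x2 factorial contrasts.

    Sign conventions: main_day is (day 1) - (day 2); main_time is
    (pre) - (post); the interaction is the day-1 pre-to-post change minus
    the day-2 pre-to-post change.  All tests downstream are two-sided, so
    the conventions only fix reporting signs.
    """

    slopes: tuple[float, float, float, float]
    main_day: float
    main_time: float
    interaction: float


def run_coupling_slope(seed: np.ndarray, target: np.ndarray,
                       nuisance: np.ndarray | None = None) -> float:
    """OLS slope of target on seed after partialling nuisance from both.

    ``nuisance`` columns should include the drift basis; the constant is
    always removed.  Raises if the seed has no variance left after
    filtering.
    """
    seed = np.asarray(seed, dtype=float)
    target = np.asarray(target, dtype=float)
    if seed.shape != target.shape or seed.ndim != 1:
        raise ValueError("seed and target must be equal-length 1-D series")
    nuis = nuisance if nuisance is not None else np.empty((len(seed), 0))
    s = residualize(seed, nuis)
    t = residualize(target, nuis)
    denom = float(s @ s)
    if denom <= 1e-12 * len(s):
        raise ValueError("seed series has (near-)zero variance "
                         "after nuisance removal")
    return float(s @ t / denom)


def factorial_contrasts(slopes) -> FactorialCoupling:
    """2x2 day-by-time contrasts of the four run slopes.

    Runs are ordered (day1-pre, day1-post, day2-pre, day2-post):
    main_day = (b1+b2)-(b3+b4); main_time = (b1+b3)-(b2+b4);
    interaction = (b2-b1)-(b4-b3).
    """
    b = np.asarray(slopes, dtype=float)
    if b.shape != (4,) or not np.all(np.isfinite(b)):
        raise ValueError("exactly 4 finite run slopes required")
    return FactorialCoupling(
        slopes=tuple(float(x) for x in b),
        main_day=float((b[0] + b[1]) - (b[2] + b[3])),
        main_time=float((b[0] + b[2]) - (b[1] + b[3])),
        interaction=float((b[1] - b[0]) - (b[3] - b[2])),
    )


def subject_factorial(rest: pd.DataFrame, scan: ScanConfig,
                      seed_region: str = REGIONS[0],
                      target_region: str = REGIONS[1],
                      highpass_cutoff_s: float = 256.0) -> FactorialCoupling:
    """Per-run slopes and factorial contrasts for one subject's rest data.

    Runs are filtered independently (separate acquisitions); the first
    volumes of each run are dropped per the scan configuration.
    """
    slopes = []
    for r in sorted(rest["run"].unique()):
        sub = rest[rest["run"] == r].sort_values("volume")
        s = sub[seed_region].to_numpy()[scan.discard_initial:]
        t = sub[target_region].to_numpy()[scan.discard_initial:]
        basis = dct_highpass_basis(len(s), scan.tr_s, highpass_cutoff_s)
        slopes.append(run_coupling_slope(s, t, basis))
    if len(slopes) != 4:
        raise ValueError(f"expected 4 rest runs, found {len(slopes)}")
    return factorial_contrasts(slopes)


def group_interaction_test(interactions) -> dict:
    """One-sample t-test of per-subject interaction contrasts against 0."""
    return group_ttest(np.asarray(interactions, dtype=float))
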