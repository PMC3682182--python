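"""Behavioral analysis: inverse efficiency and the exponential learning curve.

Performance is summarized per block by inverse efficiency,
``IE = mean reaction time / accuracy`` (seconds; lower is better), after a
single pass of per-block outlier exclusion (trials deviating from the block
mean RT by more than three sample standard deviations).  The 25 motion-task
block IEs are then fitted with a two-parameter exponential

    y = a * exp(-b * x),  x = 1..n_blocks

whose fitted values serve downstream as the parametric modulator of the
task GLM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .config import MOTION

__all__ = [
    "LearningCurve",
    "exclude_rt_outliers",
    "block_inverse_efficiency",
    "fit_learning_curve",
    "screen_performance",
]


@dataclass(frozen=True)
class LearningCurve:
    ie_raw: np.ndarray       # per-block inverse efficiency (s)
    ie_fitted: np.ndarray    # fitted exponential values (s)
    a: float                 # amplitude (s)
    b: float                 # learning rate (1/block)
    rss: float               # residual sum of squares
    n_blocks: int
    excluded_trials: int
    x_origin: int = 1        # block index of the first block in the fit

    def __post_init__(self):
        if len(self.ie_raw) != len(self.ie_fitted) or \
                len(self.ie_raw) != self.n_blocks:
            raise ValueError("curve length mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "block": np.arange(self.x_origin, self.x_origin + self.n_blocks),
            "ie_raw": self.ie_raw,
            "ie_fitted": self.ie_fitted,
        })


def exclude_rt_outliers(trials: pd.DataFrame, n_sd: float = 3.0
                        ) -> tuple[pd.DataFrame, int]:
    """Remove responded trials deviating > ``n_sd`` SDs from their block mean.

    A single pass per (condition, block) with the sample SD (n-1
    denominator).  Omitted responses (NaN RT) are untouched; they carry no
    RT and count as errors in the accuracy computation.  Returns the
    filtered table and the number of excluded trials.
    """
    if trials.empty:
        raise ValueError("empty trial table")
    responded = trials["rt_s"].notna()
    grp = trials.loc[responded].groupby(["condition", "block"])["rt_s"]
    mean = grp.transform("mean")
    sd = grp.transform("std")  # ddof=1; NaN for singleton blocks
    dev = (trials.loc[responded, "rt_s"] - mean).abs()
    # a block with zero RT variance cannot flag anything (0 > 3*0 is False)
    out = dev > n_sd * sd.fillna(np.inf)
    keep = trials.index.difference(out.index[out])
    return trials.loc[keep], int(out.sum())


def block_inverse_efficiency(trials: pd.DataFrame,
                             condition: str = MOTION) -> pd.Series:
    """Per-block inverse efficiency, IE = mean RT / accuracy (seconds).

    Accuracy is the fraction of correct trials among all trials of the
    block (omissions count as errors); the mean RT averages responded
    trials only.  Raises if any block has zero accuracy, where IE is
    undefined.
    """
    sub = trials[trials["condition"] == condition]
    if sub.empty:
        raise ValueError(f"no trials for condition {condition!r}")

    def _ie(block: pd.DataFrame) -> float:
        acc = block["correct"].mean()
        if acc == 0:
            raise ValueError(
                f"block {block.name}: zero accuracy, IE undefined")
        return block["rt_s"].mean() / acc

    ie = sub.groupby("block", sort=True).apply(_ie, include_groups=False)
    ie.name = "ie_s"
    return ie


def _exp_model(params: np.ndarray, x: np.ndarray) -> np.ndarray:
    a, b = params
    return a * np.exp(-b * x)


def fit_learning_curve(ie: np.ndarray | pd.Series,
                       excluded_trials: int = 0,
                       x_origin: int = 1,
                       b_starts: tuple[float, ...] = (0.01, 0.05, 0.2),
                       ) -> LearningCurve:
    """Nonlinear least-squares fit of y = a*exp(-b*x) to per-block IE.

    Block index x starts at ``x_origin`` (default 1).  Multi-start over
    initial learning rates, keeping the lowest residual sum of squares;
    the amplitude is initialized at the first IE value.  A negative fitted
    b (performance worsening) is permitted.
    """
    y = np.asarray(ie, dtype=float)
    if y.ndim != 1 or len(y) < 3:
        raise ValueError("need at least 3 blocks to fit a learning curve")
    if np.any(y <= 0) or not np.all(np.isfinite(y)):
        raise ValueError("IE values must be positive and finite")
    x = np.arange(x_origin, x_origin + len(y), dtype=float)

    best = None
    for b0 in b_starts:
        res = least_squares(lambda p: _exp_model(p, x) - y,
                            x0=[y[0] * np.exp(b0 * x[0]), b0],
                            method="lm", max_nfev=2000)
        if not res.success:
            continue
        rss = float(2 * res.cost)
        if best is None or rss < best[0]:
            best = (rss, res)
    if best is None:
        raise RuntimeError("learning-curve fit failed to converge "
                           f"(last status: {res.status})")
    rss, res = best
    a, b = res.x
    fitted = _exp_model(res.x, x)
    return LearningCurve(ie_raw=y, ie_fitted=fitted, a=float(a), b=float(b),
                         rss=rss, n_blocks=len(y),
                         excluded_trials=excluded_trials, x_origin=x_origin)


def analyze_subject(trials: pd.DataFrame, condition: str = MOTION,
                    ) -> LearningCurve:
    """Outlier exclusion -> block IE -> exponential fit, in one call."""
    kept, n_excl = exclude_rt_outliers(trials)
    ie = block_inverse_efficiency(kept, condition=condition)
    return fit_learning_curve(ie.to_numpy(), excluded_trials=n_excl)


def screen_performance(trials: pd.DataFrame,
                       ceiling: float = 0.97,
                       floor: float = 0.60) -> dict:
    """Flag ceiling / floor performers on the motion task.

    Mirrors the participant screening of the original study design:
    subjects at ceiling from the start show no learning-related variance,
    and floor performers never learned the task.  This only flags; exclusion
    is the pipeline's decision.
    """
    motion = trials[trials["condition"] == MOTION]
    acc = motion["correct"].mean()
    early = motion[motion["block"] <= motion["block"].min() + 4]
    return {
        "accuracy_overall": float(acc),
        "accuracy_early": float(early["correct"].mean()),
        "at_ceiling": bool(early["correct"].mean() >= ceiling),
        "at_floor": bool(acc <= floor),
    }
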