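"""Report figures: learning curve, relative log evidences, coupling profile."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402


def plot_learning_curves(curves: dict[str, dict], path: str | Path) -> None:
    """Per-subject raw block IE with the cohort-mean fitted curve."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    raws, fits = [], []
    for frame in curves.values():
        raws.append(np.asarray(frame["ie_raw"]))
        fits.append(np.asarray(frame["ie_fitted"]))
    raw = np.mean(raws, axis=0)
    sem = np.std(raws, axis=0, ddof=1) / np.sqrt(len(raws)) \
        if len(raws) > 1 else np.zeros_like(raw)
    x = np.arange(1, len(raw) + 1)
    ax.errorbar(x, raw, yerr=sem, fmt="o", ms=4, capsize=2,
                label="block IE (mean ± SEM)")
    ax.plot(x, np.mean(fits, axis=0), "-", label="fitted a·exp(−b·x)")
    ax.set_xlabel("block")
    ax.set_ylabel("inverse efficiency (s)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_relative_evidence(model_names, relative, path: str | Path) -> None:
    """Summed relative log evidence per model (worst model at zero)."""
    fig, ax = plt.subplots(figsize=(6, 3.5))
    idx = np.arange(len(model_names))
    colors = ["crimson" if r == max(relative) else "steelblue"
              for r in relative]
    ax.bar(idx, relative, color=colors)
    ax.set_xticks(idx, model_names, rotation=45, ha="right")
    ax.set_ylabel("relative log evidence (nats)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_coupling_timecourse(timecourse: dict, path: str | Path) -> None:
    """Run-wise coupling change (relative to rest run 1), mean ± SEM."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    runs = np.arange(1, 5)
    for conn, stats_ in timecourse.items():
        ax.errorbar(runs, stats_["mean"], yerr=stats_["sem"], marker="o",
                    capsize=3, label=conn)
    ax.set_xticks(runs, ["rest 1", "rest 2", "rest 3", "rest 4"])
    ax.set_ylabel("coupling change (Hz)")
    ax.axhline(0.0, color="gray", lw=0.5)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
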