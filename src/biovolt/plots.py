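"""Presentation helpers: trace rendering and per-condition boxplots.

These figures mirror the usual view of a day-course experiment — stacked
representative traces and boxplots of per-minute rate and amplitude — and are
purely cosmetic; nothing in the analysis depends on them.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .types import VoltageTrace


def plot_traces(traces: list[VoltageTrace], max_seconds: float = 60.0,
                path=None):
    """Stacked voltage traces, one axis row per condition."""
    fig, axes = plt.subplots(len(traces), 1, sharex=True,
                             figsize=(8, 1.6 * len(traces)), squeeze=False)
    for ax, trace in zip(axes.ravel(), traces):
        n = min(trace.n_samples, int(max_seconds * trace.fs_hz))
        ax.plot(trace.times[:n], trace.samples[:n], lw=0.4, color="k")
        ax.set_ylabel(f"{trace.meta.condition}\n(µV)", fontsize=8)
    axes.ravel()[-1].set_xlabel("time (s)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_condition_boxes(per_condition_counts: dict, per_condition_amps: dict,
                         path=None):
    """Boxplots of per-minute rate (top) and amplitude (bottom) per condition."""
    labels = list(per_condition_counts)
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(8, 6), sharex=True)
    ax1.boxplot([np.asarray(per_condition_counts[c]) for c in labels],
                tick_labels=labels)
    ax1.set_ylabel("events / min")
    ax2.boxplot([np.asarray(per_condition_amps[c]) for c in labels],
                tick_labels=labels)
    ax2.set_ylabel("amplitude (µV)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
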