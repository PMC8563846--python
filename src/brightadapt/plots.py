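"""Publication-style figures for condition summaries and model evaluation."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .analysis import PREV_BRIGHT, PREV_DULL, EvaluationResult, summaries_to_frame


def plot_condition_summaries(summaries, ax=None):
    """p(bright) vs coloration level, one line per previous-trial class."""
    frame = summaries if isinstance(summaries, pd.DataFrame) else summaries_to_frame(summaries)
    if ax is None:
        _, ax = plt.subplots()
    for (ctx, prev), sub in frame.groupby(["context", "prev_class"]):
        sub = sub[sub["n_trials"] > 0].sort_values("level")
        color = "tab:blue" if prev == PREV_DULL else "tab:orange"
        ls = {"shift_plus_1": "--", "openear_context": "--"}.get(ctx, "-")
        yerr = None
        if "ci_lo" in sub:
            yerr = np.vstack([sub["p_bright"] - sub["ci_lo"], sub["ci_hi"] - sub["p_bright"]])
        ax.errorbar(sub["level"], sub["p_bright"], yerr=yerr, color=color, ls=ls,
                    marker="o", ms=4, capsize=2, label=f"{ctx}, prev {prev}")
    ax.set_xlabel("coloration level")
    ax.set_ylabel("p(bright)")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=7)
    return ax


def plot_rms_vs_integration_length(results: list[EvaluationResult], ax=None):
    """RMS error against integration length L for each model type."""
    if ax is None:
        _, ax = plt.subplots()
    for res in results:
        Ls = sorted(res.rms_by_L)
        ax.plot(Ls, [res.rms_by_L[L] for L in Ls], marker="o", label=res.model_type)
    ax.set_xscale("log", base=2)
    ax.set_xlabel("integration length L (s)")
    ax.set_ylabel("pooled RMS error")
    ax.legend()
    return ax


def plot_response_trajectory(trajectory: pd.DataFrame, ax=None):
    """Smoothed p(bright) per trial index on a logarithmic time axis."""
    if ax is None:
        _, ax = plt.subplots()
    for ctx, sub in trajectory.groupby("context"):
        ax.plot(sub["index_n"], sub["p_bright"], label=ctx)
    ax.set_xscale("log")
    ax.set_xlabel("trial index")
    ax.set_ylabel("p(bright), smoothed")
    ax.set_ylim(0, 1)
    ax.legend()
    return ax
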