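"""Figure builders: tolerance time series, effect densities, SRM intervals.

Figures are derived artifacts; nothing downstream depends on them.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_tolerance_series(summary: pd.DataFrame, ax=None):
    """Credible-interval time series of maximal tolerance per group."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4.5))
    groups = sorted(summary["group"].unique())
    jitter = np.linspace(-0.18, 0.18, len(groups))
    for off, g in zip(jitter, groups):
        sub = summary[summary["group"] == g].sort_values("year")
        x = sub["year"].to_numpy() + off
        ax.errorbar(
            x,
            sub["median"],
            yerr=[sub["median"] - sub["lower"], sub["upper"] - sub["median"]],
            fmt="o",
            capsize=2,
            label=str(g),
        )
    ax.set_xlabel("year")
    ax.set_ylabel("maximal cofeeding tolerance")
    ax.set_ylim(0, 1)
    ax.legend(title="group", fontsize=8)
    return ax.figure


def plot_effect_intervals(effects: pd.DataFrame, ax=None):
    """Covariate-effect medians and intervals, grouped per covariate."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 0.4 * len(effects) + 1.5))
    if "model" in effects.columns:
        labels = [f"{r.covariate} [{r.scope}, {r.model}]" for r in effects.itertuples()]
    else:
        labels = [f"{r.covariate} [{r.scope}]" for r in effects.itertuples()]
    y = np.arange(len(effects))[::-1]
    ax.errorbar(
        effects["median"],
        y,
        xerr=[effects["median"] - effects["lower"], effects["upper"] - effects["median"]],
        fmt="o",
        capsize=2,
    )
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_yticks(y)
    ax.set_yticklabels(labels, fontsize=8)
    ax.set_xlabel("effect on logit maximal tolerance")
    return ax.figure


def plot_srm_intervals(summary: pd.DataFrame, ax=None):
    """Fig-4-style clustered interval plot of SRM category effects."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 0.35 * len(summary) + 1.5))
    y = np.arange(len(summary))[::-1]
    colors = {"presence": "tab:blue", "coresidence": "tab:red"}
    for effect, sub in summary.groupby("effect"):
        idx = sub.index.to_numpy()
        ax.errorbar(
            sub["median"],
            y[idx],
            xerr=[sub["median"] - sub["lower"], sub["upper"] - sub["median"]],
            fmt="o",
            capsize=2,
            color=colors.get(effect, "k"),
            label=effect,
        )
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_yticks(y)
    ax.set_yticklabels(summary["category"], fontsize=7)
    ax.set_xlabel("change in log-odds")
    ax.legend(fontsize=8)
    return ax.figure
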