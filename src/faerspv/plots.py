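"""Figure outputs: forest plot, onset CDF and stacked outcome bars."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Union

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .descriptives import CohortSummary, OnsetSummary


def forest_plot(signals: pd.DataFrame, path: Union[str, Path]) -> None:
    frame = signals[signals["estimable"]].reset_index(drop=True)
    fig, ax = plt.subplots(figsize=(6, 0.6 * max(len(frame), 2) + 1.5))
    y = np.arange(len(frame))[::-1]
    ax.errorbar(
        frame["ror"],
        y,
        xerr=[frame["ror"] - frame["ci_low"], frame["ci_high"] - frame["ror"]],
        fmt="s",
        color="black",
        ecolor="black",
        capsize=3,
    )
    ax.axvline(1.0, color="grey", linestyle="--", linewidth=1)
    ax.set_yticks(y)
    ax.set_yticklabels(
        [
            f"{g} (n={n})"
            for g, n in zip(frame["group"], frame["n_cases"])
        ]
    )
    ax.set_xscale("log")
    ax.set_xlabel("Reporting odds ratio (95% CI)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def onset_cdf_plot(
    summaries: Mapping[str, OnsetSummary], path: Union[str, Path]
) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, s in summaries.items():
        if s.empty:
            continue
        days = [0.0] + [d for d, _ in s.cumulative_curve]
        fracs = [0.0] + [f for _, f in s.cumulative_curve]
        ax.step(days, fracs, where="post", label=f"{label} (n={s.n_used})")
    ax.set_xlabel("Days to onset")
    ax.set_ylabel("Cumulative fraction")
    ax.set_ylim(0, 1.02)
    if ax.get_legend_handles_labels()[0]:
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def outcome_bars(summary: CohortSummary, path: Union[str, Path]) -> None:
    counts = summary.counts["outcomes"]
    groups = [c for c in counts.columns if c != "Overall"]
    fig, ax = plt.subplots(figsize=(7, 4))
    bottom = np.zeros(len(groups))
    for outcome in counts.index:
        values = counts.loc[outcome, groups].to_numpy(dtype=float)
        ax.bar(groups, values, bottom=bottom, label=outcome)
        bottom += values
    ax.set_ylabel("Reports")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
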