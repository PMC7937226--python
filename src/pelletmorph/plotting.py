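"""Minimal plotting helpers for time-course summaries and comparisons."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless; callers can switch backends beforehand

import matplotlib.pyplot as plt
import pandas as pd

from .morphometrics import ComparisonResult


def plot_timeseries(summary: pd.DataFrame, ax=None):
    """Median projected area vs. time with an IQR band per sample."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for sample_id, grp in summary.groupby("sample_id"):
        grp = grp.sort_values("time_h")
        ax.plot(grp["time_h"], grp["median_um2"], marker="o", label=str(sample_id))
        ax.fill_between(grp["time_h"], grp["q1_um2"], grp["q3_um2"], alpha=0.25)
    ax.set_xlabel("cultivation time (h)")
    ax.set_ylabel("projected biomass area (µm²)")
    ax.legend(title="sample")
    return ax


def plot_quantile_comparison(result: ComparisonResult, ax=None,
                             label_a: str = "A", label_b: str = "B"):
    """Quantile–quantile plot of two area distributions with the identity line."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    qa = [v for _, v, _ in result.paired_quantiles]
    qb = [v for _, _, v in result.paired_quantiles]
    lim = (min(qa + qb), max(qa + qb))
    ax.plot(lim, lim, "k--", lw=1, label="identity")
    ax.plot(qa, qb, "o-")
    ax.set_xlabel(f"{label_a} quantiles (µm²)")
    ax.set_ylabel(f"{label_b} quantiles (µm²)")
    ax.legend()
    return ax
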