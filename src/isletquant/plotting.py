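"""Plot helpers for the infiltration analysis and the threshold classifier.

All functions take/return matplotlib Axes and never call ``show``; figure
styling is left to the caller.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .metrics import DonorSummary, summaries_frame


def plot_roc(results, ax=None):
    """ROC curve of a fitted :class:`~isletquant.rule.ThresholdRuleResults`."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    curve = results.roc_curve().sort_values("specificity")
    ax.plot(1 - curve["specificity"], curve["sensitivity"], drawstyle="steps-post")
    ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(
        f"AUC = {results.auc:.3f} "
        f"(95% CI {results.auc_ci[0]:.3f}, {results.auc_ci[1]:.3f})"
    )
    return ax

def plot_threshold_distribution(dist: pd.DataFrame, ax=None):
    """Box plots of the Monte-Carlo optimal-threshold distribution per islet
    count (long frame from ``threshold_distribution``)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ns = sorted(dist["n_islets"].unique())
    data = [dist.loc[dist["n_islets"] == n, "threshold"].dropna() for n in ns]
    ax.boxplot(data, tick_labels=[str(n) for n in ns], showfliers=False)
    ax.set_xlabel("number of randomly selected islets")
    ax.set_ylabel("optimal threshold (CD3+ cells/mm$^2$)")
    return ax


def category_proportion_data(
    summaries: list[DonorSummary], marker: str = "cd3", n_circles: int = 100
) -> pd.DataFrame:
    """Discretised infiltration-category proportions per group.

    For each group, the mean percentages of NONE/LOW/HIGH islets are
    rescaled onto ``n_circles`` units (the one-circle-per-islet illustration
    convention); largest-remainder rounding keeps the total exact.
    """
    df = summaries_frame(summaries)
    rows = []
    for group, sub in df.groupby("group", sort=False):
        low = float(sub[f"pct_low_{marker}"].mean())
        high = float(sub[f"pct_high_{marker}"].mean())
        none = 100.0 - low - high
        raw = np.array([none, low, high]) * n_circles / 100.0
        base = np.floor(raw).astype(int)
        rem = n_circles - base.sum()
        order = np.argsort(-(raw - base))
        base[order[:rem]] += 1
        for cat, pct, n in zip(("NONE", "LOW", "HIGH"), (none, low, high), base):
            rows.append({"group": group, "category": cat,
                         "percent": pct, "n_circles": int(n)})
    return pd.DataFrame(rows)
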