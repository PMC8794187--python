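"""Diagnostic plots: accuracy-by-length and reliability-growth curves.

matplotlib is imported lazily so the core package has no hard plotting
dependency.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def plot_accuracy_by_length(result: dict, path) -> None:
    """Plot per-length accuracies (with binomial error bars) and the two
    descriptive regression lines (all lengths; lengths 2-7 only)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table: pd.DataFrame = result["table"]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.errorbar(
        table["length"], table["accuracy"], yerr=1.96 * table["se"],
        fmt="ko-", capsize=3, label="observed accuracy",
    )
    xs = np.linspace(table["length"].min(), table["length"].max(), 50)
    fit = result["fits"]["all_lengths"]
    ax.plot(xs, fit["intercept"] + fit["slope"] * xs, "b-", label="fit, all lengths")
    if "lengths_2_7" in result["fits"]:
        fit27 = result["fits"]["lengths_2_7"]
        xs27 = np.linspace(2, 7, 50)
        ax.plot(xs27, fit27["intercept"] + fit27["slope"] * xs27, "r-",
                label="fit, lengths 2-7")
    ax.set_xlabel("sequence length")
    ax.set_ylabel("proportion correct")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_reliability_curves(curves: pd.DataFrame, path) -> None:
    """Plot mean SEM and marginal reliability against test length."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    axes[0].plot(curves["n_trials"], curves["mean_sem"], "ko-")
    axes[0].set_xlabel("number of trials")
    axes[0].set_ylabel("mean SEM")
    axes[1].plot(curves["n_trials"], curves["marginal_reliability"], "ko-")
    axes[1].set_xlabel("number of trials")
    axes[1].set_ylabel("marginal reliability")
    axes[1].set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
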