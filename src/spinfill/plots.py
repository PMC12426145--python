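"""Postanticipation lag-CRP curve plots (means ± SEM by lag)."""

from __future__ import annotations

import pandas as pd

__all__ = ["plot_crp_curves"]


def plot_crp_curves(group_curves: pd.DataFrame, path=None):
    """Plot group lag-CRP curves, one panel per repeat policy.

    ``group_curves`` is the output of :func:`spinfill.crp.aggregate_crp`
    (possibly concatenated over list types and repeat policies).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    policies = sorted(group_curves["repeat_policy"].unique())
    fig, axes = plt.subplots(
        1, len(policies), figsize=(5.0 * len(policies), 4.0),
        sharey=True, squeeze=False,
    )
    for ax, policy in zip(axes[0], policies):
        sub = group_curves[group_curves["repeat_policy"] == policy]
        for list_type, curve in sub.groupby("list_type"):
            curve = curve.sort_values("lag")
            ax.errorbar(
                curve["lag"], curve["mean_crp"], yerr=curve["sem_crp"],
                marker="o", capsize=3, label=list_type,
            )
        ax.set_title(f"repeats {policy}")
        ax.set_xlabel("lag")
        ax.axhline(0, color="0.8", lw=0.5)
    axes[0][0].set_ylabel("conditional response probability")
    axes[0][0].legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
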