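"""Depth-profile plots: group mean +/- SEM and windowed correlation."""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def plot_depth_profiles(
    profiles: pd.DataFrame,
    correlation: pd.DataFrame,
    path: str | Path,
    score_col: str = "ami",
    significance: float = 0.001,
) -> None:
    """Plot one score's depth profile with the pooled windowed correlation.

    Top panel: per-group windowed mean +/- SEM along the normalized
    ventral (0) to dorsal (100) axis.  Bottom panel: Spearman's rho between
    AMI and AIS per window, with windows significant at ``significance``
    shaded.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(7, 6))
    for group, g in profiles.groupby("group", sort=True):
        g = g.sort_values("window_center")
        ax1.plot(g["window_center"], g[f"{score_col}_mean"], label=str(group))
        ax1.fill_between(
            g["window_center"],
            g[f"{score_col}_mean"] - g[f"{score_col}_sem"],
            g[f"{score_col}_mean"] + g[f"{score_col}_sem"],
            alpha=0.25,
        )
    ax1.set_ylabel(f"{score_col.upper()} (mean ± SEM)")
    ax1.legend(frameon=False)

    corr = correlation.sort_values("window_center")
    ax2.plot(corr["window_center"], corr["rho"], color="black")
    sig = corr["usable"] & (corr["p_value"] < significance)
    ax2.fill_between(
        corr["window_center"], -1, 1, where=sig, color="gold", alpha=0.3,
        label=f"p < {significance:g}",
    )
    ax2.set_ylim(-1, 1)
    ax2.set_xlabel("normalized depth (0 = ventral, 100 = dorsal)")
    ax2.set_ylabel("Spearman ρ (AMI vs AIS)")
    ax2.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
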