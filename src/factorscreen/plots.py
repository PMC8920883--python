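"""Static plot writers: funnel, outcome comparison, importance bars.

All figures are plain matplotlib PNGs; plotting is optional everywhere
(flag-gated in the CLI) so headless runs need no graphics output.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .importance import ImportanceResult
from .screening import SubgroupScreener


def funnel_plot(screener: SubgroupScreener, outcome: str, path: str | Path) -> None:
    """Subgroup size vs. truncated statistic, overall value as reference line."""
    df, ref = screener.funnel_data(outcome)
    fig, ax = plt.subplots(figsize=(7, 5))
    for depth, sub in df.groupby("depth"):
        ax.scatter(
            sub["n"], sub["display_point"],
            s=12, alpha=0.35 if depth > 1 else 0.8, label=f"depth {depth}",
        )
    ax.axhline(ref, color="tab:blue", lw=1.5, label="overall")
    if screener.statistic == "odds_ratio":
        ax.set_yscale("log")
        ax.set_ylabel("odds ratio (display-truncated)")
    else:
        ax.set_ylabel("proportion")
    ax.set_xscale("log")
    ax.set_xlabel("subgroup size n")
    ax.set_title(f"Subgroup screen: {outcome}")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def compare_plot(
    screener: SubgroupScreener, outcome_x: str, outcome_y: str, path: str | Path
) -> None:
    """Bubble-style comparison of the same subgroups under two outcomes."""
    df, refs = screener.compare_outcomes(outcome_x, outcome_y)
    ok = ~df["incomplete"]
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.scatter(
        df.loc[ok, "display_point_x"], df.loc[ok, "display_point_y"],
        s=np.sqrt(df.loc[ok, "n_x"].clip(lower=1)), alpha=0.3,
    )
    ax.axvline(refs[outcome_x], color="tab:blue", lw=1)
    ax.axhline(refs[outcome_y], color="tab:blue", lw=1)
    ax.set_xlabel(outcome_x)
    ax.set_ylabel(outcome_y)
    ax.set_title("Subgroup comparison")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def importance_plot(result: ImportanceResult, path: str | Path) -> None:
    """VIMP bars (negative = presumed noise) and minimal depth with threshold."""
    vimp = result.vimp.sort_values()
    md = result.minimal_depth.sort_values(ascending=False)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, max(3, 0.25 * len(vimp) + 1)))
    colors = ["tab:red" if v < 0 else "tab:blue" for v in vimp]
    ax1.barh(vimp.index, vimp.values, color=colors)
    ax1.set_xlabel("VIMP (OOB error increase)")
    ax1.axvline(0, color="k", lw=0.8)
    ax2.barh(md.index, md.values, color="tab:gray")
    ax2.axvline(result.minimal_depth_threshold, color="k", ls="--", lw=1,
                label="selection threshold")
    ax2.set_xlabel("mean minimal depth")
    ax2.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
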