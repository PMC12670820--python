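"""Violin and scatter figures for the analysis report.

Figures are best-effort: any rendering failure is logged and skipped, never
fatal to the pipeline.  Violin panels show the per-group distribution with
a white median dot and an IQR bar; significant comparisons are annotated
with '*' (p < 0.05) or '**' (p < 0.01).  Correlation panels show the
scatter against NRS with the Spearman rho/p printed in the corner.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns

from .stats import AnalysisReport, significance_stars

logger = logging.getLogger(__name__)

__all__ = ["render_figures"]

_GROUP_ORDER = ("control", "nonpainful_neuroma", "painful_neuroma")


def _violin_panel(ax, df: pd.DataFrame, col: str, groups: list[str]) -> None:
    sub = df[df["group"].isin(groups)]
    sns.violinplot(
        data=sub, x="group", y=col, order=groups, inner=None,
        cut=0, ax=ax, color="#c9d7e8",
    )
    for i, g in enumerate(groups):
        vals = sub.loc[sub["group"] == g, col].dropna().to_numpy()
        if vals.size == 0:
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        ax.vlines(i, q1, q3, color="black", lw=4)
        ax.scatter([i], [med], color="white", zorder=3, s=30,
                   edgecolor="black")
    ax.set_xlabel("")
    ax.set_ylabel(col)


def render_figures(
    report: AnalysisReport,
    df: pd.DataFrame,
    out_dir: str | Path,
) -> list[Path]:
    """Write violin plots per comparison and scatter panels per correlation.

    ``df`` is the tidy table from :func:`~neuromorph.stats.compositions_to_frame`.
    Returns the list of files written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    for res in report.group_comparisons:
        try:
            prefix = "rel" if res.variable.startswith("relative") else "abs"
            cls = res.variable.split("_", 1)[1]
            col = f"{prefix}_{cls}"
            if res.comparison == "control_vs_neuroma":
                groups = ["control", "nonpainful_neuroma", "painful_neuroma"]
            else:
                groups = ["nonpainful_neuroma", "painful_neuroma"]
            fig, ax = plt.subplots(figsize=(4, 3.2))
            _violin_panel(ax, df, col, groups)
            stars = significance_stars(res.p_value)
            title = f"{res.variable} ({res.comparison})"
            if stars:
                title += f"  {stars}"
            ax.set_title(f"{title}\np = {res.p_value:.3g} [{res.test_name}]",
                         fontsize=9)
            fig.tight_layout()
            path = out_dir / f"violin_{res.comparison}_{res.variable}.png"
            fig.savefig(path, dpi=110)
            plt.close(fig)
            written.append(path)
        except Exception as exc:  # noqa: BLE001 - figures are best-effort
            logger.warning("skipping violin for %s: %s", res.variable, exc)

    corr_cols = {
        "relative_unorganized_nervous": "rel_unorganized_nervous",
        "relative_organized_nervous": "rel_organized_nervous",
        "deviation_index": "deviation_index",
    }
    for res in report.pain_correlations:
        try:
            col = corr_cols.get(res.variable)
            if col is None:
                continue
            sub = df[df["group"] != "control"][["nrs", col]].dropna()
            fig, ax = plt.subplots(figsize=(4, 3.2))
            ax.scatter(sub["nrs"], sub[col], color="#31688e")
            if len(sub) >= 2 and sub["nrs"].nunique() > 1:
                coef = np.polyfit(sub["nrs"], sub[col], 1)
                xs = np.linspace(sub["nrs"].min(), sub["nrs"].max(), 10)
                ax.plot(xs, np.polyval(coef, xs), "--", color="gray", lw=1)
            ax.set_xlabel("NRS pain score")
            ax.set_ylabel(col)
            ax.set_title(
                f"{res.variable} vs NRS\n"
                f"rho = {res.statistic:.2f}, p = {res.p_value:.3g} "
                f"{significance_stars(res.p_value)}",
                fontsize=9,
            )
            fig.tight_layout()
            path = out_dir / f"scatter_{res.variable}_vs_nrs.png"
            fig.savefig(path, dpi=110)
            plt.close(fig)
            written.append(path)
        except Exception as exc:  # noqa: BLE001
            logger.warning("skipping scatter for %s: %s", res.variable, exc)
    return written
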