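"""Figure and table generation from study result CSVs.

Plotting is strictly side-effect-only: every figure is drawn from a CSV
that is emitted alongside it, and no analysis happens here.
"""

from __future__ import annotations

from pathlib import Path
from typing import List

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


class MissingInputError(FileNotFoundError):
    pass


def _load(path: Path) -> pd.DataFrame:
    if not path.exists():
        raise MissingInputError(f"required input missing: {path}")
    frame = pd.read_csv(path)
    if frame.empty:
        raise MissingInputError(f"input {path} is empty; nothing to report")
    return frame


def _save(fig, data: pd.DataFrame, out_dir: Path, stem: str) -> None:
    data.to_csv(out_dir / f"{stem}.csv", index=False)
    fig.savefig(out_dir / f"{stem}.png", dpi=150, bbox_inches="tight")
    plt.close(fig)


def deviation_bars(summary: pd.DataFrame, out_dir: Path, endpoint: str = "ctv_mean") -> None:
    sub = summary[summary["endpoint"] == endpoint].copy()
    if sub.empty:
        return
    fig, axes = plt.subplots(1, 2, figsize=(11, 4), sharey=False)
    for ax, column, title in (
        (axes[0], "mean_deviation", "mean deviation (%)"),
        (axes[1], "max_abs_deviation", "max |deviation| (%)"),
    ):
        pivot = sub.pivot_table(index="parameter", columns="percentile", values=column)
        pivot.plot.bar(ax=ax, legend=True)
        ax.set_ylabel(title)
        ax.axhline(0.0, color="k", lw=0.5)
    fig.suptitle(f"Dose-proxy deviations vs 50th-percentile baseline ({endpoint})")
    _save(fig, sub, out_dir, f"fig_deviations_{endpoint}")


def site_panels(summary_site: pd.DataFrame, out_dir: Path, endpoint: str = "ctv_mean") -> None:
    sub = summary_site[summary_site["endpoint"] == endpoint].copy()
    if sub.empty:
        return
    sites: List[str] = sorted(sub["site_label"].unique())
    fig, axes = plt.subplots(1, len(sites), figsize=(3.2 * len(sites), 3.6), sharey=True)
    if len(sites) == 1:
        axes = [axes]
    for ax, site in zip(axes, sites):
        pivot = sub[sub["site_label"] == site].pivot_table(
            index="parameter", columns="percentile", values="mean_deviation"
        )
        pivot.plot.bar(ax=ax, legend=(site == sites[0]))
        ax.set_title(site)
        ax.axhline(0.0, color="k", lw=0.5)
    axes[0].set_ylabel("mean deviation (%)")
    _save(fig, sub, out_dir, f"fig_site_deviations_{endpoint}")


def r2_boxplot(regressions: pd.DataFrame, out_dir: Path) -> None:
    sub = regressions.dropna(subset=["r_squared"]).copy()
    if sub.empty:
        return
    order = (
        sub.groupby("metric_name")["r_squared"].mean().sort_values(ascending=False).index
    )
    data = [sub.loc[sub["metric_name"] == m, "r_squared"].values for m in order]
    fig, ax = plt.subplots(figsize=(0.6 * len(order) + 2, 4))
    ax.boxplot(data, tick_labels=list(order), showmeans=True)
    ax.set_ylabel("R-squared")
    ax.tick_params(axis="x", rotation=90)
    _save(fig, sub, out_dir, "fig_r2_by_metric")


def make_report(results_dir) -> List[str]:
    """Build all figures/tables from a study results directory."""
    out_dir = Path(results_dir)
    summary = _load(out_dir / "deviation_summary.csv")
    summary_site = _load(out_dir / "deviation_summary_by_site.csv")
    regressions = _load(out_dir / "regressions.csv")
    deviation_bars(summary, out_dir)
    site_panels(summary_site, out_dir)
    r2_boxplot(regressions, out_dir)
    made = sorted(p.name for p in out_dir.glob("fig_*.png"))
    return made
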