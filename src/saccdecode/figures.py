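"""Report figures: per-ROI accuracy bars and accuracy-vs-size curves."""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

log = logging.getLogger("saccdecode")

__all__ = ["make_figures"]


def accuracy_bars(roi_stats: pd.DataFrame, path: Path, chance_pct: float = 50.0) -> None:
    fig, ax = plt.subplots(figsize=(7, 4))
    x = range(len(roi_stats))
    ax.bar(x, roi_stats["mean_accuracy_pct"], color="#4878b0")
    for i, (_, row) in enumerate(roi_stats.iterrows()):
        if row["significant"]:
            marker = "**" if row["p_fwe"] < 0.001 else "*"
            ax.text(i, row["mean_accuracy_pct"] + 0.5, marker, ha="center")
    ax.axhline(chance_pct, color="k", linestyle="--", linewidth=1, label="chance (50%)")
    ax.set_xticks(list(x))
    ax.set_xticklabels(roi_stats["roi"], rotation=45, ha="right")
    ax.set_ylabel("decoding accuracy (%)")
    ax.set_ylim(chance_pct - 10, max(75, roi_stats["mean_accuracy_pct"].max() + 5))
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def accuracy_curves(curve_stats: pd.DataFrame, path: Path, alpha: float = 0.05) -> None:
    fig, ax = plt.subplots(figsize=(7, 4))
    for roi, grp in curve_stats.groupby("roi"):
        grp = grp.sort_values("n_features")
        ax.plot(grp["n_features"], grp["t_obs"], marker="o", label=roi)
    crit = curve_stats.groupby("n_features")["critical_t"].first()
    ax.plot(crit.index, crit.values, color="0.4", linestyle=":", label="permutation threshold")
    ax.set_xlabel("number of voxels")
    ax.set_ylabel("group t vs chance")
    ax.legend(frameon=False, fontsize=8, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def make_figures(report_dir: str | Path, out_dir: str | Path | None = None) -> list[Path]:
    """Regenerate figures from a pipeline artifact directory."""
    report_dir = Path(report_dir)
    out = Path(out_dir) if out_dir is not None else report_dir
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    stats_path = report_dir / "roi_stats.tsv"
    if stats_path.exists():
        roi_stats = pd.read_csv(stats_path, sep="\t")
        path = out / "accuracy_bars.png"
        accuracy_bars(roi_stats, path)
        written.append(path)
    else:
        log.info("no roi_stats.tsv found; skipping accuracy bar figure")

    curve_path = report_dir / "curve_stats.tsv"
    if curve_path.exists():
        curve_stats = pd.read_csv(curve_path, sep="\t")
        if curve_stats.empty:
            log.info("empty feature-count analysis; figure skipped")
        else:
            path = out / "accuracy_curves.png"
            accuracy_curves(curve_stats, path)
            written.append(path)
    else:
        log.info("no curve_stats.tsv found; skipping feature-curve figure")
    return written
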