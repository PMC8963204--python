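"""Report generation: summary tables, contrast tests, and figures."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .classify import tabulate_distribution
from .phantom import CATEGORIES
from .stats import compare_pipeline_outputs, summarize


def summary_table(measurements: pd.DataFrame) -> pd.DataFrame:
    """Median/IQR/mean/sd of defined rates per (group, pair)."""
    m = measurements[measurements["defined"]]
    rows = []
    for (group, pair), sub in m.groupby(["group", "pair"], sort=True):
        s = summarize(sub["rate_percent"])
        rows.append(
            {"group": group, "pair": pair, "n": s.n, "median": s.median,
             "q1": s.q1, "q3": s.q3, "mean": s.mean, "sd": s.sd}
        )
    return pd.DataFrame(rows)


def dot_plot(measurements: pd.DataFrame, path: str | Path, seed: int = 0) -> Path:
    """Per-islet rate dot plot by group and pair, with median/IQR bars."""
    m = measurements[measurements["defined"]]
    groups = sorted(m["group"].unique())
    pairs = sorted(m["pair"].unique())
    rng = np.random.default_rng(seed)  # jitter only
    fig, ax = plt.subplots(figsize=(1.8 * len(groups) * len(pairs) + 1, 4))
    pos = 0
    ticks, labels = [], []
    colors = {"MDA5-INS": "tab:orange", "MDA5-GCG": "tab:gray"}
    for group in groups:
        for pair in pairs:
            vals = m[(m["group"] == group) & (m["pair"] == pair)]["rate_percent"].to_numpy()
            if vals.size:
                x = pos + rng.uniform(-0.18, 0.18, size=vals.size)
                ax.plot(x, vals, "o", ms=3, alpha=0.6, color=colors.get(pair, "tab:blue"))
                s = summarize(vals)
                ax.hlines(s.median, pos - 0.3, pos + 0.3, color="k", lw=2)
                ax.vlines(pos, s.q1, s.q3, color="k", lw=1)
            ticks.append(pos)
            labels.append(f"{group}\n{pair}")
            pos += 1
        pos += 0.5
    ax.set_xticks(ticks, labels, fontsize=8)
    ax.set_ylabel("colocalization rate (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def distribution_plot(distribution: pd.DataFrame, path: str | Path) -> Path:
    """Stacked per-donor category percentages."""
    fig, ax = plt.subplots(figsize=(1 + 0.6 * len(distribution), 4))
    bottom = np.zeros(len(distribution))
    x = np.arange(len(distribution))
    for cat in CATEGORIES:
        vals = distribution[f"pct_{cat}"].to_numpy()
        ax.bar(x, vals, bottom=bottom, label=cat)
        bottom += vals
    ax.set_xticks(x, distribution["donor_id"], rotation=60, ha="right", fontsize=7)
    ax.set_ylabel("% of detected structures")
    ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def generate_report(
    measurements: pd.DataFrame,
    records: pd.DataFrame,
    out_dir: str | Path,
    alpha: float = 0.05,
    exact_below: int = 8,
    make_plots: bool = True,
) -> dict[str, Path]:
    """Write distribution table, summary stats, contrast tests, and figures."""
    from .io import write_csv

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    dist = tabulate_distribution(records)
    files["distribution"] = write_csv(out_dir / "distribution.csv", dist)
    files["summary"] = write_csv(out_dir / "summary_stats.csv", summary_table(measurements))
    contrasts = compare_pipeline_outputs(
        measurements, records, alpha=alpha, exact_below=exact_below
    )
    files["contrasts"] = write_csv(out_dir / "contrasts.csv", contrasts)

    lines = ["Group comparisons (Mann-Whitney U, two-sided):"]
    for row in contrasts.itertuples(index=False):
        star = " *" if row.significant else ""
        lines.append(
            f"  {row.contrast}: median {row.median_a:.1f} vs {row.median_b:.1f} "
            f"(n={row.n_a}/{row.n_b}), U={row.statistic:.1f}, p={row.p_value:.4g}{star}"
        )
    (out_dir / "report.txt").write_text("\n".join(lines) + "\n")
    files["text"] = out_dir / "report.txt"

    if make_plots:
        files["dot_plot"] = dot_plot(measurements, out_dir / "rates_dotplot.png")
        files["distribution_plot"] = distribution_plot(dist, out_dir / "distribution.png")
    return files
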