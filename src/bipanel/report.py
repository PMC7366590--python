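"""Tables and figures summarising a validation run."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats

from .metrics import (
    aggregate,
    band_fractions,
    error_samples,
    scenario_caps,
    summary_tests,
)

__all__ = ["render_report"]


def _heatmap(ax, pivot: pd.DataFrame, title: str) -> None:
    im = ax.imshow(
        pivot.to_numpy(),
        origin="lower",
        aspect="auto",
        extent=[
            pivot.columns.min() - 0.5,
            pivot.columns.max() + 0.5,
            pivot.index.min() - 0.5,
            pivot.index.max() + 0.5,
        ],
        cmap="viridis",
    )
    ax.set_xlabel("t_data (months of own data)")
    ax.set_ylabel("t_pred (predicted month)")
    ax.set_title(title)
    plt.colorbar(im, ax=ax, label="error ratio")


def render_report(cells: pd.DataFrame, out_dir) -> list[Path]:
    """Write the standard CSV tables and figures for a set of cells.

    Tables: the three aggregation modes, band fractions, summary tests and
    (when raw predictions are present) the cap scenario analyses.  Figures:
    mean and median error heatmaps over (t_pred, t_data), median error vs
    t_data with IQR bars and the fitted regression line, and a histogram of
    ln(observed/predicted) with a normal overlay.
    """
    if cells is None or len(cells) == 0:
        raise ValueError("no validation cells to report")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    samples = error_samples(cells)
    if samples.empty:
        raise ValueError("no cells with observed expenditure")
    written: list[Path] = []

    agg_cell = aggregate(samples, "per_tpred_tdata")
    agg_tdata = aggregate(samples, "per_tdata")
    agg_none = aggregate(samples, "none")
    tests = summary_tests(samples)
    for name, frame in [
        ("errors_per_tpred_tdata.csv", agg_cell),
        ("errors_per_tdata.csv", agg_tdata),
        ("errors_unaggregated.csv", agg_none),
        ("band_fractions.csv", band_fractions(samples)),
        ("summary_tests.csv", tests.to_frame()),
    ]:
        path = out / name
        frame.to_csv(path, index=False)
        written.append(path)

    if "raw_pred_eur" in cells.columns and "min_cap_eur" in cells.columns:
        rows = []
        for regime, res in scenario_caps(cells).items():
            row = {"scenario": regime,
                   "n_min_adjusted": res["n_min_adjusted"],
                   "n_max_adjusted": res["n_max_adjusted"]}
            row.update(res["summary"].iloc[0].to_dict())
            for _, b in res["bands"].iterrows():
                row[f"within_{int(b['band_pct'])}pct"] = b["fraction"]
            rows.append(row)
        path = out / "cap_scenarios.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        written.append(path)

    # heatmaps
    for stat, fname in [("mean", "heatmap_mean_error.png"),
                        ("median", "heatmap_median_error.png")]:
        pivot = agg_cell.pivot(index="t_pred", columns="t_data", values=stat)
        fig, ax = plt.subplots(figsize=(7, 5))
        _heatmap(ax, pivot, f"{stat} error ratio")
        fig.tight_layout()
        path = out / fname
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    # median error vs t_data with IQR bars + regression line
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.errorbar(
        agg_tdata["t_data"],
        agg_tdata["median"],
        yerr=[agg_tdata["median"] - agg_tdata["p25"],
              agg_tdata["p75"] - agg_tdata["median"]],
        fmt="o",
        color="tab:orange",
        capsize=3,
        label="median error (IQR)",
    )
    xs = np.array([samples["t_data"].min(), samples["t_data"].max()], dtype=float)
    intercept = samples["error_ratio"].mean() - tests.slope_tdata * samples["t_data"].mean()
    ax.plot(xs, intercept + tests.slope_tdata * xs, color="tab:blue",
            label=f"OLS slope {tests.slope_tdata:.3f}")
    ax.set_xlabel("t_data (months of own data)")
    ax.set_ylabel("error ratio")
    ax.legend()
    fig.tight_layout()
    path = out / "median_error_vs_tdata.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)

    # histogram of ln ratios with normal overlay
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ln = samples["ln_ratio"].to_numpy()
    ax.hist(ln, bins=50, density=True, color="tab:blue", alpha=0.7,
            label="ln(observed/predicted)")
    mu, sd = ln.mean(), ln.std(ddof=1)
    grid = np.linspace(ln.min(), ln.max(), 200)
    ax.plot(grid, stats.norm.pdf(grid, mu, sd), color="tab:orange",
            label=f"N({mu:.3f}, {sd:.3f}^2)")
    ax.set_xlabel("ln(observed / predicted)")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    path = out / "ln_ratio_histogram.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)
    return written
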