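"""Static plot exports replacing the interactive dashboard panels.

Each renderer writes a PNG plus the underlying plot data as CSV, so results
remain inspectable without the figure.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .pivot import PivotTable  # noqa: E402


def _save(fig, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def comparative_bar_plot(pivot: PivotTable, path) -> None:
    """Grouped bar chart of the pivot counts (one group per row level)."""
    counts = pivot.counts
    n_rows, n_cols = counts.shape
    x = np.arange(n_rows)
    width = 0.8 / n_cols
    fig, ax = plt.subplots(figsize=(6, 4))
    for j, col in enumerate(counts.columns):
        ax.bar(x + j * width, counts[col].to_numpy(), width, label=f"{pivot.col_var}={col}")
    ax.set_xticks(x + width * (n_cols - 1) / 2)
    ax.set_xticklabels(counts.index)
    ax.set_xlabel(pivot.row_var)
    ax.set_ylabel("count")
    ax.legend()
    _save(fig, path)
    counts.to_csv(Path(path).with_suffix(".csv"))


def forest_plot(or_table: pd.DataFrame, path) -> None:
    """Forest plot of odds-ratio points with CI whiskers on a log axis."""
    est = or_table[or_table["estimable"]]
    labels = [f"{r.row_level} / {r.col_level}" for r in est.itertuples()]
    y = np.arange(len(est))
    fig, ax = plt.subplots(figsize=(6, 1 + 0.6 * max(len(est), 1)))
    if len(est):
        err = np.array(
            [est["or_point"] - est["ci_low"], est["ci_high"] - est["or_point"]]
        )
        ax.errorbar(est["or_point"], y, xerr=err, fmt="o", capsize=3)
    ax.axvline(1.0, color="grey", linestyle="--", linewidth=1)
    ax.set_xscale("log")
    ax.set_yticks(y)
    ax.set_yticklabels(labels)
    ax.set_xlabel("odds ratio (log scale)")
    _save(fig, path)
    or_table.to_csv(Path(path).with_suffix(".csv"), index=False)


def pivot_heat_table(pivot: PivotTable, path) -> None:
    """Colour-mapped count table: cool for low counts, warm for high."""
    counts = pivot.counts
    fig, ax = plt.subplots(figsize=(1.5 + counts.shape[1], 1 + 0.6 * counts.shape[0]))
    im = ax.imshow(counts.to_numpy(), cmap="coolwarm", aspect="auto")
    ax.set_xticks(range(counts.shape[1]))
    ax.set_xticklabels(counts.columns)
    ax.set_yticks(range(counts.shape[0]))
    ax.set_yticklabels(counts.index)
    ax.set_xlabel(pivot.col_var)
    ax.set_ylabel(pivot.row_var)
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            ax.text(j, i, str(counts.iat[i, j]), ha="center", va="center")
    fig.colorbar(im, ax=ax, label="count")
    _save(fig, path)


def render_pivot_outputs(pivot: PivotTable, or_table: pd.DataFrame, out_dir) -> dict:
    """Write pivot counts, OR table, bar/forest/heat figures under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pivot.with_margins().to_csv(out / "pivot_counts.csv")
    or_table.to_csv(out / "odds_ratios.csv", index=False)
    comparative_bar_plot(pivot, out / "comparative_bar.png")
    forest_plot(or_table, out / "forest.png")
    pivot_heat_table(pivot, out / "pivot_table.png")
    return {
        "pivot_counts": out / "pivot_counts.csv",
        "odds_ratios": out / "odds_ratios.csv",
        "bar": out / "comparative_bar.png",
        "forest": out / "forest.png",
        "heat": out / "pivot_table.png",
    }


def _panel(ax, x: pd.Series, yv: pd.Series):
    x_num = pd.api.types.is_numeric_dtype(x)
    y_num = pd.api.types.is_numeric_dtype(yv)
    sub = pd.concat([x, yv], axis=1).dropna()
    if x_num and y_num:
        ax.scatter(sub.iloc[:, 0], sub.iloc[:, 1], s=4, alpha=0.4)
    elif x_num != y_num:
        num = sub.iloc[:, 0] if x_num else sub.iloc[:, 1]
        cat = sub.iloc[:, 1] if x_num else sub.iloc[:, 0]
        groups = [num[cat.astype(str) == lv].to_numpy() for lv in sorted(cat.astype(str).unique())]
        if groups:
            ax.boxplot(
                groups,
                tick_labels=sorted(cat.astype(str).unique()),
                orientation="horizontal" if x_num else "vertical",
            )
    else:
        tab = pd.crosstab(sub.iloc[:, 0].astype(str), sub.iloc[:, 1].astype(str))
        xs, ys, ss = [], [], []
        for i, r in enumerate(tab.index):
            for j, c in enumerate(tab.columns):
                xs.append(j)
                ys.append(i)
                ss.append(tab.iat[i, j])
        smax = max(ss) if ss else 1
        ax.scatter(xs, ys, s=[20 + 200 * v / max(smax, 1) for v in ss], alpha=0.6)
        ax.set_xticks(range(len(tab.columns)))
        ax.set_xticklabels(tab.columns)
        ax.set_yticks(range(len(tab.index)))
        ax.set_yticklabels(tab.index)


def pairs_plot(table, variables, path) -> None:
    """Generalised pairs grid: scatter, box or count panels by type pair."""
    frame = getattr(table, "frame", table)
    k = len(variables)
    fig, axes = plt.subplots(k, k, figsize=(2.2 * k, 2.2 * k), squeeze=False)
    for i, vy in enumerate(variables):
        for j, vx in enumerate(variables):
            ax = axes[i][j]
            if i == j:
                s = frame[vx].dropna()
                if pd.api.types.is_numeric_dtype(s):
                    ax.hist(s.astype(float), bins=20)
                else:
                    counts = s.astype(str).value_counts().sort_index()
                    ax.bar(counts.index, counts.to_numpy())
            else:
                _panel(ax, frame[vx], frame[vy])
            if i == k - 1:
                ax.set_xlabel(vx)
            if j == 0:
                ax.set_ylabel(vy)
    _save(fig, path)


def coefficient_plot(coef: pd.DataFrame, path) -> None:
    """Point estimates with 95% CI whiskers and a zero reference line."""
    sub = coef[coef["term"] != "Intercept"]
    y = np.arange(len(sub))
    fig, ax = plt.subplots(figsize=(6, 1 + 0.5 * max(len(sub), 1)))
    err = np.array([sub["estimate"] - sub["ci_low"], sub["ci_high"] - sub["estimate"]])
    ax.errorbar(sub["estimate"], y, xerr=err, fmt="o", capsize=3)
    ax.axvline(0.0, color="grey", linestyle="--", linewidth=1)
    ax.set_yticks(y)
    ax.set_yticklabels(sub["term"])
    ax.set_xlabel("estimate")
    _save(fig, path)
    coef.to_csv(Path(path).with_suffix(".csv"), index=False)


def render_regression_outputs(result, table, response, predictors, out_dir) -> dict:
    """Write coefficient/ANOVA CSVs, pairs and coefficient plots."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.coef.to_csv(out / "coefficients.csv", index=False)
    result.anova.to_csv(out / "anova.csv")
    pairs_plot(table, [response] + list(predictors), out / "pairs.png")
    coefficient_plot(result.coef, out / "coefficient_plot.png")
    return {
        "coefficients": out / "coefficients.csv",
        "anova": out / "anova.csv",
        "pairs": out / "pairs.png",
        "coefficients_plot": out / "coefficient_plot.png",
    }
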