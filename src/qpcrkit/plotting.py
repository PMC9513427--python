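"""Matplotlib figures for standard curves and expression summaries.

All functions return a :class:`matplotlib.figure.Figure` that the caller can
restyle (axes, titles, colors) before saving; nothing is written to disk
unless ``save`` is given.  Input tables are never mutated.
"""

from __future__ import annotations

import math

import matplotlib

matplotlib.use("Agg")  # noqa: E402 — headless backend before pyplot import

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def _facet_grid(n: int):
    ncols = min(n, 3)
    nrows = math.ceil(n / ncols)
    fig, axes = plt.subplots(nrows, ncols, figsize=(4 * ncols, 3.2 * nrows), squeeze=False)
    return fig, [ax for row in axes for ax in row]


def plot_curve(report: pd.DataFrame, dilutions: pd.DataFrame | None = None,
               save=None):
    """One panel per gene: dilution points, fitted line, R² and efficiency.

    Parameters
    ----------
    report : DataFrame
        Output of :func:`qpcrkit.standard_curve.curve_report`.
    dilutions : DataFrame, optional
        The dilution table; when given, observed (log10 conc, Cq) points are
        drawn under the fitted line.
    """
    if report.empty:
        raise ValueError("curve report is empty")
    fig, axes = _facet_grid(len(report))
    for ax, (_, row) in zip(axes, report.iterrows()):
        gene = row["gene"]
        if dilutions is not None:
            sub = dilutions[dilutions["gene"] == gene]
            x = np.log10(sub["rel_conc"].to_numpy(float))
            ax.scatter(x, sub["cq"], s=18, color="#2b6cb0", zorder=3)
            xs = np.linspace(x.min(), x.max(), 50)
        else:
            xs = np.linspace(-3, 0, 50)
        ax.plot(xs, row["slope"] * xs + row["intercept"], color="#c53030", lw=1.5)
        eff = "" if pd.isna(row["efficiency_pct"]) else f"E = {row['efficiency_pct']:.2f}%"
        ax.text(0.03, 0.05, f"R² = {row['r_squared']:.4f}\n{eff}",
                transform=ax.transAxes, va="bottom", fontsize=9)
        ax.set_title(str(gene))
        ax.set_xlabel("log10(relative concentration)")
        ax.set_ylabel("Cq")
    for ax in axes[len(report):]:
        ax.set_visible(False)
    fig.tight_layout()
    if save:
        fig.savefig(save, dpi=150)
    return fig


def plot_expression(summaries: pd.DataFrame, records: pd.DataFrame | None = None,
                    kind: str = "bar", error_bar: str = "se",
                    value_col: str | None = None, save=None):
    """Bar or box plot of relative expression, one panel per gene.

    Bar panels show group means with SE (default) or SD error bars and the
    significance annotation (stars or compact letters) above each bar.  Box
    panels draw the per-replicate distributions and therefore additionally
    require ``records`` (the per-replicate method output).
    """
    if kind not in ("bar", "box"):
        raise ValueError(f"kind must be 'bar' or 'box', got {kind!r}")
    if error_bar not in ("se", "sd"):
        raise ValueError(f"error_bar must be 'se' or 'sd', got {error_bar!r}")
    if summaries.empty:
        raise ValueError("summaries table is empty")
    if kind == "box" and records is None:
        raise ValueError("box plots need the per-replicate records")
    if kind == "box" and value_col is None:
        from .group_stats import _VALUE_COLS
        value_col = next(c for c in _VALUE_COLS if c in records.columns)

    genes = summaries["gene"].unique().tolist()
    group_order = summaries["group"].unique().tolist()  # consistent across panels
    fig, axes = _facet_grid(len(genes))
    for ax, gene in zip(axes, genes):
        sub = summaries[summaries["gene"] == gene].set_index("group").loc[group_order]
        xs = np.arange(len(group_order))
        err = sub[error_bar].to_numpy(float)
        if kind == "bar":
            ax.bar(xs, sub["mean"], yerr=err, capsize=3, color="#a3bfdd",
                   edgecolor="#2b6cb0")
            tops = sub["mean"].to_numpy(float) + err
        else:
            data = [
                records[(records["gene"] == gene) & (records["group"] == g)][value_col]
                .to_numpy(float)
                for g in group_order
            ]
            ax.boxplot(data, positions=xs, widths=0.5)
            tops = np.array([d.max() for d in data])
        span = max(tops.max(), 1e-12)
        for x, top, label in zip(xs, tops, sub["signif_label"]):
            ax.text(x, top + 0.03 * span, str(label), ha="center", va="bottom", fontsize=10)
        ax.set_ylim(top=span * 1.18)
        ax.set_xticks(xs)
        ax.set_xticklabels(group_order)
        ax.set_title(str(gene))
        ax.set_ylabel("relative expression")
    for ax in axes[len(genes):]:
        ax.set_visible(False)
    fig.tight_layout()
    if save:
        fig.savefig(save, dpi=150)
    return fig
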