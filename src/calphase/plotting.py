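"""Matplotlib figures for timeline results.

Three layouts: stacked start-boundary distributions per category with
interval brackets and the ACR/YD bands; a KDE/Sum summary of the component
set with the per-snapshot +/-1 sigma band; and a last-appearance-date
panel against the estimated start of exploitation.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .calcurve import CalendarPDF
from .density import ACR, YD, IntervalDefinition
from .pipeline import CategoryModelResult

__all__ = ["plot_category_starts", "plot_kde_summary", "plot_lad_panel"]


def _shade_intervals(ax, intervals: Sequence[IntervalDefinition] = (ACR, YD)) -> None:
    for iv, alpha in zip(intervals, (0.18, 0.10)):
        ax.axvspan(iv.older, iv.younger, color="grey", alpha=alpha, lw=0)


def plot_category_starts(
    results: Mapping[str, CategoryModelResult], path: str | None = None
):
    """Stacked start-boundary posteriors, oldest axis left, one row per
    category, with 95.4/68.2% brackets beneath each distribution."""
    n = len(results)
    fig, axes = plt.subplots(n, 1, figsize=(8, 1.1 * n + 1), sharex=True)
    if n == 1:
        axes = [axes]
    for ax, (name, res) in zip(axes, results.items()):
        pdf = res.start_pdf
        ax.fill_between(pdf.grid, pdf.mass, color="#4477aa", alpha=0.8, lw=0)
        _shade_intervals(ax)
        for iv, y in ((res.ci_954, -0.12), (res.ci_682, -0.22)):
            for old, young in iv:
                ax.plot([old, young], [y * pdf.mass.max()] * 2, color="k", lw=1.2)
        ax.set_yticks([])
        ax.set_ylabel(f"{name}\n(n={res.n_components})", rotation=0, ha="right", fontsize=7)
    axes[-1].set_xlabel("cal BP")
    axes[-1].invert_xaxis()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_kde_summary(kde_result, sum_pdf: CalendarPDF | None = None, path: str | None = None):
    """Kernel-density summary with the snapshot +/-1 sigma band and the
    noisier Sum distribution behind."""
    fig, ax = plt.subplots(figsize=(8, 3))
    pe = kde_result.point_estimate
    if sum_pdf is not None:
        ax.fill_between(sum_pdf.grid, sum_pdf.mass, color="lightgrey", lw=0, label="Sum")
    scale = pe.mass.sum() / max(kde_result.snapshot_mean.sum(), 1e-300)
    mean_d = kde_result.snapshot_mean * scale
    sd_d = kde_result.snapshot_sd * scale
    ax.fill_between(pe.grid, np.clip(mean_d - sd_d, 0, None), mean_d + sd_d,
                    color="#88aadd", alpha=0.5, lw=0, label="snapshots +/-1 sigma")
    ax.plot(pe.grid, pe.mass, color="#224488", lw=1.2, label="KDE model")
    _shade_intervals(ax)
    ax.set_xlabel("cal BP")
    ax.set_yticks([])
    ax.invert_xaxis()
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_lad_panel(lad_report: dict, exploitation_start: CalendarPDF, path: str | None = None):
    """Last-appearance-date KDE with the exploitation-start posterior."""
    fig, ax = plt.subplots(figsize=(8, 3))
    kde = lad_report["kde"]
    ax.fill_between(kde.grid, kde.mass, color="#ee8833", alpha=0.6, lw=0, label="LAD KDE")
    ax.fill_between(
        exploitation_start.grid, exploitation_start.mass,
        color="#882288", alpha=0.6, lw=0, label="exploitation start",
    )
    _shade_intervals(ax)
    ax.set_xlabel("cal BP")
    ax.set_yticks([])
    ax.invert_xaxis()
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
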