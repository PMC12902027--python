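"""Plots: accessibility histograms, fitted dose-response curves, stacked peaks."""

from __future__ import annotations

import numpy as np

from .inversion import HistogramFit, histogram_density
from .peaks import PeakSet, peak_contributions
from .series import DoseResponseSeries


def _get_ax(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_histogram(fit: HistogramFit, ax=None, color="tab:blue"):
    """Bar plot of λ_j / w_j on a logarithmic K axis (area = Σλ)."""
    ax = _get_ax(ax)
    dens = histogram_density(fit)
    ax.bar(
        dens.edges[:-1],
        dens.heights,
        width=np.diff(dens.edges),
        align="edge",
        color=color,
        edgecolor="black",
        linewidth=0.3,
    )
    ax.set_xscale("log")
    ax.set_xlabel(r"accessibility constant $K_\tau$ (dilution quotient)")
    ax.set_ylabel("equivalent epitopes per decade")
    return ax


def plot_fit(fit: HistogramFit, series: DoseResponseSeries | None = None, ax=None, n_points: int = 200):
    """Dose-response data with the fitted model curve overlaid."""
    ax = _get_ax(ax)
    series = series if series is not None else fit.series
    if series is not None:
        ax.errorbar(series.d, series.r, yerr=series.dr, fmt="o", ms=4, capsize=2, label="data")
        d_lo, d_hi = series.d.min(), series.d.max()
    else:
        d_lo, d_hi = fit.grid.points[0], fit.grid.points[-1]
    dd = np.geomspace(d_lo, d_hi, n_points)
    ax.plot(dd, fit.model(dd), "-", label="model")
    ax.set_xscale("log")
    ax.set_xlabel("dilution quotient $d$")
    ax.set_ylabel("normalized response")
    ax.legend()
    return ax


def plot_stacked_contributions(peaks: PeakSet, fit: HistogramFit, series: DoseResponseSeries | None = None, ax=None, n_points: int = 200):
    """Per-peak contributions stacked from low K to high K."""
    ax = _get_ax(ax)
    series = series if series is not None else fit.series
    d_lo, d_hi = (
        (series.d.min(), series.d.max()) if series is not None else (fit.grid.points[0], fit.grid.points[-1])
    )
    dd = np.geomspace(d_lo, d_hi, n_points)
    contrib = peak_contributions(peaks, fit, dd)
    stacked = contrib.stacked
    lower = np.zeros_like(dd)
    for k in range(len(peaks)):
        ax.fill_between(dd, lower, stacked[k], alpha=0.5, label=f"peak {k + 1}")
        lower = stacked[k]
    if series is not None:
        ax.errorbar(series.d, series.r, yerr=series.dr, fmt="ko", ms=4, capsize=2, label="data")
    ax.set_xscale("log")
    ax.set_xlabel("dilution quotient $d$")
    ax.set_ylabel("normalized response")
    ax.legend()
    return ax
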