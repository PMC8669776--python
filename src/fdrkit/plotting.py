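"""Diagnostic plots: FDR results by rank or Z-value, and pi0 histograms.

All plots are written to non-interactive image files (PNG/SVG/PDF per the
path suffix) and the (figure, axes) pair is returned for further styling.
"""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402

from .adjust import FDRResult  # noqa: E402
from .pi0 import _resolve_breaks  # noqa: E402
from .transforms import RawPValueSet, p_to_z, z_to_p  # noqa: E402
from .twogroup import TwoGroupModel, mixture_density  # noqa: E402

__all__ = ["plot_results", "plot_pi0_diagnostics"]

_DEFAULT_COLORS = ("dodgerblue", "firebrick", "black")


def plot_results(
    result: FDRResult,
    path=None,
    x_axis: str = "rank",
    raw_pvalues: bool = True,
    adj_pvalues: bool = True,
    fdrs: bool = True,
    sig_line: bool = True,
    adj_sig_line: bool = True,
    zvalues=None,
    xlim=None,
    ylim=(0.0, 1.0),
    title: str | None = None,
    legend_where: str | None = None,
    colors=_DEFAULT_COLORS,
):
    """Plot raw p-values, adjusted p-values and FDR estimates.

    With ``x_axis="rank"`` the x-coordinate is the p-value rank and the raw
    step-up rejection line gamma*i/m is drawn; with ``x_axis="zvalues"`` the
    x-coordinate is the Z-value (computed from the raw p-values under the
    result's sidedness unless an explicit, consistent ``zvalues`` vector is
    supplied).  Each point series and threshold line can be suppressed.
    """
    if result.m == 0:
        raise ValueError("empty result; nothing to plot")
    if x_axis not in ("rank", "zvalues"):
        raise ValueError(f"x_axis must be 'rank' or 'zvalues', got {x_axis!r}")
    m = result.m
    if x_axis == "rank":
        order = np.argsort(result.raw_p, kind="stable")
        x = np.empty(m)
        x[order] = np.arange(1, m + 1)
        xlabel = "Rank of raw p-value"
    else:
        if zvalues is not None:
            z = np.asarray(zvalues, dtype=float)
            back = z_to_p(z, result.sidedness)
            if np.max(np.abs(back - result.raw_p)) > 1e-6:
                raise ValueError(
                    "supplied Z-values are inconsistent with the raw p-values "
                    "under the result's sidedness"
                )
            x = z
        else:
            x = p_to_z(result.raw_p, result.sidedness)
        xlabel = "Z-value"

    fig, ax = plt.subplots(figsize=(7, 5))
    col_fdr, col_adj, col_raw = (colors * 3)[:3] if len(colors) < 3 else colors[:3]
    if raw_pvalues:
        ax.plot(x, result.raw_p, linestyle="none", marker="o", color=col_raw,
                markersize=4, label="Raw p-values")
    if adj_pvalues:
        ax.plot(x, result.adjusted_p, linestyle="none", marker="*", color=col_adj,
                markersize=7, label="Adjusted p-values")
    if fdrs:
        ax.plot(x, result.fdrs, linestyle="none", marker="o", color=col_fdr,
                markersize=4, label="FDR estimates")
    if sig_line and x_axis == "rank":
        i = np.arange(1, m + 1)
        ax.plot(i, result.threshold * i / m, color="black", linestyle="--",
                linewidth=1, label="Rejection line γ·i/m")
    if adj_sig_line:
        ax.axhline(result.threshold, color=col_fdr, linestyle=":",
                   linewidth=1, label=f"Threshold γ = {result.threshold:g}")
    ax.set_xlabel(xlabel)
    ax.set_ylabel("Probability")
    if xlim is not None:
        ax.set_xlim(xlim)
    if ylim is not None:
        ax.set_ylim(ylim)
    ax.set_title(title or f"{result.method} FDR estimation and control")
    ax.legend(loc=legend_where or ("upper left" if x_axis == "rank" else "upper right"))
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig, ax


def plot_pi0_diagnostics(
    pset: RawPValueSet,
    model: TwoGroupModel | None = None,
    breaks: int | str = "scott",
    path=None,
    sidedness: str = "two.sided",
):
    """P-value histogram with the last-bin-height line; optional Z overlay.

    The left panel shows the p-value histogram on the density scale with a
    horizontal line at the height of the bin adjacent to 1 (the Last
    Histogram Height null level).  When a two-group model is supplied, a
    second panel overlays the null, alternative and mixture densities on the
    Z-value histogram.
    """
    if pset.m < 2:
        raise ValueError("need at least 2 p-values to plot diagnostics")
    b = _resolve_breaks(pset, breaks)
    counts, edges = np.histogram(pset.values, bins=b, range=(0.0, 1.0))
    last_density = counts[-1] * b / pset.m

    ncols = 2 if model is not None else 1
    fig, axes = plt.subplots(1, ncols, figsize=(6 * ncols, 4.5), squeeze=False)
    ax = axes[0, 0]
    ax.hist(pset.values, bins=edges, density=True, color="grey", edgecolor="white")
    ax.axhline(last_density, color="firebrick", linewidth=1.5,
               label=f"Last bin height (H_B·B/m = {last_density:.3g})")
    ax.set_xlabel("Raw p-value")
    ax.set_ylabel("Density")
    ax.set_title("P-value histogram")
    ax.legend()

    if model is not None:
        axz = axes[0, 1]
        z = p_to_z(pset.values, sidedness)
        zgrid = np.linspace(min(z.min(), -4.0), max(z.max(), 4.0), 400)
        axz.hist(z, bins=min(30, max(10, b)), density=True, color="grey",
                 edgecolor="white")
        axz.plot(zgrid, model.null.pdf(zgrid), color="dodgerblue", label="Null f0")
        axz.plot(zgrid, model.alt.pdf(zgrid), color="firebrick", label="Alternative f1")
        axz.plot(zgrid, mixture_density(model, zgrid), color="black",
                 label=f"Mixture (π0 = {model.pi0:g})")
        axz.set_xlabel("Z-value")
        axz.set_ylabel("Density")
        axz.set_title("Two-group densities")
        axz.legend()

    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig, axes
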