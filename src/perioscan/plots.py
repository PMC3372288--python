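"""Static rendering of periodicity plots and scans.

Figures are derived views: every plot has a sibling tab-delimited table
written by the CLI, and nothing is computed here that the tables do not
already contain.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .scan import PersistencyCurves, ScanIndices, ScanResult, heatmap_matrix
from .spectrum import SpacingSpectrum

__all__ = ["render_periodicity_plot", "render_scan_plot"]

_THRESHOLD_COLORS = {2.0: "c", 2.5: "m", 3.0: "b", 4.0: "g", 6.0: "r"}


def render_periodicity_plot(
    spectrum: SpacingSpectrum,
    thresholds: tuple[float, float, float] | None,
    path: str | Path,
) -> Path:
    """Q*(P) curve with significance shading.

    The dark band marks values below the null 50th percentile, the light
    band values between the 50th and 95th percentiles, and a bare line
    marks the 99th percentile; peaks rising above the shading can be
    considered significant.  Degenerate spectra yield a placeholder figure
    with a diagnostic message.
    """
    path = Path(path)
    fig, ax = plt.subplots(figsize=(7, 4))
    if spectrum.degenerate:
        ax.text(
            0.5,
            0.5,
            f"degenerate spectrum: {spectrum.note}",
            ha="center",
            va="center",
            transform=ax.transAxes,
        )
        ax.set_axis_off()
    else:
        ax.plot(spectrum.periods, spectrum.q, "k-", lw=1)
        if thresholds is not None:
            p99, p95, p50 = thresholds
            x = spectrum.periods
            ax.fill_between(x, 0, p50, color="0.55", zorder=0)
            ax.fill_between(x, p50, p95, color="0.82", zorder=0)
            ax.axhline(p99, color="0.3", lw=0.8)
        ax.annotate(
            f"MaxQ = {spectrum.max_q:.2f}\nPMaxQ = {spectrum.p_max_q:.2f} bp",
            xy=(spectrum.p_max_q, spectrum.max_q),
            xytext=(0.75, 0.85),
            textcoords="axes fraction",
            arrowprops={"arrowstyle": "->", "lw": 0.8},
        )
        ax.set_xlim(spectrum.periods[0], spectrum.periods[-1])
        ax.set_ylim(bottom=0)
        ax.set_xlabel("period P (bp)")
        ax.set_ylabel("Q*(P)")
        code = spectrum.method.code if spectrum.method else ""
        ax.set_title(
            f"periodicity plot ({code}, s = {spectrum.s_min}-{spectrum.s_max} bp)"
        )
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path


def render_scan_plot(
    scan: ScanResult,
    curves: PersistencyCurves,
    indices: ScanIndices,
    path: str | Path,
) -> Path:
    """Three-panel periodicity scan figure.

    (a) heat map of Q*(P) per window, white at Q* <= 1.8 and black at
    Q* >= 4.0; (b) fraction of windows with the spectrum maximum within
    +/- 0.2 bp of each period; (c) fraction of windows with Q*(P) above
    each of the five exceedance thresholds.
    """
    if scan.n_retained == 0:
        raise ValueError("scan has no retained windows; nothing to plot")
    path = Path(path)
    fig, axes = plt.subplots(
        3, 1, figsize=(8, 9), gridspec_kw={"height_ratios": [2, 1, 1]}
    )
    grey = heatmap_matrix(scan)
    mids = scan.midpoints
    extent = (
        float(mids[0] - scan.window_length / 2),
        float(mids[-1] + scan.window_length / 2),
        float(scan.periods[0]),
        float(scan.periods[-1]),
    )
    axes[0].imshow(
        grey,
        aspect="auto",
        origin="lower",
        cmap="gray_r",
        vmin=0.0,
        vmax=1.0,
        extent=extent,
        interpolation="nearest",
    )
    axes[0].set_xlabel("chromosome position (bp)")
    axes[0].set_ylabel("period (bp)")
    axes[0].set_title(
        f"periodicity scan ({scan.method.code}, {scan.window_length / 1000:g} kb "
        f"window, {scan.step / 1000:g} kb step)"
    )

    axes[1].plot(curves.periods, curves.argmax_fraction, "k-", lw=1)
    axes[1].set_ylabel("fraction of windows\n(argmax near P)")
    if indices.p_max_max is not None:
        axes[1].annotate(
            f"MaxMax = {indices.max_max:.2f} @ {indices.p_max_max:.2f} bp",
            xy=(0.65, 0.85),
            xycoords="axes fraction",
        )

    for t, curve in curves.exceed_fraction.items():
        axes[2].plot(
            curves.periods, curve, color=_THRESHOLD_COLORS.get(t, "k"), lw=1,
            label=f"Q* ≥ {t:g}",
        )
    axes[2].set_xlabel("period P (bp)")
    axes[2].set_ylabel("fraction of windows")
    axes[2].legend(fontsize=7, ncol=5, loc="upper right")
    note = []
    if indices.p_max2 is not None:
        note.append(f"Max2 = {indices.max2:.2f} @ {indices.p_max2:.2f} bp")
    if indices.p_max3 is not None:
        note.append(f"Max3 = {indices.max3:.2f} @ {indices.p_max3:.2f} bp")
    if note:
        axes[2].annotate("\n".join(note), xy=(0.02, 0.75), xycoords="axes fraction")
    for ax in axes[1:]:
        ax.set_xlim(curves.periods[0], curves.periods[-1])
        ax.set_ylim(0, 1.05)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path
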