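"""Standard figures for an agreement report: correlation, Bland-Altman, histograms."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .stats import ComparisonReport


def correlation_plot(report: ComparisonReport, comp: str, ax=None):
    """Scatter of MRI vs reference velocities with OLS fit and identity line."""
    pv = report.pairs[comp]
    corr = report.correlation[comp]
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(pv.v_ref, pv.v_mri, ".", ms=2, alpha=0.4)
    lim = np.array([min(pv.v_ref.min(), pv.v_mri.min()), max(pv.v_ref.max(), pv.v_mri.max())])
    ax.plot(lim, lim, "k--", lw=0.8, label="identity")
    ax.plot(lim, corr.slope * lim + corr.intercept, "b-", lw=1.2, label="best fit")
    ax.set_xlabel(f"reference v_{comp} (cm/s)")
    ax.set_ylabel(f"PC MRI v_{comp} (cm/s)")
    ax.set_title(f"v_{comp}: r={corr.r:.3f}, n={corr.n}")
    ax.legend(fontsize=8)
    return ax


def bland_altman_plot(report: ComparisonReport, comp: str, ax=None):
    """Pairwise mean vs difference with bias and limits of agreement."""
    pv = report.pairs[comp]
    ba = report.agreement[comp]
    if ax is None:
        _, ax = plt.subplots()
    mean = 0.5 * (pv.v_mri + pv.v_ref)
    diff = pv.v_mri - pv.v_ref
    ax.plot(mean, diff, ".", ms=2, alpha=0.4)
    for y, style in ((ba.bias, "b-"), (ba.loa_lower, "r--"), (ba.loa_upper, "r--")):
        ax.axhline(y, ls=style[1:], color=style[0], lw=1.0)
    ax.set_xlabel(f"mean of methods, v_{comp} (cm/s)")
    ax.set_ylabel("MRI − reference (cm/s)")
    ax.set_title(f"v_{comp}: bias={ba.bias:.2f} cm/s")
    return ax


def histogram_plot(report: ComparisonReport, comp: str, ax=None):
    """Overlaid velocity histograms of the two methods."""
    h = report.histograms[comp]
    if ax is None:
        _, ax = plt.subplots()
    edges = np.asarray(h["bin_edges"])
    centers = 0.5 * (edges[:-1] + edges[1:])
    ax.step(centers, h["mri_counts"], where="mid", color="tab:blue", label="PC MRI")
    ax.step(centers, h["ref_counts"], where="mid", color="tab:red", label="reference")
    ax.set_xlabel(f"v_{comp} (cm/s)")
    ax.set_ylabel("voxels")
    ax.legend(fontsize=8)
    return ax


def report_figures(report: ComparisonReport, out_dir: str | Path) -> list[Path]:
    """Write correlation/Bland-Altman/histogram PNGs per component."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for comp in report.pairs:
        fig, axes = plt.subplots(1, 3, figsize=(13, 4))
        correlation_plot(report, comp, axes[0])
        bland_altman_plot(report, comp, axes[1])
        histogram_plot(report, comp, axes[2])
        fig.tight_layout()
        path = out_dir / f"agreement_{comp}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
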