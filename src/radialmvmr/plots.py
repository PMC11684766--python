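"""Radial MVMR plot construction.

Plot geometry is computed as pure data (:class:`PlotSpec`) so it can be
asserted in tests; rendering to an image is a thin matplotlib step.  The
paired unadjusted/adjusted plots share x-coordinates, display filtering and
fitted lines (the MVMR estimates through the origin); in the adjusted plot
each point's squared vertical distance to its exposure's line is its
heterogeneity contribution Q_kj.  Points are shown only for (SNP, exposure)
pairs whose univariable F-statistic exceeds a display threshold (default
10), which hides clusters of negligible weightings without affecting
estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import RadialPoint, SummaryDataset
from .mvmr import RadialFit, adjust_points, detect_outliers

__all__ = ["PlotSpec", "build_rmvmr_plot_pair", "build_outlier_plot",
           "render_plot", "render_plot_pair"]

_PALETTE = ("#1b9e77", "#d95f02", "#7570b3", "#e7298a", "#66a61e", "#e6ab02")


@dataclass(frozen=True)
class PlotSpec:
    """Renderer-agnostic description of one radial plot.

    ``points`` carries one row per displayed (SNP, exposure) observation
    with x, y and the exposure's display colour; ``lines`` one row per
    exposure with the fitted slope through the origin.  ``reference_p`` is
    the p-value threshold line for outlier plots (None otherwise).
    """

    points: pd.DataFrame
    lines: pd.DataFrame
    adjusted: bool
    display_filter: float
    x_label: str = "square-root weight"
    y_label: str = "ratio estimate × square-root weight"
    reference_p: float | None = None

    def to_frame(self) -> pd.DataFrame:
        """Flat table of displayed points (for export / assertions)."""
        return self.points.copy()


def _colour_map(exposure_names) -> dict[str, str]:
    return {name: _PALETTE[i % len(_PALETTE)] for i, name in enumerate(exposure_names)}


def _points_frame(points: list[RadialPoint], adjusted: bool,
                  colours: dict[str, str]) -> pd.DataFrame:
    return pd.DataFrame({
        "snp": [p.snp_id for p in points],
        "exposure": [p.exposure for p in points],
        "x": [p.x for p in points],
        "y": [p.y_adjusted if adjusted else p.y_unadjusted for p in points],
        "F": [p.per_exposure_F for p in points],
        "colour": [colours[p.exposure] for p in points],
    })


def build_rmvmr_plot_pair(ds: SummaryDataset, fit: RadialFit,
                          threshold: float = 10.0) -> tuple[PlotSpec, PlotSpec]:
    """Construct the paired (unadjusted, adjusted) radial MVMR plot specs.

    Both specs display the same points (per-exposure F above ``threshold``)
    at the same x-coordinates and carry identical fitted lines; only the
    ordinate differs (raw versus other-exposure-adjusted).
    """
    if threshold < 0:
        raise ValueError(f"display threshold must be >= 0, got {threshold}")
    pts = adjust_points(ds, fit)
    shown = [p for p in pts if p.per_exposure_F > threshold]
    colours = _colour_map(fit.exposure_names)
    lines = pd.DataFrame({
        "exposure": fit.exposure_names,
        "slope": fit.beta,
        "colour": [colours[e] for e in fit.exposure_names],
    })
    make = lambda adj: PlotSpec(points=_points_frame(shown, adj, colours),
                                lines=lines, adjusted=adj,
                                display_filter=threshold)
    return make(False), make(True)


def build_outlier_plot(fit: RadialFit, alpha: float = 0.05) -> PlotSpec:
    """Scatter of flagged SNPs' minimum Q p-values with the threshold line."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    flagged = detect_outliers(fit, alpha)
    order = {s: i for i, s in enumerate(fit.snp_ids)}
    min_p = fit.per_snp_Q_p.min(axis=1)
    points = pd.DataFrame({
        "snp": flagged,
        "exposure": "",
        "x": [float(order[s]) for s in flagged],
        "y": [float(min_p[order[s]]) for s in flagged],
        "F": np.nan,
        "colour": "#d95f02",
    })
    lines = pd.DataFrame({"exposure": [], "slope": [], "colour": []})
    return PlotSpec(points=points, lines=lines, adjusted=False,
                    display_filter=0.0, x_label="SNP index",
                    y_label="minimum Q p-value across exposures",
                    reference_p=alpha)


def render_plot(spec: PlotSpec, path, title: str | None = None) -> None:
    """Render a single plot spec to an image file (format from the suffix)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    if len(spec.points):
        for name, grp in spec.points.groupby("exposure", sort=False):
            ax.scatter(grp["x"], grp["y"], s=14, alpha=0.8,
                       color=grp["colour"].iloc[0], label=str(name) or None)
    if len(spec.lines):
        xmax = float(spec.points["x"].max()) if len(spec.points) else 1.0
        xs = np.array([0.0, 1.05 * xmax])
        for _, row in spec.lines.iterrows():
            ax.plot(xs, row["slope"] * xs, color=row["colour"], lw=1.5,
                    label=f"{row['exposure']} (slope {row['slope']:.3g})")
    if spec.reference_p is not None:
        ax.axhline(spec.reference_p, ls=":", color="grey",
                   label=f"p = {spec.reference_p:g}")
    ax.set_xlabel(spec.x_label)
    ax.set_ylabel(spec.y_label)
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8, frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def render_plot_pair(unadjusted: PlotSpec, adjusted: PlotSpec, path) -> None:
    """Render the unadjusted/adjusted pair side by side."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(11, 4.5))
    for ax, spec, label in zip(axes, (unadjusted, adjusted),
                               ("unadjusted", "adjusted")):
        if len(spec.points):
            for name, grp in spec.points.groupby("exposure", sort=False):
                ax.scatter(grp["x"], grp["y"], s=14, alpha=0.8,
                           color=grp["colour"].iloc[0], label=str(name))
        if len(spec.lines):
            xmax = float(spec.points["x"].max()) if len(spec.points) else 1.0
            xs = np.array([0.0, 1.05 * xmax])
            for _, row in spec.lines.iterrows():
                ax.plot(xs, row["slope"] * xs, color=row["colour"], lw=1.5)
        ax.set_title(label)
        ax.set_xlabel(spec.x_label)
        ax.set_ylabel(spec.y_label)
    axes[0].legend(fontsize=8, frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
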