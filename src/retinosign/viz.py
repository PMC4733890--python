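"""Figure conventions: contour maps, arrow diagrams, and sign overlays.

Conventions reproduced here:

* isoeccentricity contours are solid and thick, with an extra-thick contour
  every 10 deg; the shading ramp runs red (central) -> blue -> green
  (peripheral);
* isopolar angle contours are thinner -- dashed in the upper field, dotted in
  the lower field, with a thick dashed horizontal-meridian (0 deg) line; the
  ramp runs green (lower) -> blue (horizontal meridian) -> red (upper);
* field sign shading is yellow (mirror) / gray (indeterminate) / blue-purple
  (nonmirror), composited at partial opacity over an optional background with
  contours on top;
* arrow diagrams place one arrow per penetration whose length is the RF
  eccentricity and whose angle is the RF polar angle; upper-field arrows are
  bold.

Output is SVG; rendering is deterministic for fixed input.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import LinearSegmentedColormap

from .fieldsign import FieldSignMap
from .gridding import GridField
from .rf_data import RFTable

__all__ = ["ContourStyle", "PALETTE", "contour_levels", "contour_map",
           "arrow_diagram", "sign_overlay", "save_svg"]

# Single palette table so figures stay comparable across runs.  Paper colors
# are approximations (exact values are not recoverable from the text).
PALETTE = {
    "mirror": "#e8d24a",          # yellow
    "indeterminate": "#9a9a9a",   # gray
    "nonmirror": "#5a3f9e",       # blue-purple
    "eccentricity_ramp": ["#c0392b", "#3b5bd6", "#2e8b57"],
    "polar_ramp": ["#2e8b57", "#3b5bd6", "#c0392b"],
    "border": "#666666",
}

SIGN_CMAP = LinearSegmentedColormap.from_list(
    "fieldsign", [PALETTE["mirror"], PALETTE["indeterminate"],
                  PALETTE["nonmirror"]])


@dataclass(frozen=True)
class ContourStyle:
    """Contouring rules for one quantity."""

    quantity: str = "eccentricity"   # or "polar_angle"
    interval: float = 2.0
    emphasis_interval: float = 10.0
    base_linewidth: float = 0.8
    shade: bool = True

    def __post_init__(self) -> None:
        if self.interval <= 0:
            raise ValueError("interval must be > 0")
        ratio = self.emphasis_interval / self.interval
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                "emphasis interval must be an integer multiple of interval")


def contour_levels(vmin: float, vmax: float, interval: float) -> np.ndarray:
    """Multiples of ``interval`` inside [vmin, vmax]."""
    lo = math.ceil(vmin / interval - 1e-9)
    hi = math.floor(vmax / interval + 1e-9)
    return interval * np.arange(lo, hi + 1)


def _is_emphasis(level: float, style: ContourStyle) -> bool:
    ratio = level / style.emphasis_interval
    return abs(ratio - round(ratio)) < 1e-9


def contour_map(field: GridField, style: ContourStyle, ax=None):
    """Contour a grid field with the texture/ramp conventions above.

    Returns the matplotlib figure.  A field with no supported cell yields an
    empty drawing with a warning annotation.
    """
    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 6))
    else:
        fig = ax.figure
    ax.set_aspect("equal")
    ax.set_xlabel("cortex x (mm)")
    ax.set_ylabel("cortex y (mm)")
    if not field.mask.any():
        ax.annotate("no supported cells", (0.5, 0.5),
                    xycoords="axes fraction", ha="center")
        return fig
    vals = np.ma.masked_invalid(field.values)
    vmin, vmax = float(vals.min()), float(vals.max())
    levels = contour_levels(vmin, vmax, style.interval)
    ramp_key = ("eccentricity_ramp" if style.quantity == "eccentricity"
                else "polar_ramp")
    if style.shade:
        cmap = LinearSegmentedColormap.from_list(ramp_key, PALETTE[ramp_key])
        ax.pcolormesh(field.xs, field.ys, vals, cmap=cmap, shading="nearest",
                      alpha=0.6)
    for level in levels:
        if vmax - vmin <= 0:
            break
        emph = _is_emphasis(level, style)
        if style.quantity == "eccentricity":
            lw = style.base_linewidth * (3.0 if emph else 1.5)
            ls = "solid"
        else:
            if level == 0.0:               # horizontal meridian
                lw, ls = style.base_linewidth * 2.5, "dashed"
            elif level > 0:                # upper field
                lw = style.base_linewidth * (1.6 if emph else 1.0)
                ls = "dashed"
            else:                          # lower field
                lw = style.base_linewidth * (1.6 if emph else 1.0)
                ls = "dotted"
        ax.contour(field.xs, field.ys, vals, levels=[level], colors="black",
                   linewidths=lw, linestyles=ls)
    return fig


def arrow_diagram(table: RFTable, scale: float = 0.05, ax=None):
    """One arrow per record: length proportional to eccentricity, direction
    the polar angle under the left-hemifield convention (upper-field arrows
    bold)."""
    if not table.normalized:
        raise ValueError("arrow diagrams require a normalized table")
    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 6))
    else:
        fig = ax.figure
    ax.set_aspect("equal")
    ax.set_xlabel("cortex x (mm)")
    ax.set_ylabel("cortex y (mm)")
    for rec in table.records:
        length = scale * rec.r
        psi = math.radians(rec.theta)
        # left-hemifield chart direction at clockwise angle theta from the
        # left horizontal meridian
        dx, dy = -math.cos(psi) * length, math.sin(psi) * length
        if length == 0.0:
            ax.plot([rec.x], [rec.y], marker=".", color="black",
                    markersize=2)
            continue
        bold = rec.theta > 0
        ax.annotate(
            "", xy=(rec.x + dx / 2, rec.y + dy / 2),
            xytext=(rec.x - dx / 2, rec.y - dy / 2),
            arrowprops=dict(arrowstyle="->", color="black",
                            lw=1.6 if bold else 0.8),
        )
    return fig


def sign_overlay(fsmap: FieldSignMap, contour_fields=None, background=None,
                 borders=None, truth_borders=None, ax=None):
    """Composite drawing: optional background raster, field sign shading at
    partial opacity, then contours and border polylines on top."""
    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 6))
    else:
        fig = ax.figure
    ax.set_aspect("equal")
    ny, nx = fsmap.shape
    extent = (fsmap.origin[0] - fsmap.spacing / 2,
              fsmap.origin[0] + (nx - 0.5) * fsmap.spacing,
              fsmap.origin[1] - fsmap.spacing / 2,
              fsmap.origin[1] + (ny - 0.5) * fsmap.spacing)
    if background is not None:
        ax.imshow(background, extent=extent, origin="lower", cmap="gray")
    shade = np.where(fsmap.valid, fsmap.shade, 0.0)
    ax.imshow(shade, extent=extent, origin="lower", cmap=SIGN_CMAP,
              vmin=-1.0, vmax=1.0, alpha=0.75, interpolation="nearest")
    if contour_fields:
        for fld, style in contour_fields:
            if (fld.shape != fsmap.shape
                    or abs(fld.spacing - fsmap.spacing) > 1e-9
                    or np.any(np.abs(np.subtract(fld.origin, fsmap.origin))
                              > 1e-9)):
                raise ValueError("contour field frame does not match the "
                                 "sign map frame")
            contour_map(fld, style, ax=ax)
    for group, color, lw in ((borders, PALETTE["border"], 1.5),
                             (truth_borders, "black", 1.0)):
        if group:
            for poly in group:
                arr = np.asarray(poly)
                ax.plot(arr[:, 0], arr[:, 1], color=color, lw=lw)
    return fig


def save_svg(fig, path: str | os.PathLike) -> None:
    """Write an SVG with stable ids and no timestamp, so identical input
    produces identical bytes."""
    with plt.rc_context({"svg.hashsalt": "retinosign"}):
        fig.savefig(path, format="svg", metadata={"Date": None})
    plt.close(fig)
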