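"""Quiver and 3D renderings of alignment vector fields.

Axial vectors have no head, so 2D fields are drawn as headless bars
centered on their grid position, color-coded by alignment length; 3D stack
views show only cells above the visualization threshold, with z magnified
(default ×4) to separate the slices.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .field import CircularBoundary, StackField, VectorField, filter_high_alignment

PathLike = Union[str, Path]


def plot_field(
    field: VectorField,
    path: Optional[PathLike] = None,
    boundary: Optional[CircularBoundary] = None,
    ax=None,
):
    """2D headless quiver of one slice's valid cells, tumor circle overlaid."""
    if ax is None:
        fig, ax = plt.subplots(figsize=(7, 7))
    else:
        fig = ax.figure
    valid = field.valid_cells()
    if valid:
        pos = np.array([c.position for c in valid])
        length = np.array([c.vector.length for c in valid])
        ang = np.radians([c.vector.axial_angle or 0.0 for c in valid])
        scale = field.grid.circle_radius  # bar length 0..R like the field plots
        u = scale * length * np.cos(ang)
        v = -scale * length * np.sin(ang)  # y axis points down on screen
        ax.quiver(
            pos[:, 0], pos[:, 1], u, v, length,
            angles="xy", scale_units="xy", scale=1.0, pivot="mid",
            headwidth=1, headlength=0, headaxislength=0,
            cmap="viridis", clim=(0.0, 1.0), width=0.0025,
        )
        fig.colorbar(ax.collections[-1], ax=ax, label="alignment", shrink=0.8)
    if boundary is not None:
        ax.add_patch(
            plt.Circle(boundary.center, boundary.radius, fill=False,
                       color="goldenrod", lw=2)
        )
    ax.set_xlim(0, field.grid.image_width + 1)
    ax.set_ylim(field.grid.image_height + 1, 0)  # image convention: y down
    ax.set_aspect("equal")
    ax.set_xlabel("x [px]")
    ax.set_ylabel("y [px]")
    ax.set_title(f"local alignment vectors, z={field.z_index}")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_stack_3d(
    stack: StackField,
    path: Optional[PathLike] = None,
    viz_threshold: float = 0.8,
    z_scale: float = 4.0,
):
    """3D view of high-alignment cells (length > viz_threshold), z magnified."""
    fig = plt.figure(figsize=(8, 7))
    ax = fig.add_subplot(projection="3d")
    high = filter_high_alignment(stack, viz_threshold)
    px = stack.fields[0].pixel_size
    if high:
        x = np.array([h[0] for h in high]) * px
        y = np.array([h[1] for h in high]) * px
        z = np.array([h[2] for h in high]) * z_scale
        length = np.array([h[3].length for h in high])
        ang = np.radians([h[3].axial_angle or 0.0 for h in high])
        bar = stack.fields[0].grid.circle_radius * px
        u = bar * length * np.cos(ang)
        v = -bar * length * np.sin(ang)
        ax.quiver(
            x - u / 2, y - v / 2, z, u, v, 0.0,
            arrow_length_ratio=0.0, linewidth=0.8,
            colors=plt.cm.viridis(length),
        )
    ax.set_xlabel("x [μm]")
    ax.set_ylabel("y [μm]")
    ax.set_zlabel(f"z [μm × {z_scale:g}]")
    ax.set_title(f"alignment > {viz_threshold:g}")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
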