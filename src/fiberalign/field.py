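"""Local sampling-circle grids, alignment vector fields and summaries.

A square grid of sampling positions (default every 5 px) is laid over each
image slice; at every position a circle of radius R (default 25 px) gathers
the quantized fiber segments whose midpoints fall inside it, and the
alignment vector of those segments' angles becomes the local vector.

Cells are excluded — in this priority order — when the sampling circle
crosses the image boundary, when it crosses or lies inside the circular
tumor boundary, or when it contains no more than the minimum number of
fiber segments (strictly more than F segments are required).  Summary
statistics (alignment distribution, mean alignment, strong-alignment ratio)
pool the valid cells of all z-slices with equal weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .circular import AlignmentVector, alignment_vector
from .errors import ConfigError, EmptyInputError, EmptyStatisticsError
from .geometry import Point, QuantizedSegment

VALID = "valid"
EXCLUDED_IMAGE_BOUNDARY = "excluded_image_boundary"
EXCLUDED_TUMOR_BOUNDARY = "excluded_tumor_boundary"
EXCLUDED_MIN_FIBERS = "excluded_min_fibers"
STATUSES = (VALID, EXCLUDED_IMAGE_BOUNDARY, EXCLUDED_TUMOR_BOUNDARY, EXCLUDED_MIN_FIBERS)


@dataclass(frozen=True)
class CircularBoundary:
    """Circular tumor boundary for one z-slice: center (x, y) and radius, px."""

    center: Point
    radius: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.center).all() and np.isfinite(self.radius)):
            raise ConfigError("boundary center/radius must be finite")
        if self.radius <= 0:
            raise ConfigError(f"boundary radius must be positive, got {self.radius}")


@dataclass(frozen=True)
class GridSpec:
    """Sampling-grid geometry and exclusion parameters."""

    image_width: int
    image_height: int
    spacing: float = 5.0
    circle_radius: float = 25.0
    min_fiber_count: int = 10

    def __post_init__(self) -> None:
        if self.spacing <= 0 or self.circle_radius <= 0:
            raise ConfigError("spacing and circle_radius must be positive")
        if self.image_width < 1 or self.image_height < 1:
            raise ConfigError("image dimensions must be >= 1 pixel")
        if self.min_fiber_count < 0:
            raise ConfigError("min_fiber_count must be >= 0")


@dataclass(frozen=True)
class GridCell:
    """One grid position with its exclusion status and (if valid) vector."""

    position: Point
    status: str
    vector: Optional[AlignmentVector] = None
    n_segments: int = 0  # segments inside the circle, recorded for all cells


@dataclass(frozen=True)
class VectorField:
    """Alignment vector field of one z-slice."""

    grid: GridSpec
    cells: List[GridCell] = field(repr=False)
    z_index: int = 0
    z_spacing: float = 1.0  # μm between slices
    pixel_size: float = 1.0  # μm per pixel

    def valid_cells(self) -> List[GridCell]:
        return [c for c in self.cells if c.status == VALID]

    def status_counts(self) -> dict:
        counts = {s: 0 for s in STATUSES}
        for c in self.cells:
            counts[c.status] += 1
        return counts


@dataclass(frozen=True)
class StackField:
    """Z-stack of vector fields sharing one grid."""

    fields: List[VectorField]

    def __post_init__(self) -> None:
        if not self.fields:
            raise EmptyInputError("StackField needs at least one VectorField")
        g0 = self.fields[0].grid
        for f in self.fields[1:]:
            if f.grid != g0 or f.pixel_size != self.fields[0].pixel_size:
                raise ConfigError("all fields in a stack must share GridSpec and pixel size")

    def valid_cells(self) -> List[Tuple[VectorField, GridCell]]:
        return [(f, c) for f in self.fields for c in f.valid_cells()]


FieldLike = Union[VectorField, StackField]


def _as_stack(obj: FieldLike) -> StackField:
    return obj if isinstance(obj, StackField) else StackField([obj])


def _valid_lengths(obj: FieldLike) -> np.ndarray:
    lengths = np.array(
        [c.vector.length for _, c in _as_stack(obj).valid_cells()], dtype=float
    )
    if lengths.size == 0:
        raise EmptyStatisticsError("no valid cells in field/stack")
    return lengths


def build_grid(width: int, height: int, spacing: float) -> np.ndarray:
    """Grid positions 1 + k·spacing (1-based) covering a width×height image.

    Returns an (n, 2) array of (x, y) positions in row-major order (y outer,
    x inner); each axis has floor((dim − 1)/spacing) + 1 positions.
    """
    if spacing <= 0:
        raise ConfigError(f"spacing must be positive, got {spacing}")
    if width < 1 or height < 1:
        raise ConfigError("image dimensions must be >= 1 pixel")
    xs = 1.0 + spacing * np.arange(int(np.floor((width - 1) / spacing)) + 1)
    ys = 1.0 + spacing * np.arange(int(np.floor((height - 1) / spacing)) + 1)
    gx, gy = np.meshgrid(xs, ys)  # row-major: y varies slowest
    return np.column_stack([gx.ravel(), gy.ravel()])


def classify_cell(
    position: Point,
    grid: GridSpec,
    boundary: Optional[CircularBoundary],
    segments_in_circle: int,
) -> str:
    """Exclusion status of a sampling circle at ``position``.

    Priority: image boundary (circle must lie wholly inside
    [1, width] × [1, height]) > tumor boundary (circle intersects or lies
    inside the tumor disk) > minimum fiber count (strictly more than
    ``min_fiber_count`` segments required).
    """
    x, y = position
    R = grid.circle_radius
    if x - R < 1 or x + R > grid.image_width or y - R < 1 or y + R > grid.image_height:
        return EXCLUDED_IMAGE_BOUNDARY
    if boundary is not None:
        d = float(np.hypot(x - boundary.center[0], y - boundary.center[1]))
        if d < boundary.radius + R:
            return EXCLUDED_TUMOR_BOUNDARY
    if segments_in_circle <= grid.min_fiber_count:
        return EXCLUDED_MIN_FIBERS
    return VALID


def segments_in_circle(
    segments: Sequence[QuantizedSegment], center: Point, radius: float
) -> List[QuantizedSegment]:
    """Segments whose midpoint lies within ``radius`` of ``center`` (inclusive)."""
    if radius <= 0:
        raise ConfigError(f"radius must be positive, got {radius}")
    cx, cy = center
    return [
        s
        for s in segments
        if np.hypot(s.midpoint[0] - cx, s.midpoint[1] - cy) <= radius
    ]


def compute_field(
    segments: Sequence[QuantizedSegment],
    grid: GridSpec,
    boundary: Optional[CircularBoundary] = None,
    *,
    z_index: int = 0,
    z_spacing: float = 1.0,
    pixel_size: float = 1.0,
) -> VectorField:
    """Alignment vector field over the sampling grid for one slice.

    For every grid position the segments whose midpoints fall inside the
    sampling circle are gathered (KD-tree lookup), the cell is classified,
    and valid cells receive the alignment vector of the gathered angles.
    Deterministic given its inputs.
    """
    positions = build_grid(grid.image_width, grid.image_height, grid.spacing)
    if len(segments) > 0:
        mids = np.array([s.midpoint for s in segments], dtype=float)
        angles = np.array([s.angle for s in segments], dtype=float)
        hits = cKDTree(mids).query_ball_point(positions, grid.circle_radius)
    else:
        angles = np.empty(0)
        hits = [[] for _ in range(len(positions))]
    cells: List[GridCell] = []
    for pos, idx in zip(positions, hits):
        p = (float(pos[0]), float(pos[1]))
        n = len(idx)
        status = classify_cell(p, grid, boundary, n)
        vec = alignment_vector(angles[idx], position=p) if status == VALID else None
        cells.append(GridCell(p, status, vec, n))
    return VectorField(grid, cells, z_index, z_spacing, pixel_size)


def global_alignment(segments: Sequence[QuantizedSegment]) -> AlignmentVector:
    """Alignment vector over *all* segments (the global, whole-image measure)."""
    if len(segments) == 0:
        raise EmptyInputError("global_alignment: no segments")
    return alignment_vector([s.angle for s in segments])


def alignment_distribution(
    stack: FieldLike, bin_width: float = 0.05
) -> Tuple[np.ndarray, np.ndarray]:
    """Normalized histogram of valid-cell alignment lengths, pooled over z.

    Returns ``(edges, density)`` with bins of width ``bin_width`` spanning
    [0, 1]; the density integrates to 1.
    """
    if not (0 < bin_width <= 1):
        raise ConfigError(f"bin_width must be in (0, 1], got {bin_width}")
    lengths = _valid_lengths(stack)
    edges = np.concatenate([np.arange(0.0, 1.0, bin_width), [1.0]])
    density, edges = np.histogram(lengths, bins=edges, density=True)
    return edges, density


def mean_alignment(stack: FieldLike) -> float:
    """Mean alignment length over valid cells, pooled over all z-slices."""
    return float(_valid_lengths(stack).mean())


def strong_alignment_ratio(stack: FieldLike, threshold: float = 0.7) -> float:
    """Fraction of valid cells (pooled over z) with alignment > threshold."""
    if not (0.0 <= threshold <= 1.0):
        raise ConfigError(f"threshold must be in [0, 1], got {threshold}")
    lengths = _valid_lengths(stack)
    return float((lengths > threshold).mean())


def filter_high_alignment(
    stack: FieldLike, threshold: float = 0.8
) -> List[Tuple[float, float, float, AlignmentVector]]:
    """Valid cells with alignment > threshold, as (x, y, z_μm, vector).

    The z coordinate is z_index × z_spacing; x and y stay in pixels.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ConfigError(f"threshold must be in [0, 1], got {threshold}")
    out = []
    for f, c in _as_stack(stack).valid_cells():
        if c.vector.length > threshold:
            out.append(
                (c.position[0], c.position[1], f.z_index * f.z_spacing, c.vector)
            )
    return out


def circle_size_sweep(
    segments: Sequence[QuantizedSegment],
    grid: GridSpec,
    radii: Sequence[float],
    boundary: Optional[CircularBoundary] = None,
) -> pd.DataFrame:
    """Effect of the sampling-circle radius on the field statistics.

    One row per radius:

    - ``mean_alignment`` over valid cells (NaN when none are valid),
    - ``mean_segment_count`` over *interior* cells (those passing the
      image- and tumor-boundary exclusions) — non-decreasing in radius on
      any fixed segment set,
    - ``valid_fraction``: valid cells / all grid cells.
    """
    if len(radii) == 0 or any(r <= 0 for r in radii):
        raise ConfigError("radii must be a non-empty list of positive values")
    rows = []
    for r in radii:
        f = compute_field(segments, replace(grid, circle_radius=float(r)), boundary)
        interior = [c for c in f.cells if c.status not in
                    (EXCLUDED_IMAGE_BOUNDARY, EXCLUDED_TUMOR_BOUNDARY)]
        valid = f.valid_cells()
        rows.append(
            {
                "radius": float(r),
                "mean_alignment": float(np.mean([c.vector.length for c in valid]))
                if valid
                else float("nan"),
                "mean_segment_count": float(np.mean([c.n_segments for c in interior]))
                if interior
                else float("nan"),
                "valid_fraction": len(valid) / len(f.cells),
            }
        )
    return pd.DataFrame(rows)


def select_circle_radius(
    sweep: pd.DataFrame,
    segments: Sequence[QuantizedSegment],
    grid: GridSpec,
    boundary: Optional[CircularBoundary] = None,
    coverage: float = 0.9,
) -> Optional[float]:
    """Heuristic choice of sampling-circle radius from a sweep.

    Picks the smallest swept radius for which at least ``coverage`` of the
    interior cells contain strictly more than ``grid.min_fiber_count``
    segments — i.e. the smallest circle that keeps the minimum-fiber
    exclusion rare.  This selection rule is this package's own heuristic;
    returns ``None`` when no swept radius qualifies.
    """
    for r in sorted(sweep["radius"]):
        f = compute_field(segments, replace(grid, circle_radius=float(r)), boundary)
        interior = [c for c in f.cells if c.status not in
                    (EXCLUDED_IMAGE_BOUNDARY, EXCLUDED_TUMOR_BOUNDARY)]
        if not interior:
            continue
        frac = np.mean([c.n_segments > grid.min_fiber_count for c in interior])
        if frac >= coverage:
            return float(r)
    return None
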