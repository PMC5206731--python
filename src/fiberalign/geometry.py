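"""Fiber polylines and their quantization into fixed-length segments.

Extracted fibers (e.g. CT-FIRE output) arrive as ordered polylines of
sub-pixel vertex coordinates.  Because a fiber's contribution to an
alignment measure should be proportional to its length, each polyline is
*quantized*: walked by arclength and cut into straight chords whose
arclength step is exactly the filter length L (default 5 px).  A long fiber
thus becomes many equal-weight segments, and fibers shorter than L — mostly
segmentation noise — drop out entirely.

Coordinate convention: continuous pixel coordinates, origin at the image's
top-left, x rightward, y downward (1-based for raster-aligned data).  Angles
are measured counterclockwise from +x with y negated, so "vertical" on
screen is 90°.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, List, Sequence, Tuple

import numpy as np

from .errors import ConfigError, DegenerateSegmentError, DomainError

Point = Tuple[float, float]


@dataclass(frozen=True)
class FiberPath:
    """An extracted fiber: ordered polyline of (x, y) pixel vertices."""

    id: Hashable
    vertices: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
            raise DomainError(f"fiber {self.id!r}: need an (n>=2, 2) vertex array")
        if not np.all(np.isfinite(v)):
            raise DomainError(f"fiber {self.id!r}: non-finite vertex coordinates")
        if float(np.linalg.norm(np.diff(v, axis=0), axis=1).sum()) <= 0.0:
            raise DomainError(f"fiber {self.id!r}: zero arclength")
        object.__setattr__(self, "vertices", v)

    @property
    def arclength(self) -> float:
        """Total polyline length: sum of consecutive vertex distances."""
        return float(np.linalg.norm(np.diff(self.vertices, axis=0), axis=1).sum())


@dataclass(frozen=True)
class QuantizedSegment:
    """A straight chord cut from a fiber at fixed arclength step."""

    p1: Point
    p2: Point
    midpoint: Point
    angle: float  # axial, degrees in [0, 180)
    source_fiber: Hashable


def segment_angle(p1: Point, p2: Point) -> float:
    """Axial angle of the chord p1→p2, degrees in [0, 180).

    Uses the image convention (y downward, angle CCW from +x with y
    negated); swapping the endpoints gives the same angle.
    """
    dx = float(p2[0]) - float(p1[0])
    dy = float(p2[1]) - float(p1[1])
    if dx == 0.0 and dy == 0.0:
        raise DegenerateSegmentError(f"coincident points {p1} and {p2}")
    return float(np.degrees(np.arctan2(-dy, dx)) % 180.0)


def quantize_fiber(fiber: FiberPath, filter_length: float) -> List[QuantizedSegment]:
    """Cut a fiber polyline into chords of arclength step ``filter_length``.

    The polyline is sampled at arclengths 0, L, 2L, … by linear
    interpolation within its edges; each quantized segment is the straight
    chord between consecutive samples (chord length ≤ L for curved paths,
    arclength step exactly L).  The trailing remainder of arclength < L is
    dropped, so a fiber yields floor(arclength / L) segments and fibers
    shorter than L yield none.
    """
    if not np.isfinite(filter_length) or filter_length <= 0:
        raise ConfigError(f"filter_length must be positive, got {filter_length!r}")
    v = fiber.vertices
    step = np.linalg.norm(np.diff(v, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(step)])
    total = float(cum[-1])
    # small epsilon so an exact multiple of L (e.g. 40/5) is not lost to roundoff
    n = int(np.floor(total / filter_length + 1e-9))
    if n == 0:
        return []
    s = filter_length * np.arange(n + 1, dtype=float)
    xs = np.interp(s, cum, v[:, 0])
    ys = np.interp(s, cum, v[:, 1])
    out: List[QuantizedSegment] = []
    for i in range(n):
        p1 = (float(xs[i]), float(ys[i]))
        p2 = (float(xs[i + 1]), float(ys[i + 1]))
        mid = ((p1[0] + p2[0]) / 2.0, (p1[1] + p2[1]) / 2.0)
        out.append(QuantizedSegment(p1, p2, mid, segment_angle(p1, p2), fiber.id))
    return out


def quantize_all(
    fibers: Sequence[FiberPath], filter_length: float
) -> List[QuantizedSegment]:
    """Quantize every fiber; segments keep fiber order, then path order."""
    out: List[QuantizedSegment] = []
    for f in fibers:
        out.extend(quantize_fiber(f, filter_length))
    return out
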