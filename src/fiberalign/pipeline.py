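"""End-to-end analysis: fibers in, vector fields and summaries out."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .errors import ConfigError, EmptyInputError
from .field import (
    CircularBoundary,
    GridSpec,
    StackField,
    alignment_distribution,
    circle_size_sweep,
    compute_field,
    mean_alignment,
    strong_alignment_ratio,
)
from .geometry import FiberPath, quantize_all

log = logging.getLogger("fiberalign")


@dataclass(frozen=True)
class PipelineResult:
    stack: StackField
    distribution: Tuple[np.ndarray, np.ndarray]  # (edges, density)
    mean_alignment: float
    strong_ratio: float
    exclusion_counts: Dict[int, Dict[str, int]] = field(repr=False, default_factory=dict)
    sweep: Optional[pd.DataFrame] = None


def run_pipeline(
    config: AnalysisConfig,
    fibers_by_slice: Dict[int, Sequence[FiberPath]],
    boundaries_by_slice: Optional[Dict[int, CircularBoundary]] = None,
    image_size: Tuple[int, int] = (512, 512),
    sweep_radii: Optional[Sequence[float]] = None,
) -> PipelineResult:
    """Quantize fibers, compute per-slice fields, and summarize the stack.

    ``fibers_by_slice`` maps z_index → fibers; if ``boundaries_by_slice``
    is given it must cover every fiber slice.  Deterministic given inputs.
    When ``sweep_radii`` is set, a circle-size sweep over the first slice
    is attached to the result.
    """
    if not fibers_by_slice:
        raise EmptyInputError("no fiber slices provided")
    grid = GridSpec(
        image_width=image_size[0],
        image_height=image_size[1],
        spacing=config.spacing,
        circle_radius=config.circle_radius,
        min_fiber_count=config.min_fiber_count,
    )
    log.info("analysis config: %s; grid: %s", config, grid)
    fields: List = []
    exclusion_counts: Dict[int, Dict[str, int]] = {}
    first_segments = None
    first_boundary = None
    for z in sorted(fibers_by_slice):
        fibers = list(fibers_by_slice[z])
        if not fibers:
            raise EmptyInputError(f"slice {z}: no fibers")
        boundary = None
        if boundaries_by_slice is not None:
            if z not in boundaries_by_slice:
                raise ConfigError(f"slice {z}: no tumor boundary provided")
            boundary = boundaries_by_slice[z]
        segments = quantize_all(fibers, config.filter_length)
        f = compute_field(
            segments,
            grid,
            boundary,
            z_index=int(z),
            z_spacing=config.z_spacing,
            pixel_size=config.pixel_size,
        )
        counts = f.status_counts()
        exclusion_counts[int(z)] = counts
        log.info(
            "slice %d: %d fibers -> %d segments; cells %s", z, len(fibers),
            len(segments), counts,
        )
        fields.append(f)
        if first_segments is None:
            first_segments, first_boundary = segments, boundary
    stack = StackField(fields)
    result = PipelineResult(
        stack=stack,
        distribution=alignment_distribution(stack, config.bin_width),
        mean_alignment=mean_alignment(stack),
        strong_ratio=strong_alignment_ratio(stack, config.strong_threshold),
        exclusion_counts=exclusion_counts,
        sweep=circle_size_sweep(first_segments, grid, sweep_radii, first_boundary)
        if sweep_radii
        else None,
    )
    log.info(
        "stack: %d slices, %d valid cells, mean alignment %.4f, strong ratio %.4f",
        len(fields), len(stack.valid_cells()), result.mean_alignment,
        result.strong_ratio,
    )
    return result
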