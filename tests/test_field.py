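"""Sampling-circle grids, exclusion rules, vector fields and summaries."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import fiberalign as fa
from fiberalign.errors import ConfigError, EmptyInputError, EmptyStatisticsError
from fiberalign.field import (
    EXCLUDED_IMAGE_BOUNDARY,
    EXCLUDED_MIN_FIBERS,
    EXCLUDED_TUMOR_BOUNDARY,
    VALID,
)

from conftest import make_stack, straight_fiber


def dense_parallel_segments(angle=30.0, box=200, spacing=4.0):
    """Homogeneous field of parallel segments covering a box."""
    fibers = [
        straight_fiber(f"{i}_{j}", (x, y), angle, 20.0)
        for i, x in enumerate(np.arange(5.0, box - 25.0, spacing))
        for j, y in enumerate(np.arange(5.0, box - 5.0, spacing))
    ]
    return fa.quantize_all(fibers, 5.0)


# ---------------------------------------------------------------- build_grid

@pytest.mark.parametrize(
    "w,h,spacing,n_axis_x,n_axis_y",
    [(512, 512, 5, 103, 103), (10, 10, 5, 2, 2), (10, 10, 50, 1, 1), (7, 13, 3, 3, 5)],
)
def test_build_grid_counts(w, h, spacing, n_axis_x, n_axis_y):
    pos = fa.build_grid(w, h, spacing)
    assert len(pos) == n_axis_x * n_axis_y
    assert pos[:, 0].min() == 1 and pos[:, 1].min() == 1
    assert pos[:, 0].max() <= w and pos[:, 1].max() <= h


@given(st.integers(1, 600), st.integers(1, 600), st.integers(1, 50))
def test_build_grid_matches_enumeration(w, h, spacing):
    pos = fa.build_grid(w, h, spacing)
    xs = [c for c in range(1, w + 1) if (c - 1) % spacing == 0]
    ys = [c for c in range(1, h + 1) if (c - 1) % spacing == 0]
    assert len(pos) == len(xs) * len(ys)
    # row-major: y varies slowest
    assert list(pos[: len(xs), 0]) == xs
    assert all(pos[: len(xs), 1] == ys[0])


def test_build_grid_rejects_bad_spacing():
    with pytest.raises(ConfigError):
        fa.build_grid(512, 512, 0)


# ------------------------------------------------------------- classify_cell

def test_classification_rules_and_priority():
    grid = fa.GridSpec(512, 512, 5, 25, 10)
    tumor = fa.CircularBoundary((256.0, 256.0), 100.0)
    # circle leaves the image
    assert fa.classify_cell((2.0, 2.0), grid, None, 99) == EXCLUDED_IMAGE_BOUNDARY
    # image boundary wins over tumor overlap
    assert fa.classify_cell((2.0, 256.0), grid, fa.CircularBoundary((2.0, 256.0), 100.0),
                            99) == EXCLUDED_IMAGE_BOUNDARY
    # at the tumor center: inside the disk
    assert fa.classify_cell((256.0, 256.0), grid, tumor, 99) == EXCLUDED_TUMOR_BOUNDARY
    # circle grazing the tumor: distance < r_tumor + R excluded, beyond valid
    assert fa.classify_cell((256.0 + 124.0, 256.0), grid, tumor, 99) == EXCLUDED_TUMOR_BOUNDARY
    assert fa.classify_cell((256.0 + 126.0, 256.0), grid, tumor, 99) == VALID
    # strictly-more-than rule for the minimum fiber count
    assert fa.classify_cell((256.0, 156.0 - 26.0), grid, tumor, 5) == EXCLUDED_MIN_FIBERS
    assert fa.classify_cell((256.0, 130.0), grid, tumor, 10) == EXCLUDED_MIN_FIBERS
    assert fa.classify_cell((256.0, 130.0), grid, tumor, 11) == VALID


def test_segments_in_circle_inclusive_boundary():
    segs = fa.quantize_all([straight_fiber("f", (100.0, 100.0), 0.0, 5.0)], 5.0)
    mid = segs[0].midpoint
    got = fa.segments_in_circle(segs, (mid[0] + 10.0, mid[1]), 10.0)
    assert got == segs  # distance exactly equal to the radius is inside
    assert fa.segments_in_circle(segs, (mid[0] + 10.001, mid[1]), 10.0) == []


# ------------------------------------------------------------- compute_field

def test_homogeneous_field_matches_global_vector():
    segs = dense_parallel_segments(angle=30.0)
    grid = fa.GridSpec(200, 200, 10, 25, 10)
    field = fa.compute_field(segs, grid)
    glob = fa.global_alignment(segs)
    valid = field.valid_cells()
    assert valid, "expected valid cells on a dense homogeneous field"
    for c in valid:
        assert c.vector.length == pytest.approx(glob.length, abs=1e-12)
        assert c.vector.axial_angle == pytest.approx(glob.axial_angle, abs=1e-9)
    assert glob.length == pytest.approx(1.0)


def test_empty_segments_give_min_fiber_exclusions():
    grid = fa.GridSpec(200, 200, 10, 25, 0)
    field = fa.compute_field([], grid)
    statuses = {c.status for c in field.cells
                if c.status != EXCLUDED_IMAGE_BOUNDARY}
    assert statuses == {EXCLUDED_MIN_FIBERS}  # 0 <= 0 fails the strict rule


def test_statuses_partition_the_grid():
    segs = dense_parallel_segments()
    grid = fa.GridSpec(200, 200, 10, 25, 10)
    tumor = fa.CircularBoundary((0.0, 200.0), 60.0)
    field = fa.compute_field(segs, grid, tumor)
    counts = field.status_counts()
    assert sum(counts.values()) == len(field.cells) == len(fa.build_grid(200, 200, 10))
    assert all(v >= 0 for v in counts.values())
    assert counts[EXCLUDED_TUMOR_BOUNDARY] > 0


def test_radial_configuration_recovers_radial_directions():
    """With fibers normal to the tumor boundary, every valid cell's axial
    angle is close to its own radial direction from the tumor center."""
    cfg = fa.RadialSimConfig(seed=7)
    segs = fa.quantize_all(fa.simulate_radial(cfg), 5.0)
    grid = fa.GridSpec(512, 512, 25, 25, 10)
    field = fa.compute_field(segs, grid, cfg.boundary)
    cx, cy = cfg.boundary.center
    checked = 0
    for c in field.valid_cells():
        radial = np.degrees(np.arctan2(-(c.position[1] - cy), c.position[0] - cx)) % 180.0
        delta = abs(c.vector.axial_angle - radial) % 180.0
        assert min(delta, 180.0 - delta) < 10.0
        checked += 1
    assert checked > 50


def test_translation_equivariance():
    """Shifting segments, boundary and positions by one grid step maps each
    interior cell onto an identical cell."""
    fibers = [straight_fiber(i, (60.0 + 7 * i % 80, 60.0 + 11 * i % 80), (37 * i) % 180, 20.0)
              for i in range(40)]
    segs = fa.quantize_all(fibers, 5.0)
    shifted = [
        fa.QuantizedSegment(
            (s.p1[0] + 10, s.p1[1] + 10), (s.p2[0] + 10, s.p2[1] + 10),
            (s.midpoint[0] + 10, s.midpoint[1] + 10), s.angle, s.source_fiber)
        for s in segs
    ]
    grid = fa.GridSpec(300, 300, 10, 25, 0)
    tumor = fa.CircularBoundary((150.0, 150.0), 30.0)
    tumor2 = fa.CircularBoundary((160.0, 160.0), 30.0)
    f1 = {c.position: c for c in fa.compute_field(segs, grid, tumor).cells}
    f2 = {c.position: c for c in fa.compute_field(shifted, grid, tumor2).cells}
    compared = 0
    for (x, y), c in f1.items():
        c2 = f2.get((x + 10, y + 10))
        if c2 is None or c.status == EXCLUDED_IMAGE_BOUNDARY or \
                c2.status == EXCLUDED_IMAGE_BOUNDARY:
            continue
        assert c2.status == c.status
        assert c2.n_segments == c.n_segments
        if c.status == VALID:
            assert c2.vector.length == pytest.approx(c.vector.length, abs=1e-12)
        compared += 1
    assert compared > 100


# ------------------------------------------------------------------ summaries

def test_distribution_normalizes_and_localizes():
    edges, density = fa.alignment_distribution(make_stack([1.0, 1.0, 1.0]), 0.05)
    assert np.sum(density * np.diff(edges)) == pytest.approx(1.0, abs=1e-9)
    assert density[-1] > 0 and np.all(density[:-1] == 0)
    edges, density = fa.alignment_distribution(make_stack(np.linspace(0.01, 0.99, 500)))
    assert np.sum(density * np.diff(edges)) == pytest.approx(1.0, abs=1e-9)


def test_summary_statistics_examples():
    assert fa.mean_alignment(make_stack([0.2, 0.4])) == pytest.approx(0.3)
    stack = make_stack([0.8, 0.6, 0.9, 0.5])
    assert fa.strong_alignment_ratio(stack, 0.7) == pytest.approx(0.5)
    assert fa.strong_alignment_ratio(stack, 1.0) == 0.0  # strict inequality
    assert fa.strong_alignment_ratio(make_stack([1.0] * 4), 0.7) == 1.0


def test_strong_ratio_non_increasing_in_threshold(rng):
    stack = make_stack(rng.uniform(0, 1, 200))
    ratios = [fa.strong_alignment_ratio(stack, t) for t in np.linspace(0, 1, 21)]
    assert all(a >= b for a, b in zip(ratios, ratios[1:]))


def test_empty_statistics_raise():
    grid = fa.GridSpec(100, 100, 10, 25, 0)
    stack = fa.StackField([fa.compute_field([], grid)])
    for call in (
        lambda: fa.mean_alignment(stack),
        lambda: fa.strong_alignment_ratio(stack, 0.7),
        lambda: fa.alignment_distribution(stack),
    ):
        with pytest.raises(EmptyStatisticsError):
            call()
    with pytest.raises(EmptyInputError):
        fa.global_alignment([])


def test_filter_high_alignment():
    stack = make_stack([0.5, 0.85, 0.95], z_spacing=2.0)
    assert fa.filter_high_alignment(stack, 0.8 + 0.2) == []
    assert len(fa.filter_high_alignment(stack, 0.0)) == 3
    high = fa.filter_high_alignment(stack, 0.8)
    assert [h[3].length for h in high] == [0.85, 0.95]
    assert all(h[2] == 0.0 for h in high)  # z_index 0 × z_spacing


def test_circle_size_sweep_area_scaling():
    segs = dense_parallel_segments(spacing=3.0)
    grid = fa.GridSpec(200, 200, 10, 25, 10)
    sweep = fa.circle_size_sweep(segs, grid, [15.0, 25.0, 35.0])
    counts = sweep["mean_segment_count"].to_numpy()
    assert np.all(np.diff(counts) > 0)
    # homogeneous density: counts scale with circle area
    assert counts[1] / counts[0] == pytest.approx((25 / 15) ** 2, rel=0.1)
    assert counts[2] / counts[0] == pytest.approx((35 / 15) ** 2, rel=0.1)
    single = fa.circle_size_sweep(segs, grid, [25.0])
    assert len(single) == 1


def test_circle_size_sweep_mixing_lowers_alignment():
    """On the heterogeneous radial field, larger circles mix orientations."""
    cfg = fa.RadialSimConfig(seed=11)
    segs = fa.quantize_all(fa.simulate_radial(cfg), 5.0)
    grid = fa.GridSpec(512, 512, 20, 25, 10)
    sweep = fa.circle_size_sweep(segs, grid, [15.0, 40.0, 80.0], cfg.boundary)
    align = sweep["mean_alignment"].to_numpy()
    assert align[0] > align[1] > align[2]


def test_select_circle_radius_heuristic():
    segs = dense_parallel_segments(spacing=3.0)
    grid = fa.GridSpec(200, 200, 10, 25, 10)
    sweep = fa.circle_size_sweep(segs, grid, [3.0, 15.0, 25.0])
    chosen = fa.select_circle_radius(sweep, segs, grid)
    assert chosen == 15.0  # smallest swept radius with ample segment coverage
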